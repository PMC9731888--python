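"""End-to-end pipeline: digest -> quantify -> differential -> enrich -> correlate.

``run_pipeline`` executes the stages in order on file inputs, writes every
output table as TSV under the output directory, and records a manifest
(package version, config hash, per-stage row counts) so that reruns on
identical inputs can be verified to be identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .correlation import correlate, read_clinical_table
from .differential import (
    COMPARISONS,
    Thresholds,
    differential_table,
    volcano_plot,
    volcano_table,
)
from .digestion import DigestionParams, build_gene_models, capacity_table, read_isoform_fasta
from .enrichment import over_representation, read_gmt
from .errors import ConfigError, GclfqError
from .quantify import quantify, read_design, read_peptide_table

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """File inputs and parameters of one pipeline run."""

    fasta: Path
    peptides: Path
    design: Path
    out_dir: Path
    gmt: Path | None = None
    clinical: Path | None = None
    digestion: DigestionParams = field(default_factory=DigestionParams)
    thresholds: Thresholds = field(default_factory=Thresholds)
    comparisons: tuple[str, ...] = ("T1_vs_T0", "T2_vs_T0", "T2_vs_T1")
    razor: bool = False
    plots: bool = False

    def __post_init__(self) -> None:
        for name in ("fasta", "peptides", "design", "gmt", "clinical", "out_dir"):
            value = getattr(self, name)
            if value is not None:
                setattr(self, name, Path(value))
        for name in ("fasta", "peptides", "design"):
            path = getattr(self, name)
            if not path.exists():
                raise ConfigError(f"{name} file not found: {path}")
        for name in ("gmt", "clinical"):
            path = getattr(self, name)
            if path is not None and not path.exists():
                raise ConfigError(f"{name} file not found: {path}")
        unknown = set(self.comparisons) - set(COMPARISONS)
        if unknown:
            raise ConfigError(f"unknown comparison(s): {sorted(unknown)}")

    def config_hash(self) -> str:
        payload = {
            "fasta": str(self.fasta),
            "peptides": str(self.peptides),
            "design": str(self.design),
            "gmt": str(self.gmt),
            "clinical": str(self.clinical),
            "digestion": {
                "protease_rule": self.digestion.protease_rule.value,
                "max_missed_cleavages": self.digestion.max_missed_cleavages,
                "min_peptide_length": self.digestion.min_peptide_length,
                "max_peptide_length": self.digestion.max_peptide_length,
            },
            "thresholds": {
                "log2fc_min": self.thresholds.log2fc_min,
                "alpha": self.thresholds.alpha,
                "min_pairs": self.thresholds.min_pairs,
            },
            "comparisons": list(self.comparisons),
            "razor": self.razor,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    capacities: pd.DataFrame
    quant: "object"  # GeneQuantMatrix
    differential: dict[str, pd.DataFrame]
    volcano: dict[str, pd.DataFrame]
    enrichment: dict[str, pd.DataFrame]
    correlations: dict[str, pd.DataFrame]
    manifest: dict


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write outputs under ``config.out_dir``."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "gclfq_version": __version__,
        "config_hash": config.config_hash(),
        "comparisons": list(config.comparisons),
        "counts": {},
    }

    stage = "digest"
    try:
        isoforms = read_isoform_fasta(config.fasta)
        genes = build_gene_models(isoforms, config.digestion)
        caps = capacity_table(genes).sort_values("gene_symbol").reset_index(drop=True)
        caps.to_csv(out / "capacities.tsv", sep="\t", index=False)
        manifest["counts"]["isoforms"] = len(isoforms)
        manifest["counts"]["genes_with_capacity"] = len(genes)
        logger.info("digest: %d isoforms -> %d genes with capacity", len(isoforms), len(genes))

        stage = "quantify"
        table = read_peptide_table(config.peptides)
        design = read_design(config.design)
        quant, report = quantify(table, genes, config.digestion, design, razor=config.razor)
        quant_sorted_index = quant.total_auc.index.sort_values()
        for layer in ("total_auc", "ibaq", "ifot", "log_ifot"):
            setattr(quant, layer, getattr(quant, layer).loc[quant_sorted_index])
        quant.to_tsv(out / "quant.tsv")
        manifest["counts"]["peptide_rows"] = report.n_rows_in
        manifest["counts"]["peptide_rows_assigned"] = report.n_rows_assigned
        manifest["counts"]["shared_peptides_dropped"] = report.n_peptides_shared
        manifest["counts"]["unassigned_peptides"] = report.n_peptides_unassigned
        manifest["counts"]["genes_quantified"] = int(quant.detected.any(axis=1).sum())

        stage = "differential"
        de_tables: dict[str, pd.DataFrame] = {}
        volcano_tables: dict[str, pd.DataFrame] = {}
        for name in config.comparisons:
            comp = COMPARISONS[name]
            de = differential_table(quant, comp, config.thresholds)
            de = de.sort_index()
            de_out = de.reset_index().rename(columns={"index": "gene_symbol"})
            de_out.to_csv(out / f"de_{name}.tsv", sep="\t", index=False, float_format="%.6g")
            volcano = volcano_table(de)
            volcano.reset_index().to_csv(
                out / f"volcano_{name}.tsv", sep="\t", index=False, float_format="%.6g"
            )
            if config.plots:
                volcano_plot(de, out / f"volcano_{name}.png", title=name)
            de_tables[name] = de
            volcano_tables[name] = volcano
            manifest["counts"][f"called_{name}"] = int(de["called"].sum())
            logger.info("differential %s: %d genes called", name, int(de["called"].sum()))

        stage = "enrich"
        enrich_tables: dict[str, pd.DataFrame] = {}
        if config.gmt is not None:
            background = list(quant.genes)
            collection = read_gmt(config.gmt, background)
            for name, de in de_tables.items():
                de_genes = list(de.index[de["called"]])
                if not de_genes:
                    continue
                enr = over_representation(de_genes, collection)
                enr.to_csv(out / f"enrichment_{name}.tsv", sep="\t", index=False,
                           float_format="%.6g")
                enrich_tables[name] = enr
                manifest["counts"][f"enriched_sets_{name}"] = int(len(enr))

        stage = "correlate"
        corr_tables: dict[str, pd.DataFrame] = {}
        if config.clinical is not None:
            clinical = read_clinical_table(config.clinical)
            for name, de in de_tables.items():
                if name not in ("T1_vs_T0", "T2_vs_T0"):
                    continue  # biomarker panels are referenced to baseline
                de_genes = list(de.index[de["called"]])
                if not de_genes:
                    continue
                corr = correlate(quant, clinical, COMPARISONS[name], de_genes)
                corr.to_csv(out / f"correlations_{name}.tsv", sep="\t", index=False,
                            float_format="%.6g")
                corr_tables[name] = corr
                manifest["counts"][f"correlation_pairs_{name}"] = int(len(corr))
    except GclfqError as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return PipelineResult(
        capacities=caps,
        quant=quant,
        differential=de_tables,
        volcano=volcano_tables,
        enrichment=enrich_tables,
        correlations=corr_tables,
        manifest=manifest,
    )
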