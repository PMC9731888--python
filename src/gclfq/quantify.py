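"""Peptide-to-gene aggregation and iBAQ / iFOT abundance matrices.

One LC-MS run (= one sample) yields a table of peptide intensities (AUC,
area under the chromatographic peak).  Quantification proceeds gene-wise:

* ``total_auc``  — sum of AUC over the gene's uniquely assigned peptides,
* ``ibaq``       — total_auc / peptide_capacity (intensity per observable
  peptide, comparable across genes of different size),
* ``ifot``       — ibaq / sum of all genes' iBAQ in the same run
  (intensity-based fraction of total; comparable across runs),
* ``log_ifot``   — log2(ifot) where detected, NaN elsewhere.

Peptides shared between genes are dropped (and counted); no value is
imputed for undetected gene/sample cells — missingness propagates to the
paired analysis, which uses complete pairs only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .digestion import DigestionParams, GeneModel, gene_peptide_index
from .errors import ConfigError, InputError

logger = logging.getLogger(__name__)

TIMEPOINTS = ("T0_before", "T1_end", "T2_week_after")

PEPTIDE_COLUMNS = ["sample_id", "subject_id", "timepoint", "peptide_sequence", "auc"]
DESIGN_COLUMNS = ["sample_id", "subject_id", "timepoint"]


def _check_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"{what} is missing column(s): {', '.join(missing)}")


def read_peptide_table(path: str | Path) -> pd.DataFrame:
    """Read the long-form peptide measurement TSV and validate it."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"peptide table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str})
    validate_peptide_table(df)
    return df


def validate_peptide_table(df: pd.DataFrame) -> None:
    _check_columns(df, PEPTIDE_COLUMNS, "peptide table")
    if (df["auc"] < 0).any():
        bad = df.loc[df["auc"] < 0].index[0]
        raise InputError(f"negative AUC at row {bad}")
    unknown = set(df["timepoint"].unique()) - set(TIMEPOINTS)
    if unknown:
        raise InputError(f"unknown timepoint label(s): {sorted(unknown)}")
    # each sample must map to exactly one (subject, timepoint)
    per_sample = df.groupby("sample_id")[["subject_id", "timepoint"]].nunique()
    conflicted = per_sample[(per_sample > 1).any(axis=1)]
    if len(conflicted):
        raise InputError(
            f"sample(s) with conflicting subject/timepoint: {list(conflicted.index)}"
        )


def read_design(path: str | Path) -> pd.DataFrame:
    """Read the study design TSV (sample_id, subject_id, timepoint)."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"design file not found: {path}")
    design = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str})
    _check_columns(design, DESIGN_COLUMNS, "design table")
    if design["sample_id"].duplicated().any():
        raise InputError("design table has duplicate sample_id rows")
    unknown = set(design["timepoint"].unique()) - set(TIMEPOINTS)
    if unknown:
        raise InputError(f"unknown timepoint label(s) in design: {sorted(unknown)}")
    return design


def design_from_table(table: pd.DataFrame) -> pd.DataFrame:
    """Derive the design (sample -> subject, timepoint) from a peptide table."""
    return (
        table[DESIGN_COLUMNS]
        .drop_duplicates()
        .sort_values("sample_id")
        .reset_index(drop=True)
    )


@dataclass
class AssignmentReport:
    """Bookkeeping from peptide-to-gene assignment."""

    n_rows_in: int = 0
    n_rows_assigned: int = 0
    n_peptides_unique: int = 0
    n_peptides_shared: int = 0
    n_peptides_unassigned: int = 0
    shared_peptides: list[str] = field(default_factory=list)
    unassigned_peptides: list[str] = field(default_factory=list)


def assign_peptides_to_genes(
    table: pd.DataFrame,
    genes: Iterable[GeneModel],
    params: DigestionParams,
    *,
    razor: bool = False,
) -> tuple[pd.DataFrame, AssignmentReport]:
    """Annotate each measurement row with the gene its peptide belongs to.

    A peptide belongs to a gene when some isoform of the gene yields it as
    a digest span under ``params``.  Peptides matching exactly one gene are
    retained.  Shared peptides are dropped by default; with ``razor=True``
    they are instead given to the matching gene with the largest number of
    unique peptides in the table (ties broken by gene symbol).  Peptides
    matching no gene are reported and excluded.
    """
    validate_peptide_table(table)
    report = AssignmentReport(n_rows_in=len(table))
    if table.empty:
        logger.warning("empty peptide table: nothing to assign")
        out = table.copy()
        out["gene_symbol"] = pd.Series(dtype=str)
        return out, report

    index = gene_peptide_index(genes, params)
    peptides = table["peptide_sequence"].unique()

    unique_map: dict[str, str] = {}
    shared: dict[str, set[str]] = {}
    for pep in peptides:
        owners = index.get(pep)
        if owners is None:
            report.unassigned_peptides.append(pep)
        elif len(owners) == 1:
            unique_map[pep] = next(iter(owners))
        else:
            shared[pep] = owners
    report.n_peptides_unique = len(unique_map)
    report.n_peptides_shared = len(shared)
    report.n_peptides_unassigned = len(report.unassigned_peptides)
    report.shared_peptides = sorted(shared)

    if razor and shared:
        # razor: most unique peptides wins, alphabetical tie-break
        unique_counts: dict[str, int] = {}
        for gene in unique_map.values():
            unique_counts[gene] = unique_counts.get(gene, 0) + 1
        for pep, owners in shared.items():
            winner = min(owners, key=lambda g: (-unique_counts.get(g, 0), g))
            unique_map[pep] = winner
    elif shared:
        logger.info("dropping %d shared peptide(s)", len(shared))
    if report.unassigned_peptides:
        logger.info("%d peptide(s) matched no gene", len(report.unassigned_peptides))

    out = table.copy()
    out["gene_symbol"] = out["peptide_sequence"].map(unique_map)
    out = out.dropna(subset=["gene_symbol"]).reset_index(drop=True)
    report.n_rows_assigned = len(out)
    return out, report


def gene_total_auc(annotated: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Gene x sample matrix of summed AUC; absent combinations are 0."""
    _check_columns(annotated, ["gene_symbol", "sample_id", "auc"], "annotated table")
    samples = list(design["sample_id"])
    if annotated.empty:
        return pd.DataFrame(index=pd.Index([], name="gene_symbol"), columns=samples, dtype=float)
    mat = (
        annotated.pivot_table(
            index="gene_symbol", columns="sample_id", values="auc", aggfunc="sum", fill_value=0.0
        )
        .reindex(columns=samples, fill_value=0.0)
        .astype(float)
    )
    mat.index.name = "gene_symbol"
    return mat


def compute_ibaq(total_auc: pd.DataFrame, capacities: Mapping[str, float] | pd.Series) -> pd.DataFrame:
    """Divide each gene's AUC row by its peptide capacity."""
    capacities = pd.Series(capacities, dtype=float)
    missing = total_auc.index.difference(capacities.index)
    if len(missing):
        raise ConfigError(
            f"no peptide capacity for quantified gene(s): {sorted(missing)}"
        )
    caps = capacities.reindex(total_auc.index)
    if (caps <= 0).any():
        bad = list(caps.index[caps <= 0])
        raise ConfigError(f"non-positive capacity for gene(s): {bad}")
    return total_auc.div(caps, axis=0)


def compute_ifot(ibaq: pd.DataFrame) -> pd.DataFrame:
    """Per-sample fraction of total iBAQ; each column sums to 1."""
    totals = ibaq.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise InputError(f"sample(s) with zero total iBAQ: {list(zero.index)}")
    return ibaq.div(totals, axis=1)


def log_transform(ifot: pd.DataFrame, base: float = 2.0) -> pd.DataFrame:
    """log_base(ifot) where detected; undetected (0) cells become NaN."""
    with np.errstate(divide="ignore"):
        logged = np.log(ifot.to_numpy(dtype=float)) / np.log(base)
    logged[~(ifot.to_numpy() > 0)] = np.nan
    return pd.DataFrame(logged, index=ifot.index, columns=ifot.columns)


@dataclass
class GeneQuantMatrix:
    """Gene x sample abundance layers plus the design that produced them."""

    total_auc: pd.DataFrame
    ibaq: pd.DataFrame
    ifot: pd.DataFrame
    log_ifot: pd.DataFrame
    design: pd.DataFrame

    @property
    def detected(self) -> pd.DataFrame:
        return self.total_auc > 0

    @property
    def genes(self) -> pd.Index:
        return self.total_auc.index

    @property
    def samples(self) -> pd.Index:
        return self.total_auc.columns

    def to_tsv(self, path: str | Path) -> None:
        """Write all layers to one wide TSV with ``{sample}:{layer}`` columns."""
        layers = {
            "total_auc": self.total_auc,
            "ibaq": self.ibaq,
            "ifot": self.ifot,
            "log_ifot": self.log_ifot,
        }
        wide = pd.concat(
            {name: df for name, df in layers.items()}, axis=1
        )  # columns: (layer, sample)
        wide.columns = [f"{sample}:{layer}" for layer, sample in wide.columns]
        wide.insert(0, "gene_symbol", wide.index)
        wide.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, design: pd.DataFrame) -> "GeneQuantMatrix":
        path = Path(path)
        if not path.exists():
            raise InputError(f"quant matrix not found: {path}")
        wide = pd.read_csv(path, sep="\t").set_index("gene_symbol")
        layers: dict[str, dict[str, pd.Series]] = {}
        for col in wide.columns:
            sample, _, layer = col.rpartition(":")
            layers.setdefault(layer, {})[sample] = wide[col]
        frames = {name: pd.DataFrame(cols) for name, cols in layers.items()}
        return cls(
            total_auc=frames["total_auc"],
            ibaq=frames["ibaq"],
            ifot=frames["ifot"],
            log_ifot=frames["log_ifot"],
            design=design,
        )


def quantify(
    table: pd.DataFrame,
    genes: list[GeneModel],
    params: DigestionParams,
    design: pd.DataFrame | None = None,
    *,
    razor: bool = False,
) -> tuple[GeneQuantMatrix, AssignmentReport]:
    """Run the full peptide table -> GeneQuantMatrix aggregation."""
    if design is None:
        design = design_from_table(table)
    annotated, report = assign_peptides_to_genes(table, genes, params, razor=razor)
    total = gene_total_auc(annotated, design)
    caps = pd.Series(
        {g.gene_symbol: g.peptide_capacity for g in genes if g.peptide_capacity},
        dtype=float,
    )
    ibaq = compute_ibaq(total, caps)
    ifot = compute_ifot(ibaq)
    log_ifot = log_transform(ifot)
    logger.info(
        "quantified %d genes across %d samples (%d/%d rows assigned)",
        total.shape[0], total.shape[1], report.n_rows_assigned, report.n_rows_in,
    )
    return GeneQuantMatrix(total, ibaq, ifot, log_ifot, design), report
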