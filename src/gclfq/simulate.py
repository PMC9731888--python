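"""Synthetic proteome and peptide-level measurement generator.

The generator produces the inputs the analysis pipeline consumes — an
isoform FASTA and a long-form peptide AUC table with a paired design —
with the statistical structure the paired analysis assumes:

* 14 subjects, each sampled at three timepoints (before, end of, and one
  week after a 4-week intervention);
* per-gene baseline abundance drawn log-uniformly across more than six
  orders of magnitude on the iFOT scale;
* a per-(gene, subject) random effect (stable biology within a subject,
  which pairing removes) and per-cell Gaussian noise, both on log2 scale;
* a per-sample global intensity factor (instrument/loading variation,
  which iFOT normalization removes);
* spiked log2 effects on a subset of genes at the end-of-intervention
  timepoint, partially persisting one week after;
* abundance-dependent detection dropout (logistic in log10 abundance),
  producing not-detected patterns for low-abundance genes;
* gene abundance split across a handful of the gene's own digest peptides
  with Dirichlet weights, so that the signal lives at the gene level.

Everything is deterministic given (config, seed); the ground truth
(baselines, spiked effects per comparison, dropout pattern, subject
effects) is returned alongside the tables for parameter-recovery tests.

Note that iFOT is compositional (fractions of a per-sample total): a
spiked gene perturbs every gene's iFOT through the denominator by its own
share of the total.  With symmetric up/down spikes on a minority of genes
and no single gene dominating the total, this perturbation is small, but
recovered effects match spiked effects only up to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .digestion import (
    DigestionParams,
    GeneModel,
    ProteinIsoform,
    build_gene_models,
)
from .errors import InputError
from .quantify import TIMEPOINTS

# Approximate human proteome amino-acid frequencies (K/R together ~11%,
# giving realistic tryptic peptide counts).
_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_FREQ = np.array(
    [7.0, 2.3, 4.7, 7.1, 3.6, 6.6, 2.6, 4.3, 5.7, 10.0,
     2.1, 3.6, 6.3, 4.8, 5.6, 8.3, 5.3, 6.0, 1.2, 2.7]
)
_AA_FREQ = _AA_FREQ / _AA_FREQ.sum()

_TP_SHORT = {"T0_before": "T0", "T1_end": "T1", "T2_week_after": "T2"}


@dataclass
class SimulationConfig:
    """Study-design and noise parameters of the generator.

    Defaults emulate the profiled cohort: 14 paired subjects, ~900
    detectable gene products, iFOT-scale baselines spanning >6 orders of
    magnitude.  ``seed`` is mandatory: all randomness derives from it.
    """

    seed: int
    n_subjects: int = 14
    n_genes: int = 900
    isoforms_per_gene: tuple[int, int] = (1, 3)
    sequence_length: tuple[int, int] = (80, 600)
    baseline_log10_ifot_range: tuple[float, float] = (-7.5, -1.0)
    spike_fraction: float = 0.1
    spike_log2fc_values: tuple[float, ...] = (-3.0, -2.0, -1.0, 1.0, 2.0, 3.0)
    # Spiked genes are drawn from below this baseline (log10 iFOT): the
    # regulated fraction of a proteome is not its dominant mass, so the
    # per-run total (the iFOT denominator) stays stable under spiking.
    spike_max_baseline_log10: float = -3.5
    t2_carryover: float = 0.5  # fraction of the T1 effect persisting at T2
    noise_sd_log2: float = 0.5
    subject_sd_log2: float = 0.5
    sample_scale_sd_log2: float = 0.5
    dropout: bool = True
    dropout_midpoint_log10: float = -7.2
    dropout_slope: float = 2.5
    peptides_per_gene: int = 5
    total_intensity: float = 1e9
    digestion: DigestionParams = field(default_factory=DigestionParams)

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise InputError("n_subjects must be >= 2")
        if self.n_genes < 1:
            raise InputError("n_genes must be >= 1")
        lo, hi = self.baseline_log10_ifot_range
        if not lo < hi:
            raise InputError("baseline_log10_ifot_range must be a non-degenerate interval")
        if not 0.0 <= self.spike_fraction <= 1.0:
            raise InputError("spike_fraction must be in [0, 1]")
        if self.noise_sd_log2 < 0 or self.subject_sd_log2 < 0:
            raise InputError("noise/subject SDs must be non-negative")
        if self.spike_fraction > 0 and not self.spike_log2fc_values:
            raise InputError("spike_fraction > 0 requires spike_log2fc_values")

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if seed is not None:
            raw["seed"] = seed
        if "seed" not in raw:
            raise InputError("simulation config requires a seed")
        if "digestion" in raw and isinstance(raw["digestion"], dict):
            raw["digestion"] = DigestionParams(**raw["digestion"])
        for key in ("isoforms_per_gene", "sequence_length",
                    "baseline_log10_ifot_range", "spike_log2fc_values"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SimulationTruth:
    """Ground truth behind one simulated dataset."""

    baseline_log10_ifot: pd.Series  # per gene
    spiked: pd.Series  # bool per gene
    effects: pd.DataFrame  # gene x comparison true log2 effects
    subject_effects: pd.DataFrame  # gene x subject
    detected: pd.DataFrame  # gene x sample detection indicators
    log2_abundance: pd.DataFrame  # gene x sample, pre-dropout
    peptide_weights: pd.DataFrame  # rows: gene_symbol, peptide_sequence, weight
    design: pd.DataFrame

    def to_tsv(self, path: str | Path) -> None:
        out = pd.DataFrame(
            {
                "gene_symbol": self.baseline_log10_ifot.index,
                "baseline_log10_ifot": self.baseline_log10_ifot.to_numpy(),
                "spiked": self.spiked.to_numpy(),
            }
        )
        for comp in self.effects.columns:
            out[f"effect_{comp}"] = self.effects[comp].to_numpy()
        out.to_csv(path, sep="\t", index=False)


def _gene_labels(n_genes: int) -> tuple[list[str], list[str]]:
    width = max(4, len(str(n_genes)))
    symbols = [f"G{i + 1:0{width}d}" for i in range(n_genes)]
    gene_ids = [str(100000 + i + 1) for i in range(n_genes)]
    return symbols, gene_ids


def generate_proteome(config: SimulationConfig) -> list[ProteinIsoform]:
    """Random isoform sequences with realistic K/R content.

    Deterministic given the config seed; every sequence passes isoform
    validation and sequences are generated per gene so downstream digests
    yield workable peptide sets.
    """
    rng = np.random.default_rng([config.seed, 0])
    symbols, gene_ids = _gene_labels(config.n_genes)
    lo_iso, hi_iso = config.isoforms_per_gene
    lo_len, hi_len = config.sequence_length
    aa = np.array(list(_AA))
    isoforms: list[ProteinIsoform] = []
    for symbol, gid in zip(symbols, gene_ids):
        n_iso = int(rng.integers(lo_iso, hi_iso + 1))
        for j in range(n_iso):
            length = int(rng.integers(lo_len, hi_len + 1))
            seq = "".join(rng.choice(aa, size=length, p=_AA_FREQ))
            isoforms.append(ProteinIsoform(f"{symbol}.{j + 1}", symbol, gid, seq))
    return isoforms


def write_fasta(isoforms: Sequence[ProteinIsoform], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iso in isoforms:
            fh.write(f">{iso.isoform_id} GN={iso.gene_symbol} GID={iso.gene_id}\n")
            seq = iso.sequence
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def make_design(config: SimulationConfig) -> pd.DataFrame:
    subjects = [f"S{i + 1:02d}" for i in range(config.n_subjects)]
    rows = [
        {"sample_id": f"{subj}_{_TP_SHORT[tp]}", "subject_id": subj, "timepoint": tp}
        for subj in subjects
        for tp in TIMEPOINTS
    ]
    return pd.DataFrame(rows)


def _spike_effects(
    baseline_log10: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """(spiked indicator, per-gene T1 effect) arrays.

    Spiked genes are drawn only from those with baseline below
    ``spike_max_baseline_log10`` (see SimulationConfig)."""
    n_genes = baseline_log10.size
    n_spiked = int(round(config.spike_fraction * n_genes))
    if n_spiked > n_genes:
        raise InputError("more spiked genes requested than n_genes")
    eligible = np.nonzero(baseline_log10 < config.spike_max_baseline_log10)[0]
    if n_spiked > eligible.size:
        raise InputError(
            f"only {eligible.size} genes below spike_max_baseline_log10="
            f"{config.spike_max_baseline_log10}, cannot spike {n_spiked}"
        )
    spiked_idx = rng.choice(eligible, size=n_spiked, replace=False)
    effects = np.zeros(n_genes)
    if n_spiked:
        effects[spiked_idx] = rng.choice(
            np.asarray(config.spike_log2fc_values, dtype=float), size=n_spiked
        )
    spiked = np.zeros(n_genes, dtype=bool)
    spiked[spiked_idx] = True
    return spiked, effects


def simulate_peptide_measurements(
    config: SimulationConfig, isoforms: Sequence[ProteinIsoform] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Generate (peptide table, design, truth) for one simulated study.

    When ``isoforms`` is omitted the proteome is generated from the same
    config.  Genes whose digest yields no peptide under the configured
    parameters are silently absent from the measurement table (they have
    no observable peptides), but remain in the truth.
    """
    if isoforms is None:
        isoforms = generate_proteome(config)
    rng = np.random.default_rng([config.seed, 1])
    design = make_design(config)
    samples = design["sample_id"].to_numpy()
    subjects = design["subject_id"].unique()
    n_samples = len(samples)

    genes: list[GeneModel] = build_gene_models(isoforms, config.digestion)
    symbols = [g.gene_symbol for g in genes]
    n_genes = len(symbols)
    if n_genes == 0:
        raise InputError("no gene yields peptides under the digestion parameters")

    # --- gene-level truth -------------------------------------------------
    lo, hi = config.baseline_log10_ifot_range
    baseline_log10 = rng.uniform(lo, hi, size=n_genes)
    spiked, t1_effect = _spike_effects(baseline_log10, config, rng)
    t2_effect = config.t2_carryover * t1_effect
    effects = pd.DataFrame(
        {
            "T1_vs_T0": t1_effect,
            "T2_vs_T0": t2_effect,
            "T2_vs_T1": t2_effect - t1_effect,
        },
        index=pd.Index(symbols, name="gene_symbol"),
    )

    subj_eff = rng.normal(0.0, config.subject_sd_log2, size=(n_genes, len(subjects)))
    subj_eff_df = pd.DataFrame(subj_eff, index=symbols, columns=subjects)

    # --- per-sample log2 abundance ---------------------------------------
    tp_of_sample = design["timepoint"].to_numpy()
    subj_of_sample = design["subject_id"].to_numpy()
    subj_pos = {s: i for i, s in enumerate(subjects)}
    log2_ab = np.empty((n_genes, n_samples))
    log2_10 = np.log2(10.0)
    for j in range(n_samples):
        tp = tp_of_sample[j]
        eff = np.zeros(n_genes)
        if tp == "T1_end":
            eff = t1_effect
        elif tp == "T2_week_after":
            eff = t2_effect
        noise = rng.normal(0.0, config.noise_sd_log2, size=n_genes)
        log2_ab[:, j] = (
            baseline_log10 * log2_10
            + subj_eff[:, subj_pos[subj_of_sample[j]]]
            + eff
            + noise
        )

    # --- detection dropout ------------------------------------------------
    if config.dropout:
        log10_ab = log2_ab / log2_10
        p_detect = expit(config.dropout_slope * (log10_ab - config.dropout_midpoint_log10))
        detected = rng.uniform(size=p_detect.shape) < p_detect
    else:
        detected = np.ones_like(log2_ab, dtype=bool)

    # --- distribute gene AUC across digest peptides -----------------------
    scale = 2.0 ** rng.normal(0.0, config.sample_scale_sd_log2, size=n_samples)
    pep_rows = []
    weight_rows = []
    from .digestion import enumerate_peptides  # local import avoids cycle at module load

    for gi, gene in enumerate(genes):
        pool = sorted(
            {s.sequence for iso in gene.isoforms
             for s in enumerate_peptides(iso.sequence, config.digestion)}
        )
        k = min(config.peptides_per_gene, len(pool))
        chosen = list(rng.choice(pool, size=k, replace=False))
        weights = rng.dirichlet(np.ones(k))
        for pep, w in zip(chosen, weights):
            weight_rows.append(
                {"gene_symbol": gene.gene_symbol, "peptide_sequence": pep, "weight": w}
            )
        gene_auc = (
            2.0 ** log2_ab[gi]
            * detected[gi]
            * gene.peptide_capacity
            * scale
            * config.total_intensity
        )
        for j in np.nonzero(detected[gi])[0]:
            for pep, w in zip(chosen, weights):
                pep_rows.append(
                    (samples[j], subj_of_sample[j], tp_of_sample[j], pep, gene_auc[j] * w)
                )

    table = pd.DataFrame(
        pep_rows, columns=["sample_id", "subject_id", "timepoint", "peptide_sequence", "auc"]
    )
    truth = SimulationTruth(
        baseline_log10_ifot=pd.Series(baseline_log10, index=symbols, name="baseline_log10_ifot"),
        spiked=pd.Series(spiked, index=symbols, name="spiked"),
        effects=effects,
        subject_effects=subj_eff_df,
        detected=pd.DataFrame(detected, index=symbols, columns=samples),
        log2_abundance=pd.DataFrame(log2_ab, index=symbols, columns=samples),
        peptide_weights=pd.DataFrame(weight_rows),
        design=design,
    )
    return table, design, truth


def asdict_shallow(config: SimulationConfig) -> dict:
    """Config as a dict without recursing into DigestionParams."""
    out = {f: getattr(config, f) for f in config.__dataclass_fields__}
    return out


def simulate_clinical(
    config: SimulationConfig,
    truth: SimulationTruth,
    n_parameters: int = 6,
    slope: float = 0.6,
    clinical_noise_sd_log2: float = 0.4,
) -> pd.DataFrame:
    """Clinical biomarker values correlated with spiked-gene fold changes.

    Each parameter tracks one spiked gene: the subject's log2 biomarker
    fold change between timepoints is ``slope`` times the gene's realized
    per-subject log2 abundance change plus noise.  Parameters beyond the
    number of spiked genes are pure noise.  Values are positive
    (baseline 100 on an arbitrary unit scale).
    """
    rng = np.random.default_rng([config.seed, 2])
    design = truth.design
    subjects = design["subject_id"].unique()
    spiked_genes = list(truth.spiked.index[truth.spiked])
    rows = []
    sample_of = design.set_index(["subject_id", "timepoint"])["sample_id"]
    for p in range(n_parameters):
        name = f"biomarker_{p + 1:02d}"
        gene = spiked_genes[p] if p < len(spiked_genes) else None
        for subj in subjects:
            base = 100.0 * 2.0 ** rng.normal(0.0, 0.5)
            values = {"T0_before": base}
            for tp in ("T1_end", "T2_week_after"):
                if gene is not None:
                    s0 = sample_of[(subj, "T0_before")]
                    s1 = sample_of[(subj, tp)]
                    gene_delta = (
                        truth.log2_abundance.at[gene, s1]
                        - truth.log2_abundance.at[gene, s0]
                    )
                else:
                    gene_delta = 0.0
                fold = slope * gene_delta + rng.normal(0.0, clinical_noise_sd_log2)
                values[tp] = base * 2.0 ** fold
            for tp, val in values.items():
                rows.append(
                    {"subject_id": subj, "parameter_name": name,
                     "timepoint": tp, "value": val}
                )
    return pd.DataFrame(rows)


def write_bundle(
    config: SimulationConfig,
    out_dir: str | Path,
    *,
    clinical: bool = True,
) -> dict[str, Path]:
    """Generate a full synthetic study and write it under ``out_dir``.

    Writes proteome.fa, peptides.tsv, design.tsv, truth.tsv and
    (optionally) clinical.tsv; returns the paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    isoforms = generate_proteome(config)
    table, design, truth = simulate_peptide_measurements(config, isoforms)
    paths = {
        "proteome": out_dir / "proteome.fa",
        "peptides": out_dir / "peptides.tsv",
        "design": out_dir / "design.tsv",
        "truth": out_dir / "truth.tsv",
    }
    write_fasta(isoforms, paths["proteome"])
    table.to_csv(paths["peptides"], sep="\t", index=False)
    design.to_csv(paths["design"], sep="\t", index=False)
    truth.to_tsv(paths["truth"])
    if clinical:
        paths["clinical"] = out_dir / "clinical.tsv"
        simulate_clinical(config, truth).to_csv(paths["clinical"], sep="\t", index=False)
    return paths
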