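"""Paired three-timepoint differential expression on log2 iFOT.

Each subject contributes one sample per timepoint (T0 = before the
intervention, T1 = end of the 4-week intervention, T2 = one week after).
For a comparison num-vs-den, the per-gene effect is the mean over subjects
of the per-subject difference log2(iFOT_num) - log2(iFOT_den), computed on
subjects where the gene is detected at BOTH timepoints (complete pairs; no
imputation).  Significance is a classical paired two-tailed t-test on the
same differences.  A gene is *called* differential when
|avg_paired_log2fc| >= log2(1.5) ~= 0.585 (inclusive) and P < 0.05
(strict) and it has at least ``min_pairs`` complete pairs.

Linear folds are reported the way the source tables print them:
round(2^|log2fc|) to the nearest integer, half away from zero, with the
direction carried by the sign of the log2 value.

No multiple-testing correction enters the calling rule; a
Benjamini-Hochberg q-value column is emitted for information only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError
from .quantify import TIMEPOINTS, GeneQuantMatrix


@dataclass(frozen=True)
class Comparison:
    name: str
    numerator: str  # timepoint whose increase gives positive fold change
    denominator: str

    def __post_init__(self) -> None:
        if self.numerator == self.denominator:
            raise InputError("comparison numerator and denominator must differ")
        for tp in (self.numerator, self.denominator):
            if tp not in TIMEPOINTS:
                raise InputError(f"unknown timepoint {tp!r}")

    def swapped(self) -> "Comparison":
        return Comparison(
            f"{self.denominator}_vs_{self.numerator}", self.denominator, self.numerator
        )


COMPARISONS: dict[str, Comparison] = {
    "T1_vs_T0": Comparison("T1_vs_T0", "T1_end", "T0_before"),
    "T2_vs_T0": Comparison("T2_vs_T0", "T2_week_after", "T0_before"),
    "T2_vs_T1": Comparison("T2_vs_T1", "T2_week_after", "T1_end"),
}


@dataclass(frozen=True)
class Thresholds:
    """Calling rule: >=1.5-fold average paired change and P < alpha."""

    log2fc_min: float = 0.585
    alpha: float = 0.05
    min_pairs: int = 3

    def __post_init__(self) -> None:
        if self.log2fc_min <= 0:
            raise InputError("log2fc_min must be positive")
        if not (0 < self.alpha < 1):
            raise InputError("alpha must be in (0, 1)")


def _paired_differences(
    log_ifot: pd.DataFrame, design: pd.DataFrame, comparison: Comparison
) -> pd.DataFrame:
    """Gene x subject matrix of per-subject log2 differences (NaN where a
    timepoint is missing or undetected)."""
    def samples_at(tp: str) -> pd.Series:
        sub = design[design["timepoint"] == tp]
        if sub["subject_id"].duplicated().any():
            dup = sub.loc[sub["subject_id"].duplicated(), "subject_id"].iloc[0]
            raise InputError(f"subject {dup} has multiple samples at {tp}")
        return sub.set_index("subject_id")["sample_id"]

    num = samples_at(comparison.numerator)
    den = samples_at(comparison.denominator)
    subjects = num.index.intersection(den.index)
    num_mat = log_ifot.reindex(columns=num.loc[subjects])
    den_mat = log_ifot.reindex(columns=den.loc[subjects])
    diffs = num_mat.to_numpy() - den_mat.to_numpy()
    return pd.DataFrame(diffs, index=log_ifot.index, columns=subjects)


def paired_log2_fold_change(
    log_ifot: pd.DataFrame, design: pd.DataFrame, comparison: Comparison
) -> pd.DataFrame:
    """Average paired log2 fold change and pair count per gene.

    Genes with no complete pair get NaN fold change and n_pairs = 0.
    """
    diffs = _paired_differences(log_ifot, design, comparison)
    n_pairs = diffs.notna().sum(axis=1)
    avg = diffs.mean(axis=1, skipna=True)
    avg[n_pairs == 0] = np.nan
    return pd.DataFrame({"avg_paired_log2fc": avg, "n_pairs": n_pairs.astype(int)})


def paired_t_test(
    log_ifot: pd.DataFrame, design: pd.DataFrame, comparison: Comparison
) -> pd.Series:
    """Two-tailed paired t-test P value per gene.

    Conventions for degenerate inputs: fewer than two complete pairs ->
    NaN; zero variance of the differences with zero mean -> P = 1 (no
    evidence of change); zero variance with nonzero mean -> NaN (the t
    statistic is undefined).
    """
    diffs = _paired_differences(log_ifot, design, comparison)
    pvals = pd.Series(np.nan, index=diffs.index, name="p_value")
    arr = diffs.to_numpy()
    for i, gene in enumerate(diffs.index):
        d = arr[i]
        d = d[~np.isnan(d)]
        if d.size < 2:
            continue
        if np.ptp(d) == 0.0:
            pvals.iloc[i] = 1.0 if d[0] == 0.0 else np.nan
            continue
        res = stats.ttest_1samp(d, 0.0, alternative="two-sided")
        pvals.iloc[i] = res.pvalue
    return pvals


def nd_status(quant: GeneQuantMatrix, comparison: Comparison) -> pd.Series:
    """True when no subject has the gene detected at both timepoints."""
    diffs = _paired_differences(quant.log_ifot, quant.design, comparison)
    return diffs.isna().all(axis=1).rename("nd")


def call_differential(
    fc: pd.DataFrame, pvals: pd.Series, thresholds: Thresholds = Thresholds()
) -> pd.DataFrame:
    """Apply the fold-change + P-value calling rule.

    The fold-change threshold is inclusive (>= 0.585) and the alpha strict
    (< 0.05), mirroring the ">= 1.5-fold and P < 0.05" convention.
    """
    out = fc.copy()
    out["p_value"] = pvals.reindex(out.index)
    called = (
        (out["avg_paired_log2fc"].abs() >= thresholds.log2fc_min)
        & (out["p_value"] < thresholds.alpha)
        & (out["n_pairs"] >= thresholds.min_pairs)
    ).fillna(False)
    out["called"] = called
    direction = np.where(
        ~called, "none", np.where(out["avg_paired_log2fc"] > 0, "up", "down")
    )
    out["direction"] = direction
    return out


def linear_fold_from_log2(x: float) -> int:
    """Printed linear fold for a log2 fold change: round(2^|x|), half away
    from zero; direction is carried separately by the sign of ``x``."""
    if not math.isfinite(x):
        raise InputError("log2 fold change must be finite")
    return int(math.floor(2.0 ** abs(x) + 0.5))


def differential_table(
    quant: GeneQuantMatrix,
    comparison: Comparison,
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Full per-gene differential result for one comparison.

    Columns: gene_symbol (index), comparison, avg_paired_log2fc,
    linear_fold, p_value, n_pairs, called, direction, nd, bh_q.
    """
    fc = paired_log2_fold_change(quant.log_ifot, quant.design, comparison)
    pvals = paired_t_test(quant.log_ifot, quant.design, comparison)
    out = call_differential(fc, pvals, thresholds)
    out.insert(0, "comparison", comparison.name)
    out["nd"] = nd_status(quant, comparison)
    out.loc[out["nd"], "called"] = False
    out["linear_fold"] = [
        linear_fold_from_log2(x) if np.isfinite(x) else np.nan
        for x in out["avg_paired_log2fc"]
    ]
    # BH q-values for information only; the calling rule uses raw P.
    valid = out["p_value"].notna()
    out["bh_q"] = np.nan
    if valid.any():
        out.loc[valid, "bh_q"] = multipletests(
            out.loc[valid, "p_value"].to_numpy(), method="fdr_bh"
        )[1]
    cols = [
        "comparison", "avg_paired_log2fc", "linear_fold", "p_value",
        "n_pairs", "called", "direction", "nd", "bh_q",
    ]
    return out[cols]


def volcano_table(results: pd.DataFrame) -> pd.DataFrame:
    """Volcano coordinates: x = avg_paired_log2fc, y = -log10 P, with the
    called/direction strata used for colouring.  Genes lacking a defined
    fold change or P value are omitted."""
    ok = results["avg_paired_log2fc"].notna() & results["p_value"].notna()
    sub = results.loc[ok]
    return pd.DataFrame(
        {
            "x": sub["avg_paired_log2fc"],
            "y": -np.log10(sub["p_value"]),
            "called": sub["called"],
            "direction": sub["direction"],
        },
        index=sub.index,
    )


def volcano_plot(results: pd.DataFrame, path: str | Path, title: str = "") -> None:
    """Save a volcano scatter (down = blue, up = red, rest grey) as PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tab = volcano_table(results)
    fig, ax = plt.subplots(figsize=(5, 4))
    rest = tab[~tab["called"]]
    ax.scatter(rest["x"], rest["y"], s=8, c="0.7", label="not called")
    for direction, colour in (("down", "tab:blue"), ("up", "tab:red")):
        sub = tab[tab["called"] & (tab["direction"] == direction)]
        ax.scatter(sub["x"], sub["y"], s=12, c=colour, label=direction)
    ax.set_xlabel("average paired log2 fold change")
    ax.set_ylabel("-log10 P")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Packaged reference table


def load_reference_differential() -> pd.DataFrame:
    """Load the packaged reference table of printed differential results
    (long form: gene_symbol, gene_id, comparison, avg_paired_log2fc,
    p_value; 'ND' cells appear as NaN)."""
    with resources.files("gclfq.fixtures").joinpath("table1.tsv").open() as fh:
        wide = pd.read_csv(fh, sep="\t", na_values=["ND"])
    records = []
    for comp in ("T1_vs_T0", "T2_vs_T1", "T2_vs_T0"):
        sub = wide[["gene_symbol", "gene_id", f"log2fc_{comp}", f"p_{comp}"]].copy()
        sub.columns = ["gene_symbol", "gene_id", "avg_paired_log2fc", "p_value"]
        sub.insert(2, "comparison", comp)
        records.append(sub)
    return pd.concat(records, ignore_index=True)
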