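"""Correlation of protein fold changes with clinical biomarker fold changes.

For a timepoint comparison, each subject has a log2 fold change per
differentially expressed gene (from paired log2 iFOT differences) and per
clinical parameter (log2 ratio of the measured values).  Pearson's r is
computed per (gene, parameter) over the subjects with both quantities
defined (pairwise-complete, no imputation), with a two-tailed P from the
exact t transform t = r * sqrt((n-2)/(1-r^2)), df = n-2.

Degenerate cases: fewer than 3 complete subjects -> the pair is skipped;
zero variance in either vector -> r undefined (NaN, flagged); |r| = 1 ->
P reported as 0 with a degeneracy flag.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .differential import Comparison, _paired_differences
from .errors import InputError
from .quantify import TIMEPOINTS, GeneQuantMatrix

logger = logging.getLogger(__name__)

CLINICAL_COLUMNS = ["subject_id", "parameter_name", "timepoint", "value"]


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"clinical table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"clinical table is missing column(s): {', '.join(missing)}")
    unknown = set(df["timepoint"].unique()) - set(TIMEPOINTS)
    if unknown:
        raise InputError(f"unknown timepoint label(s) in clinical table: {sorted(unknown)}")
    dup = df.duplicated(subset=["subject_id", "parameter_name", "timepoint"])
    if dup.any():
        raise InputError("clinical table has duplicate (subject, parameter, timepoint) rows")
    return df


def subject_fold_changes(clinical: pd.DataFrame, comparison: Comparison) -> pd.DataFrame:
    """Subject x parameter matrix of log2(value_num / value_den).

    Subjects missing either timepoint, or with a non-positive value, are
    excluded for that parameter (NaN) and logged.
    """
    pivot = clinical.pivot_table(
        index="subject_id",
        columns=["parameter_name", "timepoint"],
        values="value",
        aggfunc="first",
    )
    params = sorted({p for p, _ in pivot.columns})
    out = pd.DataFrame(index=pivot.index, columns=params, dtype=float)
    for param in params:
        for tp in (comparison.numerator, comparison.denominator):
            if (param, tp) not in pivot.columns:
                pivot[(param, tp)] = np.nan
        num = pivot[(param, comparison.numerator)]
        den = pivot[(param, comparison.denominator)]
        bad = ((num <= 0) | (den <= 0)) & num.notna() & den.notna()
        if bad.any():
            logger.info(
                "parameter %s: excluding %d subject(s) with non-positive values",
                param, int(bad.sum()),
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = np.log2(num / den)
        fc[bad | num.isna() | den.isna()] = np.nan
        out[param] = fc
    return out


def gene_subject_fold_changes(
    quant: GeneQuantMatrix, comparison: Comparison, genes: list[str] | None = None
) -> pd.DataFrame:
    """Subject x gene matrix of per-subject paired log2 iFOT differences."""
    diffs = _paired_differences(quant.log_ifot, quant.design, comparison)
    if genes is not None:
        diffs = diffs.reindex(index=genes)
    return diffs.T  # subjects x genes


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    """(r, two-tailed P, degenerate flag) with the conventions above."""
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return np.nan, np.nan, True
    r, _ = stats.pearsonr(x, y)
    r = float(np.clip(r, -1.0, 1.0))
    n = x.size
    if abs(r) == 1.0:
        return r, 0.0, True
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p), False


def pearson_fold_correlation(
    gp_folds: pd.DataFrame, clinical_folds: pd.DataFrame, min_subjects: int = 3
) -> pd.DataFrame:
    """Pearson correlation per (gene, parameter) pair of subject fold changes.

    Both inputs are subject x variable matrices; subjects are matched by
    index, pairwise-complete per pair.  Pairs with fewer than
    ``min_subjects`` complete subjects are skipped.
    """
    subjects = gp_folds.index.intersection(clinical_folds.index)
    gp = gp_folds.loc[subjects]
    clin = clinical_folds.loc[subjects]
    rows = []
    for gene in gp.columns:
        gvec = gp[gene]
        for param in clin.columns:
            cvec = clin[param]
            ok = gvec.notna() & cvec.notna()
            n = int(ok.sum())
            if n < min_subjects:
                continue
            r, p, degenerate = _pearson(gvec[ok].to_numpy(), cvec[ok].to_numpy())
            rows.append(
                {"gene_symbol": gene, "parameter_name": param, "r": r,
                 "p_value": p, "n": n, "degenerate": degenerate}
            )
    out = pd.DataFrame(
        rows, columns=["gene_symbol", "parameter_name", "r", "p_value", "n", "degenerate"]
    )
    valid = out["p_value"].notna() if len(out) else pd.Series(dtype=bool)
    out["bh_q"] = np.nan
    if len(out) and valid.any():
        out.loc[valid, "bh_q"] = multipletests(
            out.loc[valid, "p_value"].to_numpy(), method="fdr_bh"
        )[1]
    return out


def correlate(
    quant: GeneQuantMatrix,
    clinical: pd.DataFrame,
    comparison: Comparison,
    de_genes: list[str],
    min_subjects: int = 3,
) -> pd.DataFrame:
    """Correlate DE-gene fold changes with clinical fold changes."""
    gp = gene_subject_fold_changes(quant, comparison, genes=de_genes)
    clin = subject_fold_changes(clinical, comparison)
    out = pearson_fold_correlation(gp, clin, min_subjects=min_subjects)
    out.insert(2, "comparison", comparison.name)
    return out
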