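"""Gene-set over-representation analysis (ORA stand-in).

Given the list of differentially expressed genes and a collection of gene
sets (GMT), each set is scored with the upper-tail hypergeometric test:
with N background genes, K of which belong to the set, and n differential
genes, the P value is the probability of drawing >= k set members in n
draws without replacement.  Results report the "k differential / K set
genes" ratio alongside the P value.

This is a transparent stand-in for proprietary pathway impact-analysis
tools: it ranks sets by overlap only and knows nothing about topology.
Outputs are labelled accordingly.

Gene symbols are matched case-insensitively after whitespace stripping;
set members are intersected with the background (by default, all
quantified genes) before testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError

logger = logging.getLogger(__name__)

METHOD_LABEL = "hypergeometric ORA stand-in"


def _norm(symbol: str) -> str:
    return symbol.strip().upper()


@dataclass
class GeneSetCollection:
    """Named gene sets plus the background universe they are tested against."""

    sets: dict[str, set[str]]
    background: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.sets = {name: {_norm(g) for g in members} for name, members in self.sets.items()}
        self.background = {_norm(g) for g in self.background}

    def restricted(self) -> dict[str, set[str]]:
        """Sets intersected with the background; empty sets dropped."""
        out = {}
        for name, members in self.sets.items():
            inter = members & self.background
            if inter:
                out[name] = inter
        return out


def read_gmt(path: str | Path, background: Iterable[str]) -> GeneSetCollection:
    """Read a standard GMT file (set name, description, then genes)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"GMT file not found: {path}")
    sets: dict[str, set[str]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, _description, *genes = fields
            sets[name] = {g for g in genes if g.strip()}
    return GeneSetCollection(sets=sets, background=set(background))


def over_representation(
    de_genes: Iterable[str], collection: GeneSetCollection
) -> pd.DataFrame:
    """Hypergeometric upper-tail test of each set against the DE list.

    Returns one row per set: k (overlap), K (set size within background),
    n (DE genes), N (background size), ratio "k/K", p_value, bh_q; sorted
    by P value.
    """
    de = {_norm(g) for g in de_genes}
    outside = de - collection.background
    if outside:
        raise InputError(
            f"differential gene(s) not in background: {sorted(outside)[:5]}"
        )
    if not de:
        logger.warning("empty differential gene list: no enrichment computed")
        return pd.DataFrame(
            columns=["set_name", "k", "K", "n", "N", "ratio", "p_value", "bh_q"]
        )
    N = len(collection.background)
    n = len(de)
    rows = []
    for name, members in collection.restricted().items():
        K = len(members)
        k = len(de & members)
        # P(X >= k) for X ~ Hypergeom(N, K, n); sf(k-1) is the upper tail
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {"set_name": name, "k": k, "K": K, "n": n, "N": N,
             "ratio": f"{k}/{K}", "p_value": min(p, 1.0)}
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["bh_q"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
        out = out.sort_values("p_value", kind="mergesort").reset_index(drop=True)
    else:
        out["bh_q"] = np.nan
    return out
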