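"""Independent oracles shared by the unit and acceptance suites.

These deliberately re-derive results from first principles (substring
enumeration, exhaustive draws) rather than calling the implementation
paths they check.
"""

from __future__ import annotations

from itertools import combinations


def oracle_cleavage_sites(sequence: str, lysc: bool = False) -> set[int]:
    """Cut positions derived directly from the K/R-not-before-P rule."""
    sites = set()
    for i in range(len(sequence) - 1):
        if sequence[i] == "R" and sequence[i + 1] != "P":
            sites.add(i)
        elif sequence[i] == "K" and (sequence[i + 1] != "P" or lysc):
            sites.add(i)
    return sites


def oracle_peptide_spans(
    sequence: str,
    max_missed: int,
    min_len: int,
    max_len: int,
    lysc: bool = False,
) -> set[tuple[int, int]]:
    """Brute force: test every substring for being bounded by cleavage
    sites or termini and containing at most ``max_missed`` internal sites."""
    n = len(sequence)
    sites = oracle_cleavage_sites(sequence, lysc)
    spans = set()
    for i in range(n):
        for j in range(i + 1, n + 1):
            if not (min_len <= j - i <= max_len):
                continue
            if i != 0 and (i - 1) not in sites:
                continue
            if j != n and (j - 1) not in sites:
                continue
            internal = sum(1 for p in sites if i <= p < j - 1)
            if internal <= max_missed:
                spans.add((i, j))
    return spans


def oracle_overrepresentation_p(N: int, K: int, n: int, k: int) -> float:
    """Exhaustively enumerate all C(N, n) draws of the differential list and
    count those overlapping the set by >= k members.  Feasible for N <= 12."""
    population = list(range(N))
    in_set = set(range(K))
    total = 0
    hits = 0
    for draw in combinations(population, n):
        total += 1
        if len(in_set.intersection(draw)) >= k:
            hits += 1
    return hits / total
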