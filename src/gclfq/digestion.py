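"""In-silico proteolytic digestion and gene-level peptide capacity.

The quantification scheme used downstream (gene-centric iBAQ) divides a
gene's summed peptide intensity by its *peptide capacity*: the average
number of theoretically observable tryptic peptides with at most one missed
cleavage, taken across all protein isoforms annotated to the gene.  This
module computes that denominator from isoform sequences.

Cleavage rules
--------------
``trypsin``
    Cleaves C-terminally of K or R, except when the next residue is P.
``trypsin_lysC``
    As trypsin, but K|P is additionally cleaved (Lys-C is insensitive to
    proline at P1').

Peptides are counted as distinct (start, end) spans: two identical
sequences occurring at different positions in one isoform count twice,
since each position contributes an observable peptide.  'X' (unknown
residue) is accepted in sequences but never forms a cleavage site.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

from .errors import CapacityUndefinedError, InputError

ALLOWED_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class ProteaseRule(str, Enum):
    TRYPSIN = "trypsin"
    TRYPSIN_LYSC = "trypsin_lysC"


def _validate_sequence(sequence: str) -> None:
    if not sequence:
        raise InputError("protein sequence is empty")
    for i, aa in enumerate(sequence):
        if aa not in ALLOWED_RESIDUES:
            raise InputError(
                f"invalid residue {aa!r} at position {i} "
                f"(allowed: 20 canonical amino acids plus X)"
            )


@dataclass(frozen=True)
class ProteinIsoform:
    """One protein isoform sequence annotated to a gene."""

    isoform_id: str
    gene_symbol: str
    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        _validate_sequence(self.sequence)


@dataclass(frozen=True)
class DigestionParams:
    """Digestion settings used both for capacity and peptide-to-gene mapping.

    The capacity convention is <=1 missed cleavage ("singly miscut"); the
    length window 6-30 aa is the default MS-observable range and is
    configurable.
    """

    protease_rule: ProteaseRule = ProteaseRule.TRYPSIN
    max_missed_cleavages: int = 1
    min_peptide_length: int = 6
    max_peptide_length: int = 30

    def __post_init__(self) -> None:
        if self.max_missed_cleavages < 0:
            raise InputError("max_missed_cleavages must be >= 0")
        if not (1 <= self.min_peptide_length <= self.max_peptide_length):
            raise InputError(
                "need 1 <= min_peptide_length <= max_peptide_length, got "
                f"{self.min_peptide_length}..{self.max_peptide_length}"
            )


@dataclass
class GeneModel:
    """A gene with its isoforms; capacity is filled in by
    :func:`gene_peptide_capacity` or :func:`build_gene_models`."""

    gene_symbol: str
    gene_id: str
    isoforms: list[ProteinIsoform] = field(default_factory=list)
    peptide_capacity: float | None = None


@dataclass(frozen=True)
class PeptideSpan:
    """A digest peptide as a positional span within one isoform."""

    start: int  # 0-based inclusive
    end: int  # exclusive
    missed_cleavages: int
    sequence: str


def find_cleavage_sites(sequence: str, protease_rule: ProteaseRule = ProteaseRule.TRYPSIN) -> list[int]:
    """Return 0-based indices of residues after which the protease cuts.

    The terminal residue never yields a site (there is nothing to cleave
    off).  For the plain trypsin rule a K/R followed by P is protected; the
    trypsin/Lys-C rule keeps K|P cleavable.
    """
    _validate_sequence(sequence)
    rule = ProteaseRule(protease_rule)
    sites: list[int] = []
    for i in range(len(sequence) - 1):
        aa = sequence[i]
        if aa == "K":
            if sequence[i + 1] != "P" or rule is ProteaseRule.TRYPSIN_LYSC:
                sites.append(i)
        elif aa == "R":
            if sequence[i + 1] != "P":
                sites.append(i)
    return sites


def _fragment_bounds(sequence: str, rule: ProteaseRule) -> list[int]:
    """Boundaries of fully cleaved fragments: [0, s1+1, ..., len]."""
    sites = find_cleavage_sites(sequence, rule)
    return [0] + [s + 1 for s in sites] + [len(sequence)]


def enumerate_peptides(sequence: str, params: DigestionParams) -> list[PeptideSpan]:
    """All digest peptides of ``sequence`` under ``params``.

    A peptide is a run of consecutive fully cleaved fragments joined across
    at most ``max_missed_cleavages`` internal sites, filtered to the length
    window.  Spans are returned in (start, missed) order; distinct spans
    with identical sequences are all kept.
    """
    bounds = _fragment_bounds(sequence, params.protease_rule)
    n_frag = len(bounds) - 1
    spans: list[PeptideSpan] = []
    for i in range(n_frag):
        for miss in range(params.max_missed_cleavages + 1):
            j = i + miss + 1
            if j > n_frag:
                break
            start, end = bounds[i], bounds[j]
            length = end - start
            if params.min_peptide_length <= length <= params.max_peptide_length:
                spans.append(PeptideSpan(start, end, miss, sequence[start:end]))
    return spans


def isoform_peptide_count(isoform: ProteinIsoform, params: DigestionParams) -> int:
    """Number of digest peptide spans of one isoform passing the filters."""
    return len(enumerate_peptides(isoform.sequence, params))


def gene_peptide_capacity(gene: GeneModel, params: DigestionParams) -> float:
    """Arithmetic mean of per-isoform peptide counts; the iBAQ denominator.

    Raises
    ------
    CapacityUndefinedError
        If every isoform yields zero peptides after filtering (the gene
        cannot be quantified by iBAQ).
    """
    if not gene.isoforms:
        raise InputError(f"gene {gene.gene_symbol} has no isoforms")
    counts = [isoform_peptide_count(iso, params) for iso in gene.isoforms]
    capacity = statistics.fmean(counts)
    if capacity <= 0:
        raise CapacityUndefinedError(
            f"gene {gene.gene_symbol}: all {len(counts)} isoform(s) yield zero "
            "peptides under the current digestion parameters"
        )
    return capacity


# ---------------------------------------------------------------------------
# FASTA input and capacity tables


def _parse_header(record_id: str, description: str) -> tuple[str, str, str]:
    """Extract (isoform_id, gene_symbol, gene_id) from a FASTA header.

    Accepts the native dialect ``>iso1 GN=ALB GID=213`` as well as
    UniProt-style headers carrying a ``GN=`` token.  Falls back to the
    record id when annotations are absent.
    """
    gene_symbol = ""
    gene_id = ""
    for token in description.split():
        if token.startswith("GN="):
            gene_symbol = token[3:]
        elif token.startswith("GID="):
            gene_id = token[4:]
    if not gene_symbol:
        gene_symbol = record_id
    if not gene_id:
        gene_id = gene_symbol
    return record_id, gene_symbol, gene_id


def read_isoform_fasta(path: str | Path) -> list[ProteinIsoform]:
    """Read protein isoforms from FASTA, taking gene annotations from
    ``GN=``/``GID=`` header tokens."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"FASTA file not found: {path}")
    isoforms: list[ProteinIsoform] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        iso_id, symbol, gid = _parse_header(rec.id, rec.description)
        if iso_id in seen:
            raise InputError(f"duplicate isoform id in FASTA: {iso_id}")
        seen.add(iso_id)
        isoforms.append(ProteinIsoform(iso_id, symbol, gid, str(rec.seq).upper()))
    return isoforms


def group_isoforms(isoforms: Iterable[ProteinIsoform]) -> list[GeneModel]:
    """Group isoforms into genes keyed by (gene_symbol, gene_id)."""
    genes: dict[tuple[str, str], GeneModel] = {}
    for iso in isoforms:
        key = (iso.gene_symbol, iso.gene_id)
        if key not in genes:
            genes[key] = GeneModel(iso.gene_symbol, iso.gene_id)
        genes[key].isoforms.append(iso)
    return list(genes.values())


def build_gene_models(
    isoforms: Iterable[ProteinIsoform],
    params: DigestionParams,
    *,
    skip_undefined: bool = True,
) -> list[GeneModel]:
    """Group isoforms by gene and compute each gene's peptide capacity.

    Genes with undefined capacity (no peptide survives the filters in any
    isoform) are dropped when ``skip_undefined`` is true, else the error
    propagates.
    """
    genes = []
    for gene in group_isoforms(isoforms):
        try:
            gene.peptide_capacity = gene_peptide_capacity(gene, params)
        except CapacityUndefinedError:
            if skip_undefined:
                continue
            raise
        genes.append(gene)
    return genes


def capacity_table(genes: Iterable[GeneModel]) -> pd.DataFrame:
    """Tabulate capacities: gene_symbol, gene_id, n_isoforms, peptide_capacity."""
    rows = [
        {
            "gene_symbol": g.gene_symbol,
            "gene_id": g.gene_id,
            "n_isoforms": len(g.isoforms),
            "peptide_capacity": g.peptide_capacity,
        }
        for g in genes
    ]
    return pd.DataFrame(rows, columns=["gene_symbol", "gene_id", "n_isoforms", "peptide_capacity"])


def gene_peptide_index(genes: Iterable[GeneModel], params: DigestionParams) -> dict[str, set[str]]:
    """Map peptide sequence -> set of gene symbols whose digest contains it.

    Used for peptide-to-gene assignment: a peptide is digest-compatible
    with a gene if any isoform yields it as a span under ``params``.
    """
    index: dict[str, set[str]] = {}
    for gene in genes:
        peptides: set[str] = set()
        for iso in gene.isoforms:
            peptides.update(span.sequence for span in enumerate_peptides(iso.sequence, params))
        for pep in peptides:
            index.setdefault(pep, set()).add(gene.gene_symbol)
    return index
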