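"""Supermatrix assembly: completeness filtering, concatenation with a
partition map, and matrix statistics.

Missing-data conventions: ``?`` encodes whole-locus absence (a taxon with no
accepted contig at a locus), ``-`` encodes within-alignment gaps (indels).
Both are "missing" when counting parsimony-informative sites, but only
``?`` blocks count against matrix completeness — indels are part of the
alignment's characters, absent loci are not.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from ._seq import encode

GAP_CHARS = set("-?Nn")


@dataclass
class LocusAlignment:
    """One per-locus multiple alignment: taxon -> gapped sequence."""

    locus_id: str
    sequences: Dict[str, str]
    length: int = 0

    def __post_init__(self) -> None:
        if self.sequences:
            lens = {len(s) for s in self.sequences.values()}
            if len(lens) > 1:
                raise ValueError(
                    f"{self.locus_id}: sequences have unequal lengths {lens}")
            (n,) = lens
            if self.length and self.length != n:
                raise ValueError(f"{self.locus_id}: length mismatch")
            self.length = n

    @property
    def taxa(self) -> List[str]:
        return sorted(self.sequences)

    def present_taxa(self) -> List[str]:
        """Taxa with at least one non-missing character (all-gap rows count
        as absent)."""
        out = []
        for tx, seq in self.sequences.items():
            if any(c not in GAP_CHARS for c in seq):
                out.append(tx)
        return sorted(out)


@dataclass
class SuperMatrix:
    taxa: List[str]
    sequences: Dict[str, str]
    partitions: Dict[str, Tuple[int, int]]  # locus -> [start, end), 0-based
    completeness: float
    n_informative: int
    total_length: int
    presence: Dict[str, List[str]] = field(default_factory=dict)  # locus -> taxa

    def locus_alignment(self, locus_id: str) -> LocusAlignment:
        """Slice one locus back out of the concatenation (round-trip)."""
        s, e = self.partitions[locus_id]
        rows = {tx: self.sequences[tx][s:e]
                for tx in self.presence.get(locus_id, self.taxa)}
        return LocusAlignment(locus_id, rows, e - s)


def filter_by_completeness(
    loci: Iterable[LocusAlignment],
    max_missing_fraction: float,
    taxa: Sequence[str],
) -> List[LocusAlignment]:
    """Keep loci where at most ``max_missing_fraction`` of ``taxa`` are
    absent (comparison is <=, so 'up to 50%' keeps exactly-half-missing)."""
    taxa = list(taxa)
    if not taxa:
        raise ValueError("taxon set must be non-empty")
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must be in [0, 1]")
    kept = []
    for aln in loci:
        present = set(aln.present_taxa()) & set(taxa)
        missing = (len(taxa) - len(present)) / len(taxa)
        if missing <= max_missing_fraction:
            kept.append(aln)
    return kept


def build_supermatrix(loci: Sequence[LocusAlignment],
                      taxa: Sequence[str]) -> SuperMatrix:
    """Concatenate loci over ``taxa``, filling absent taxon-locus blocks
    with '?'. Completeness is cell-based: filled (taxon, locus) cells over
    all taxa x loci cells."""
    loci = list(loci)
    if not loci:
        raise ValueError("at least one locus required")
    taxa = list(taxa)
    if len(set(taxa)) != len(taxa):
        raise ValueError("duplicate taxon labels")

    parts: Dict[str, Tuple[int, int]] = {}
    presence: Dict[str, List[str]] = {}
    chunks: Dict[str, List[str]] = {tx: [] for tx in taxa}
    pos = 0
    filled = 0
    for aln in loci:
        parts[aln.locus_id] = (pos, pos + aln.length)
        pres = [tx for tx in aln.present_taxa() if tx in set(taxa)]
        presence[aln.locus_id] = pres
        pres_set = set(pres)
        filled += len(pres_set)
        for tx in taxa:
            if tx in pres_set:
                chunks[tx].append(aln.sequences[tx])
            else:
                chunks[tx].append("?" * aln.length)
        pos += aln.length

    sequences = {tx: "".join(chunks[tx]) for tx in taxa}
    completeness = filled / (len(taxa) * len(loci))
    n_inf = count_informative_sites(list(sequences.values()))
    return SuperMatrix(taxa=taxa, sequences=sequences, partitions=parts,
                       completeness=completeness, n_informative=n_inf,
                       total_length=pos, presence=presence)


def count_informative_sites(rows: Sequence[str]) -> int:
    """Parsimony-informative columns: >=2 distinct non-missing states, each
    carried by >=2 sequences. Gaps, '?' and N are missing."""
    if not rows:
        return 0
    arr = np.vstack([encode(r) for r in rows])
    counts = np.zeros((4, arr.shape[1]), dtype=np.int64)
    for s in range(4):
        counts[s] = (arr == s).sum(axis=0)
    return int(((counts >= 2).sum(axis=0) >= 2).sum())
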