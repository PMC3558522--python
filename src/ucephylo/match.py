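"""Contig-to-locus assignment and duplicate/paralog filtering.

Candidate (contig, locus) pairs are found by shared k-mer seeding and
verified by local alignment on both strands (best strand kept). A verified
pair is reported when its identity over aligned columns and its coverage of
the reference locus both clear the configured thresholds.

Duplicate filtering applies two rules in a fixed order: (a) a contig
matching more than one locus is removed entirely (the paralog screen);
(b) a locus hit by more than one surviving contig of the same taxon is
removed for that taxon. Both removals are logged in ledgers; the surviving
assignments are one-to-one within each taxon.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Set, Tuple

import pandas as pd
from Bio import Align

from ._seq import kmers, revcomp

_VALID = set("ACGTN")


class ReferenceLocusSet(dict):
    """locus_id -> reference nucleotide sequence; validates on construction."""

    def __init__(self, loci: Mapping[str, str]):
        super().__init__()
        for lid, seq in loci.items():
            s = str(seq).upper()
            if not s:
                raise ValueError(f"reference locus {lid!r} is empty")
            bad = set(s) - _VALID
            if bad:
                raise ValueError(
                    f"reference locus {lid!r} has invalid characters {bad}")
            self[lid] = s


@dataclass
class ContigMatch:
    taxon: str
    contig_id: str
    locus_id: str
    identity: float
    aligned_fraction_of_locus: float
    contig_length: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must be in [0, 1]")
        if not 0.0 <= self.aligned_fraction_of_locus <= 1.0:
            raise ValueError("aligned fraction must be in [0, 1]")


@dataclass
class TaxonLocusDB:
    """Per-taxon accepted contig-to-locus assignments plus removal ledgers."""

    accepted: Dict[Tuple[str, str], ContigMatch] = field(default_factory=dict)
    removed_multilocus_contigs: Dict[str, List[str]] = field(
        default_factory=dict)
    removed_multicontig_loci: Dict[str, List[str]] = field(
        default_factory=dict)

    def contig_for(self, taxon: str, locus: str) -> Optional[str]:
        m = self.accepted.get((taxon, locus))
        return m.contig_id if m else None

    def taxa(self) -> List[str]:
        return sorted({t for t, _ in self.accepted})

    def loci(self) -> List[str]:
        return sorted({l for _, l in self.accepted})

    def presence_frame(self, taxa: Iterable[str],
                       loci: Iterable[str]) -> pd.DataFrame:
        taxa, loci = list(taxa), list(loci)
        frame = pd.DataFrame(False, index=taxa, columns=loci)
        for (t, l) in self.accepted:
            if t in frame.index and l in frame.columns:
                frame.at[t, l] = True
        return frame

    def check_one_to_one(self) -> None:
        seen_contig: Set[Tuple[str, str]] = set()
        for (taxon, _locus), m in self.accepted.items():
            key = (taxon, m.contig_id)
            if key in seen_contig:
                raise AssertionError(
                    f"contig {m.contig_id} assigned to multiple loci")
            seen_contig.add(key)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.5
    aligner.open_gap_score = -3.0
    aligner.extend_gap_score = -1.0
    return aligner


def _verify(aligner: Align.PairwiseAligner, locus_seq: str,
            contig_seq: str) -> Tuple[float, float]:
    """Best local alignment of contig against locus; returns (identity over
    aligned columns, aligned fraction of the locus)."""
    alns = aligner.align(locus_seq, contig_seq)
    if len(alns) == 0 or alns.score <= 0:
        return 0.0, 0.0
    aln = alns[0]
    c = aln.counts()
    cols = c.identities + c.mismatches + c.gaps
    identity = c.identities / cols if cols else 0.0
    tblocks = aln.aligned[0]
    span = tblocks[-1][1] - tblocks[0][0]
    return identity, span / len(locus_seq)


def match_contigs(
    contigs: Mapping[str, Mapping[str, str]],
    reference: ReferenceLocusSet,
    min_identity: float = 0.80,
    min_locus_fraction: float = 0.80,
    kmer_size: int = 15,
) -> List[ContigMatch]:
    """All (contig, locus) matches clearing both thresholds.

    ``contigs`` maps taxon -> contig_id -> sequence. Both strands are
    searched; the better-scoring strand is reported.
    """
    if not reference:
        raise ValueError("reference locus set is empty")
    if not 0.0 <= min_identity <= 1.0 or not 0.0 <= min_locus_fraction <= 1.0:
        raise ValueError("thresholds must be in [0, 1]")

    index: Dict[str, Set[str]] = defaultdict(set)
    for lid, seq in reference.items():
        for km in kmers(seq, kmer_size):
            index[km].add(lid)

    aligner = _make_aligner()
    matches: List[ContigMatch] = []
    for taxon in sorted(contigs):
        for cid in sorted(contigs[taxon]):
            seq = contigs[taxon][cid].upper()
            rc = revcomp(seq)
            candidates: Dict[str, Set[str]] = defaultdict(set)
            for strand, s in (("+", seq), ("-", rc)):
                for km in kmers(s, kmer_size):
                    for lid in index.get(km, ()):
                        candidates[lid].add(strand)
            for lid in sorted(candidates):
                best = None
                for strand in sorted(candidates[lid], reverse=True):
                    ident, frac = _verify(
                        aligner, reference[lid], seq if strand == "+" else rc)
                    if best is None or ident * frac > best[0] * best[1]:
                        best = (ident, frac, strand)
                ident, frac, strand = best
                if ident >= min_identity and frac >= min_locus_fraction:
                    matches.append(ContigMatch(
                        taxon=taxon, contig_id=cid, locus_id=lid,
                        identity=ident, aligned_fraction_of_locus=frac,
                        contig_length=len(seq), strand=strand))
    return matches


def filter_duplicates(matches: Iterable[ContigMatch]) -> TaxonLocusDB:
    """Build the taxon-specific database, removing (a) contigs matching
    more than one locus, then (b) loci hit by more than one surviving
    contig. Any second locus above threshold removes the contig — ties do
    not rescue it."""
    by_taxon: Dict[str, List[ContigMatch]] = defaultdict(list)
    for m in matches:
        by_taxon[m.taxon].append(m)

    db = TaxonLocusDB()
    for taxon in sorted(by_taxon):
        ms = by_taxon[taxon]
        loci_per_contig: Dict[str, Set[str]] = defaultdict(set)
        for m in ms:
            loci_per_contig[m.contig_id].add(m.locus_id)
        multi = sorted(c for c, ls in loci_per_contig.items() if len(ls) > 1)
        if multi:
            db.removed_multilocus_contigs[taxon] = multi
        survivors = [m for m in ms if m.contig_id not in set(multi)]

        contigs_per_locus: Dict[str, Set[str]] = defaultdict(set)
        for m in survivors:
            contigs_per_locus[m.locus_id].add(m.contig_id)
        bad_loci = sorted(l for l, cs in contigs_per_locus.items()
                          if len(cs) > 1)
        if bad_loci:
            db.removed_multicontig_loci[taxon] = bad_loci
        for m in survivors:
            if m.locus_id not in set(bad_loci):
                db.accepted[(taxon, m.locus_id)] = m
    db.check_one_to_one()
    return db
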