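"""Shared-indel detection and clade mapping.

Scans column-homologous per-locus alignments for deletion events: maximal
gap runs of length >= 2 shared (with identical boundaries) by >= 2 ingroup
taxa. Leading and trailing gap runs are treated as missing data, not
indels. Each event is classified against a reference topology: it
validates the branch whose ingroup descendant leaf set equals the event's
sharing set exactly, and is homoplastic otherwise.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

import dendropy

from .matrix import LocusAlignment


@dataclass
class IndelEvent:
    locus_id: str
    start: int  # 0-based half-open columns
    end: int
    sharing_taxa: FrozenSet[str]
    outgroup_state: str = "missing"  # "present" | "absent" | "missing"

    @property
    def length(self) -> int:
        return self.end - self.start

    def __post_init__(self) -> None:
        if self.length < 2:
            raise ValueError("indel events must span >= 2 columns")
        if len(self.sharing_taxa) < 2:
            raise ValueError("shared events need >= 2 taxa")


@dataclass
class CladeSupportMap:
    tree: dendropy.Tree
    validating: Dict[FrozenSet[str], int]  # branch (ingroup leaf set) -> count
    homoplastic: List[IndelEvent]
    skipped: List[IndelEvent] = field(default_factory=list)

    @property
    def n_validating(self) -> int:
        return sum(self.validating.values())


def gap_runs(seq: str) -> List[Tuple[int, int]]:
    """Maximal internal '-' runs as [start, end) intervals; leading and
    trailing runs (missing data) are excluded."""
    runs: List[Tuple[int, int]] = []
    start = None
    for i, c in enumerate(seq):
        if c == "-":
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(seq)))
    # drop terminal runs
    return [(a, b) for a, b in runs if a > 0 and b < len(seq)]


def find_shared_indels(
    alignments: Iterable[LocusAlignment],
    ingroup: Sequence[str],
    min_length: int = 2,
    min_taxa: int = 2,
    outgroup: Optional[str] = None,
    boundary_slop: int = 0,
) -> List[IndelEvent]:
    """Shared gap runs across loci. Two taxa share an event iff their runs
    have identical boundaries (relaxable via ``boundary_slop``, which merges
    runs whose start and end each differ by at most that many columns;
    the reported interval is the first-seen run's). Taxa absent from a
    locus are ignored."""
    ingroup_set = set(ingroup)
    events: List[IndelEvent] = []
    for aln in alignments:
        present = set(aln.present_taxa())
        by_span: Dict[Tuple[int, int], List[str]] = {}
        spans_in_order: List[Tuple[int, int]] = []
        for tx in sorted(present & ingroup_set):
            for span in gap_runs(aln.sequences[tx]):
                if span[1] - span[0] < min_length:
                    continue
                key = span
                if boundary_slop:
                    for seen in spans_in_order:
                        if (abs(seen[0] - span[0]) <= boundary_slop
                                and abs(seen[1] - span[1]) <= boundary_slop):
                            key = seen
                            break
                if key not in by_span:
                    spans_in_order.append(key)
                    by_span[key] = []
                by_span[key].append(tx)
        for (a, b) in sorted(spans_in_order):
            taxa = by_span[(a, b)]
            if len(taxa) < min_taxa:
                continue
            og_state = "missing"
            if outgroup is not None and outgroup in present:
                og_runs = set(gap_runs(aln.sequences[outgroup]))
                if (a, b) in og_runs:
                    og_state = "absent"
                elif all(c != "-" for c in aln.sequences[outgroup][a:b]):
                    og_state = "present"
                else:
                    og_state = "missing"
            events.append(IndelEvent(aln.locus_id, a, b,
                                     frozenset(taxa), og_state))
    return events


def map_to_tree(
    events: Iterable[IndelEvent],
    reference_tree: dendropy.Tree,
    ingroup: Sequence[str],
) -> CladeSupportMap:
    """Classify each event against the reference topology.

    An event validates the branch whose ingroup descendant leaf set equals
    its sharing set exactly; anything else is homoplastic. Events whose
    sharing taxa are missing from the tree are skipped with a notice.
    """
    ingroup_set = set(ingroup)
    tip_labels = {l.taxon.label for l in reference_tree.leaf_node_iter()}
    clades: Dict[FrozenSet[str], dendropy.Node] = {}
    for node in reference_tree.preorder_internal_node_iter():
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        key = frozenset(below & ingroup_set)
        if len(key) >= 2:
            clades.setdefault(key, node)

    validating: Dict[FrozenSet[str], int] = {}
    homoplastic: List[IndelEvent] = []
    skipped: List[IndelEvent] = []
    for ev in events:
        if not ev.sharing_taxa <= tip_labels:
            skipped.append(ev)
            continue
        if ev.sharing_taxa in clades:
            validating[ev.sharing_taxa] = validating.get(ev.sharing_taxa, 0) + 1
        else:
            homoplastic.append(ev)
    return CladeSupportMap(tree=reference_tree, validating=validating,
                           homoplastic=homoplastic, skipped=skipped)
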