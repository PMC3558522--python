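"""STAR species-tree estimation (Species Trees from Average Ranks of
Coalescences) and the two-level multilocus nonparametric bootstrap.

STAR assigns rank n-1 to the root of each rooted n-tip gene tree and
rank = parent - 1 to every other internal node; the distance between two
taxa in a gene tree is twice the rank of their most recent common ancestor.
Distances are averaged entrywise across gene trees (over the trees where
both taxa occur) and a neighbor-joining tree of the averaged matrix is the
species-tree estimate.

The bootstrap resamples loci with replacement, then sites within each
drawn locus with replacement, re-estimates every gene tree and the STAR
tree, and reports per-branch support as the percentage of replicate trees
containing each bipartition of the point estimate.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import dendropy
import numpy as np

from ._seq import encode
from .matrix import LocusAlignment
from .models import codes_jc_matrix
from .trees import (Clade, DistanceMatrix, clade_splits, clade_to_dendropy,
                    dendropy_to_clade, nj_clade, root_clade_at_leaf)


# ---------------------------------------------------------------------------
# coalescence ranks
# ---------------------------------------------------------------------------

@dataclass
class RankedGeneTree:
    """A rooted binary gene tree with STAR node ranks."""

    tree: dendropy.Tree
    ranks: Dict[dendropy.Node, int]

    def pair_distance(self, a: str, b: str) -> float:
        leaves = {l.taxon.label: l for l in self.tree.leaf_node_iter()}
        ancestors_a = []
        node = leaves[a]
        while node is not None:
            ancestors_a.append(node)
            node = node.parent_node
        aset = set(id(n) for n in ancestors_a)
        node = leaves[b]
        while id(node) not in aset:
            node = node.parent_node
        return 2.0 * self.ranks[node]

    def distance_matrix(self) -> DistanceMatrix:
        taxa = sorted(l.taxon.label for l in self.tree.leaf_node_iter())
        n = len(taxa)
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = self.pair_distance(taxa[i], taxa[j])
        return DistanceMatrix(taxa, D)


def _check_rooted_binary(tree: dendropy.Tree) -> None:
    for node in tree.preorder_internal_node_iter():
        n = len(node.child_nodes())
        if node is tree.seed_node and n != 2:
            raise ValueError(
                "gene tree must be rooted (seed node with 2 children); "
                f"found {n}")
        if node is not tree.seed_node and n != 2:
            raise ValueError("multifurcating gene trees are not supported")


def rank_coalescences(tree: dendropy.Tree) -> RankedGeneTree:
    """Assign STAR ranks: root = n_tips - 1, every other internal node =
    parent rank - 1. Rejects unrooted or multifurcating trees."""
    _check_rooted_binary(tree)
    n_tips = sum(1 for _ in tree.leaf_node_iter())
    ranks: Dict[dendropy.Node, int] = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        if node is tree.seed_node:
            ranks[node] = n_tips - 1
        else:
            ranks[node] = ranks[node.parent_node] - 1
    return RankedGeneTree(tree, ranks)


# ---------------------------------------------------------------------------
# rank-distance accumulation (fast path on Clade objects)
# ---------------------------------------------------------------------------

def _accumulate_rank_distances(root: Clade, tindex: Dict[str, int],
                               sums: np.ndarray, counts: np.ndarray) -> None:
    """Add one rooted gene tree's 2*rank(MRCA) distances into the running
    entrywise sums/counts."""
    n_tips = len(root.leaves())

    def rec(node: Clade, rank: int) -> List[int]:
        if node.is_leaf():
            return [tindex[node.label]]
        groups = [rec(c, rank - 1) for c, _ in node.children]
        d = 2.0 * rank
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for a in groups[gi]:
                    for b in groups[gj]:
                        sums[a, b] += d
                        sums[b, a] += d
                        counts[a, b] += 1
                        counts[b, a] += 1
        return [i for g in groups for i in g]

    rec(root, n_tips - 1)


def average_rank_distance(gene_trees: Sequence, taxa: Optional[Sequence[str]] = None
                          ) -> DistanceMatrix:
    """Entrywise average of 2*rank(MRCA) over the gene trees containing each
    pair. Raises if some pair co-occurs in no tree (naming the pair)."""
    clades = [dendropy_to_clade(t) if isinstance(t, dendropy.Tree) else t
              for t in gene_trees]
    if not clades:
        raise ValueError("at least one gene tree required")
    for t in gene_trees:
        if isinstance(t, dendropy.Tree):
            _check_rooted_binary(t)
    if taxa is None:
        taxa = sorted(set().union(*(c.leaves() for c in clades)))
    taxa = list(taxa)
    tindex = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    sums = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=np.int64)
    for c in clades:
        _accumulate_rank_distances(c, tindex, sums, counts)
    off = ~np.eye(n, dtype=bool)
    if (counts[off] == 0).any():
        i, j = np.argwhere((counts == 0) & off)[0]
        raise ValueError(
            f"taxa {taxa[i]!r} and {taxa[j]!r} co-occur in no gene tree")
    D = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(taxa, D)


def star_tree(gene_trees: Sequence, taxa: Optional[Sequence[str]] = None
              ) -> dendropy.Tree:
    """STAR species-tree topology: NJ on the averaged rank-distance matrix."""
    dm = average_rank_distance(gene_trees, taxa)
    return clade_to_dendropy(nj_clade(dm.matrix, dm.taxa))


# ---------------------------------------------------------------------------
# multilocus bootstrap
# ---------------------------------------------------------------------------

@dataclass
class SpeciesTreeResult:
    tree: dendropy.Tree
    support: Dict[FrozenSet[str], float]  # canonical split -> percentage
    n_replicates: int
    collapse_threshold: Optional[float] = None
    n_loci_used: int = 0
    skipped_loci: List[str] = field(default_factory=list)
    replicate_splits: Optional[List[Set[FrozenSet[str]]]] = None


def _gene_clade_from_codes(arr: np.ndarray, labels: List[str],
                           outgroup: str) -> Optional[Clade]:
    """JC-NJ gene tree rooted on the outgroup, from an encoded alignment.
    Prunes taxa involved in no-shared-data pairs; None when fewer than 3
    taxa remain or the outgroup is lost."""
    D, mask = codes_jc_matrix(arr)
    keep = list(range(len(labels)))
    while True:
        sub = mask[np.ix_(keep, keep)]
        if not sub.any():
            break
        worst = keep[int(sub.sum(axis=1).argmax())]
        keep.remove(worst)
    labs = [labels[i] for i in keep]
    if len(labs) < 3 or outgroup not in labs:
        return None
    unrooted = nj_clade(D[np.ix_(keep, keep)], labs)
    return root_clade_at_leaf(unrooted, outgroup)


def _star_clade(sums: np.ndarray, counts: np.ndarray,
                taxa: List[str]) -> Optional[Clade]:
    off = ~np.eye(len(taxa), dtype=bool)
    if (counts[off] == 0).any():
        return None
    D = sums / np.maximum(counts, 1)
    np.fill_diagonal(D, 0.0)
    return nj_clade(D, taxa)


def multilocus_bootstrap(
    alignments: Sequence[LocusAlignment],
    n_replicates: int,
    seed: int,
    outgroup: str,
    max_redraws: int = 100,
    keep_replicates: bool = False,
) -> SpeciesTreeResult:
    """STAR point estimate plus two-level nonparametric bootstrap support.

    Each replicate draws L loci with replacement, then resamples columns
    with replacement within each drawn locus to its original length,
    re-estimates all gene trees (JC-NJ, outgroup-rooted) and the STAR tree.
    Support for each internal branch of the point estimate is the percentage
    of replicate trees containing that bipartition. Replicate r uses the RNG
    substream (seed, r), so replicates are reproducible independently of
    execution order. Replicates whose locus draw leaves some taxon pair
    disconnected are redrawn (up to ``max_redraws``).
    """
    alignments = list(alignments)
    if not alignments:
        raise ValueError("empty locus set")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")

    encoded: List[Tuple[np.ndarray, List[str]]] = []
    skipped: List[str] = []
    for aln in alignments:
        labs = aln.present_taxa()
        if len(labs) < 3 or outgroup not in labs:
            skipped.append(aln.locus_id)
            continue
        arr = np.vstack([encode(aln.sequences[t]) for t in labs])
        encoded.append((arr, labs))
    if not encoded:
        raise ValueError("no usable loci (need >= 3 taxa incl. outgroup)")

    taxa = sorted(set().union(*(labs for _, labs in encoded)))
    tindex = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)

    # point estimate
    sums = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=np.int64)
    for arr, labs in encoded:
        clade = _gene_clade_from_codes(arr, labs, outgroup)
        if clade is not None:
            _accumulate_rank_distances(clade, tindex, sums, counts)
    point = _star_clade(sums, counts, taxa)
    if point is None:
        raise ValueError("point estimate failed: disconnected taxon pair")
    point_splits = clade_splits(point)
    hits = {s: 0 for s in point_splits}
    replicate_splits: List[Set[FrozenSet[str]]] = []

    L = len(encoded)
    for rep in range(n_replicates):
        rng = np.random.default_rng([seed, rep])
        rep_clade = None
        for _ in range(max_redraws):
            sums.fill(0.0)
            counts.fill(0)
            for li in rng.integers(0, L, size=L):
                arr, labs = encoded[li]
                cols = rng.integers(0, arr.shape[1], size=arr.shape[1])
                clade = _gene_clade_from_codes(arr[:, cols], labs, outgroup)
                if clade is not None:
                    _accumulate_rank_distances(clade, tindex, sums, counts)
            rep_clade = _star_clade(sums, counts, taxa)
            if rep_clade is not None:
                break
        if rep_clade is None:
            raise ValueError(
                f"bootstrap replicate {rep}: could not connect all taxon "
                f"pairs in {max_redraws} locus redraws")
        rep_splits = clade_splits(rep_clade)
        if keep_replicates:
            replicate_splits.append(rep_splits)
        for s in point_splits & rep_splits:
            hits[s] += 1

    support = {s: 100.0 * c / n_replicates for s, c in hits.items()}
    tree = clade_to_dendropy(point)
    _annotate_support(tree, support)
    return SpeciesTreeResult(tree=tree, support=support,
                             n_replicates=n_replicates,
                             n_loci_used=L, skipped_loci=skipped,
                             replicate_splits=(replicate_splits
                                               if keep_replicates else None))


def _annotate_support(tree: dendropy.Tree,
                      support: Dict[FrozenSet[str], float]) -> None:
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    anchor = min(leaves)
    for node in tree.preorder_internal_node_iter():
        if node is tree.seed_node:
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        if not 1 < len(below) < len(leaves) - 1:
            continue
        key = below if anchor not in below else leaves - below
        if key in support:
            node.label = f"{support[key]:g}"


def collapse(tree: dendropy.Tree, threshold_percent: float) -> dendropy.Tree:
    """Contract every internal branch whose support (stored in the internal
    node label) is below ``threshold_percent``; tips are untouched."""
    out = tree.clone(depth=1)
    to_collapse = []
    for node in out.preorder_internal_node_iter():
        if node is out.seed_node or node.is_leaf():
            continue
        sup = None
        if node.label is not None:
            try:
                sup = float(node.label)
            except ValueError:
                sup = None
        if sup is not None and sup < threshold_percent:
            to_collapse.append(node.edge)
        elif sup is None and threshold_percent > 100.0:
            to_collapse.append(node.edge)
    for edge in to_collapse:
        edge.collapse()
    return out
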