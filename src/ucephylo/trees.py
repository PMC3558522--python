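"""Distance-based gene-tree estimation: neighbor-joining with deterministic
tie-breaking, and outgroup rooting.

The NJ core works on plain numpy matrices and a lightweight clade structure
so it can run hundreds of thousands of times inside the multilocus
bootstrap; thin wrappers convert to/from dendropy trees for the public API.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import dendropy
import numpy as np


# ---------------------------------------------------------------------------
# distance matrix container
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric matrix of substitutions/site with a mask for pairs that
    share no data."""

    taxa: List[str]
    matrix: np.ndarray
    mask: Optional[np.ndarray] = None  # True where the pair is missing

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.taxa)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if self.mask is None:
            self.mask = np.zeros((n, n), dtype=bool)
        if not np.allclose(np.diag(self.matrix), 0.0):
            raise ValueError("diagonal must be zero")
        valid = ~self.mask
        if not np.allclose(self.matrix[valid], self.matrix.T[valid]):
            raise ValueError("matrix must be symmetric")
        if (self.matrix[valid] < -1e-12).any():
            raise ValueError("distances must be >= 0")

    def masked_taxa(self) -> List[str]:
        return [self.taxa[i] for i in range(len(self.taxa))
                if self.mask[i].any()]

    def drop(self, taxa: Sequence[str]) -> "DistanceMatrix":
        keep = [i for i, t in enumerate(self.taxa) if t not in set(taxa)]
        return DistanceMatrix(
            [self.taxa[i] for i in keep],
            self.matrix[np.ix_(keep, keep)],
            self.mask[np.ix_(keep, keep)],
        )


# ---------------------------------------------------------------------------
# lightweight clades
# ---------------------------------------------------------------------------

class Clade:
    """Minimal rooted (sub)tree node: leaves carry a label, internal nodes
    carry (child, branch_length) pairs. The NJ result is a Clade whose root
    has three children (the standard unrooted representation)."""

    __slots__ = ("label", "children")

    def __init__(self, label: Optional[str] = None,
                 children: Sequence[Tuple["Clade", float]] = ()):
        self.label = label
        self.children = list(children)

    def is_leaf(self) -> bool:
        return self.label is not None

    def leaves(self) -> List[str]:
        if self.is_leaf():
            return [self.label]
        out: List[str] = []
        stack = [self]
        while stack:
            node = stack.pop()
            if node.is_leaf():
                out.append(node.label)
            else:
                stack.extend(c for c, _ in node.children)
        return out

    def newick(self, digits: int = 6) -> str:
        def rec(node: "Clade") -> str:
            if node.is_leaf():
                return node.label
            inner = ",".join(f"{rec(c)}:{bl:.{digits}g}"
                             for c, bl in node.children)
            return f"({inner})"
        return rec(self) + ";"


def clade_splits(root: Clade) -> Set[FrozenSet[str]]:
    """Non-trivial unrooted splits, each as the frozenset of leaves on the
    side away from the (arbitrary) root."""
    all_leaves = frozenset(root.leaves())
    splits: Set[FrozenSet[str]] = set()

    def rec(node: Clade) -> FrozenSet[str]:
        if node.is_leaf():
            return frozenset([node.label])
        below = frozenset().union(*(rec(c) for c, _ in node.children))
        if node is not root and 1 < len(below) < len(all_leaves) - 1:
            splits.add(below)
        return below

    rec(root)
    # canonicalise: keep the side not containing the lexicographically
    # smallest leaf, so equal splits compare equal regardless of rooting
    anchor = min(all_leaves)
    return {s if anchor not in s else all_leaves - s for s in splits}


def normalized_splits(tree: dendropy.Tree) -> Set[FrozenSet[str]]:
    """Non-trivial splits of a dendropy tree, canonicalised as in
    ``clade_splits`` (usable for unrooted topology comparison)."""
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    anchor = min(leaves)
    splits: Set[FrozenSet[str]] = set()
    for node in tree.preorder_internal_node_iter():
        if node is tree.seed_node:
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        if 1 < len(below) < len(leaves) - 1:
            splits.add(below if anchor not in below else leaves - below)
    return splits


def same_topology(a, b) -> bool:
    """Unrooted topology equality via canonical split sets."""
    sa = clade_splits(a) if isinstance(a, Clade) else normalized_splits(a)
    sb = clade_splits(b) if isinstance(b, Clade) else normalized_splits(b)
    la = set(a.leaves()) if isinstance(a, Clade) else \
        {l.taxon.label for l in a.leaf_node_iter()}
    lb = set(b.leaves()) if isinstance(b, Clade) else \
        {l.taxon.label for l in b.leaf_node_iter()}
    return la == lb and sa == sb


# ---------------------------------------------------------------------------
# neighbor-joining core
# ---------------------------------------------------------------------------

def nj_clade(D: np.ndarray, labels: Sequence[str]) -> Clade:
    """Saitou–Nei neighbor-joining on a dense matrix.

    Negative branch lengths are clamped to zero. Ties in the Q criterion are
    broken by the lexicographically smallest (rep_i, rep_j) pair, where a
    cluster's representative is its smallest leaf label — so the result is
    independent of input row order.
    """
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor-joining requires >= 3 taxa")
    # preallocate for the n-2 join nodes to avoid growing the matrix
    full = np.zeros((2 * n - 2, 2 * n - 2))
    full[:n, :n] = np.asarray(D, dtype=float)
    D = full
    nodes: List[Clade] = [Clade(label=l) for l in labels]
    reps: List[str] = list(labels)
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        idx = np.asarray(active)
        sub = D[idx[:, None], idx[None, :]]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(Q.argmin())
        i, j = flat // m, flat % m
        qmin = Q[i, j]
        if np.count_nonzero(Q <= qmin + 1e-10) > 2:  # tie (pairs counted twice)
            ties = np.argwhere(Q <= qmin + 1e-10)
            _, i, j = min(
                (tuple(sorted((reps[active[a]], reps[active[b]]))), a, b)
                for a, b in ties if a < b)
        elif i > j:
            i, j = j, i
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        if reps[aj] < reps[ai]:  # canonical child order
            ai, aj, li, lj = aj, ai, lj, li
        new = Clade(children=[(nodes[ai], li), (nodes[aj], lj)])
        k = len(nodes)
        # distances from the new node to remaining clusters
        dnew = 0.5 * (D[ai, idx] + D[aj, idx] - dij)
        D[k, idx] = dnew
        D[idx, k] = dnew
        D[k, k] = 0.0
        nodes.append(new)
        reps.append(min(reps[ai], reps[aj]))
        active = [a for a in active if a != ai and a != aj] + [k]

    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    order = sorted(((reps[x], x, max(l, 0.0)) for x, l in
                    ((a, la), (b, lb), (c, lc))))
    return Clade(children=[(nodes[x], l) for _, x, l in order])


def root_clade_at_leaf(root: Clade, outgroup: str) -> Clade:
    """Re-root an unrooted Clade on the outgroup's pendant edge (midpoint).

    Returns a rooted binary Clade whose root has the outgroup leaf as one
    child and the rest of the tree as the other.
    """
    # build adjacency
    adj: Dict[int, List[Tuple[int, float]]] = {}
    labels: Dict[int, Optional[str]] = {}
    counter = [0]

    def index(node: Clade) -> int:
        i = counter[0]
        counter[0] += 1
        labels[i] = node.label
        adj[i] = []
        for child, bl in node.children:
            j = index(child)
            adj[i].append((j, bl))
            adj[j].append((i, bl))
        return i

    index(root)
    leaf_id = next((i for i, l in labels.items() if l == outgroup), None)
    if leaf_id is None:
        raise OutgroupNotFoundError(f"outgroup {outgroup!r} not in tree")
    (nbr, bl), = adj[leaf_id]

    def hang(i: int, parent: int, incoming: float) -> Tuple[Clade, float]:
        kids = [(j, w) for j, w in adj[i] if j != parent]
        if not kids:
            return Clade(label=labels[i]), incoming
        if len(kids) == 1:  # suppress degree-2 node left behind by rerooting
            j, w = kids[0]
            return hang(j, i, incoming + w)
        built = []
        for j, w in kids:
            c, tot = hang(j, i, w)
            built.append((c, tot))
        return Clade(children=built), incoming

    rest, _ = hang(nbr, leaf_id, bl / 2.0)
    return Clade(children=[(Clade(label=outgroup), bl / 2.0),
                           (rest, bl / 2.0)])


def clade_to_dendropy(root: Clade,
                      tns: Optional[dendropy.TaxonNamespace] = None,
                      ) -> dendropy.Tree:
    if tns is None:
        tns = dendropy.TaxonNamespace(sorted(root.leaves()))
    tree = dendropy.Tree(taxon_namespace=tns)

    def build(node: Clade, dnode: dendropy.Node) -> None:
        if node.is_leaf():
            dnode.taxon = tns.get_taxon(node.label)
            return
        for child, bl in node.children:
            d = dnode.new_child()
            d.edge.length = bl
            build(child, d)

    build(root, tree.seed_node)
    return tree


def dendropy_to_clade(tree: dendropy.Tree) -> Clade:
    def build(node: dendropy.Node) -> Clade:
        if node.is_leaf():
            return Clade(label=node.taxon.label)
        return Clade(children=[(build(c), c.edge.length or 0.0)
                               for c in node.child_nodes()])
    return build(tree.seed_node)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

class OutgroupNotFoundError(KeyError):
    """Raised when the requested outgroup is not a tip of the tree."""


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree (unrooted; trifurcating seed node) from a
    complete DistanceMatrix. Masked pairs must be pruned by the caller."""
    if dm.mask is not None and dm.mask.any():
        raise ValueError(
            f"distance matrix has masked pairs; prune taxa first "
            f"({', '.join(dm.masked_taxa())})")
    return clade_to_dendropy(nj_clade(dm.matrix, dm.taxa))


def root_with_outgroup(tree: dendropy.Tree, outgroup: str) -> dendropy.Tree:
    """Root a tree at the midpoint of the outgroup's pendant edge."""
    clade = dendropy_to_clade(tree)
    rooted = root_clade_at_leaf(clade, outgroup)
    return clade_to_dendropy(rooted, tree.taxon_namespace)


def gene_tree_from_alignment(
    aln,
    outgroup: Optional[str] = None,
    model: str = "JC69",
    max_distance: float = 5.0,
) -> Optional[dendropy.Tree]:
    """NJ gene tree from one locus alignment; rooted when an outgroup is
    given. Taxa involved in masked (no shared data) pairs are pruned.
    Returns None if fewer than 3 taxa remain or the outgroup was requested
    but dropped."""
    from .models import distance_matrix  # local import to avoid a cycle

    dm = distance_matrix(aln, model=model, max_distance=max_distance)
    while dm.mask.any():
        worst = int(dm.mask.sum(axis=1).argmax())
        dm = dm.drop([dm.taxa[worst]])
    if len(dm.taxa) < 3:
        return None
    if outgroup is not None and outgroup not in dm.taxa:
        return None
    tree = nj_tree(dm)
    if outgroup is not None:
        tree = root_with_outgroup(tree, outgroup)
    return tree
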