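"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: likelihoods by
exhaustive enumeration over internal states, informative sites by a naive
per-column recount, indel runs by a regex scan, local alignment by a plain
Smith-Waterman dynamic program, and additive distances by path sums on a
random tree.
"""
from __future__ import annotations

import itertools
import re
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np

from ucephylo.models import (SubstitutionModel, discrete_gamma_rates,
                             transition_matrix)
from ucephylo.trees import Clade

BASES = "ACGT"
CODE = {b: i for i, b in enumerate(BASES)}


# ---------------------------------------------------------------------------
# likelihood by enumeration
# ---------------------------------------------------------------------------

def enumeration_log_likelihood(aln: Dict[str, str], tree: Clade,
                               model: SubstitutionModel) -> float:
    """Sum over all internal-node state assignments, column by column."""
    internals: List[Clade] = []
    leaves: List[Clade] = []

    def visit(node: Clade) -> None:
        (leaves if node.is_leaf() else internals).append(node)
        for c, _ in node.children:
            visit(c)

    visit(tree)
    parent_bl: Dict[int, Tuple[Clade, float]] = {}
    for node in internals:
        for c, bl in node.children:
            parent_bl[id(c)] = (node, bl)

    pi = model.effective_freqs()
    rates = discrete_gamma_rates(model.alpha) if model.gamma else [1.0]
    ncols = len(next(iter(aln.values())))
    total = 0.0
    for col in range(ncols):
        col_lik = 0.0
        for rate in rates:
            P = {id(c): transition_matrix(model, bl * rate)
                 for node in internals for c, bl in node.children}
            s = 0.0
            for assign in itertools.product(range(4), repeat=len(internals)):
                state = {id(n): a for n, a in zip(internals, assign)}
                term = pi[state[id(tree)]]
                for node in internals + leaves:
                    if node is tree:
                        continue
                    parent, _bl = parent_bl[id(node)]
                    if node.is_leaf():
                        obs = aln[node.label][col]
                        if obs not in CODE:
                            continue  # missing: sums to 1 over child states
                        term *= P[id(node)][state[id(parent)], CODE[obs]]
                    else:
                        term *= P[id(node)][state[id(parent)], state[id(node)]]
                s += term
            col_lik += s / len(rates)
        total += np.log(col_lik)
    return float(total)


# ---------------------------------------------------------------------------
# informative sites, naive
# ---------------------------------------------------------------------------

def naive_informative_sites(rows: Sequence[str]) -> int:
    n = 0
    for col in zip(*rows):
        counts: Dict[str, int] = {}
        for c in col:
            if c.upper() in CODE:
                counts[c.upper()] = counts.get(c.upper(), 0) + 1
        if sum(1 for v in counts.values() if v >= 2) >= 2:
            n += 1
    return n


# ---------------------------------------------------------------------------
# indel runs, naive
# ---------------------------------------------------------------------------

def naive_shared_indels(seqs: Dict[str, str], ingroup: Set[str],
                        min_length: int = 2, min_taxa: int = 2
                        ) -> Dict[Tuple[int, int], Set[str]]:
    """Regex scan for internal gap runs, grouped by exact span."""
    shared: Dict[Tuple[int, int], Set[str]] = {}
    for tx, seq in seqs.items():
        if tx not in ingroup:
            continue
        if all(c in "-?N" for c in seq):
            continue
        for m in re.finditer(r"-+", seq):
            a, b = m.span()
            if a == 0 or b == len(seq):
                continue
            if b - a < min_length:
                continue
            shared.setdefault((a, b), set()).add(tx)
    return {k: v for k, v in shared.items() if len(v) >= min_taxa}


# ---------------------------------------------------------------------------
# Smith-Waterman, plain dynamic program (scores only)
# ---------------------------------------------------------------------------

def smith_waterman_score(a: str, b: str, match: float = 1.0,
                         mismatch: float = -1.5, gap_open: float = -3.0,
                         gap_extend: float = -1.0) -> float:
    """Best local alignment score with affine gaps (Gotoh)."""
    n, m = len(a), len(b)
    NEG = -1e18
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] + gap_open, E[i, j - 1] + gap_extend)
            F[i, j] = max(H[i - 1, j] + gap_open, F[i - 1, j] + gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i, j] = max(0.0, H[i - 1, j - 1] + s, E[i, j], F[i, j])
            best = max(best, H[i, j])
    return best


# ---------------------------------------------------------------------------
# random additive trees
# ---------------------------------------------------------------------------

def random_additive_matrix(n: int, rng: np.random.Generator
                           ) -> Tuple[np.ndarray, List[str], Set[frozenset]]:
    """Random binary unrooted tree with branch lengths in [0.1, 2];
    returns its path-distance matrix, labels, and non-trivial splits."""
    labels = [f"x{i:02d}" for i in range(n)]
    # grow an unrooted tree by subdividing random edges
    # adjacency: node -> list of (nbr, length)
    adj: Dict[int, List[Tuple[int, float]]] = {0: [], 1: []}
    leaf_of = {0: labels[0], 1: labels[1]}
    edges: List[Tuple[int, int]] = [(0, 1)]
    lengths: Dict[Tuple[int, int], float] = {(0, 1): rng.uniform(0.1, 2.0)}
    next_id = 2

    def add_edge(u, v, w):
        lengths[(u, v)] = w
        lengths[(v, u)] = w

    add_edge(0, 1, lengths[(0, 1)])
    for k in range(2, n):
        u, v = edges[rng.integers(len(edges))]
        mid, leaf = next_id, next_id + 1
        next_id += 2
        leaf_of[leaf] = labels[k]
        w = lengths[(u, v)]
        cut = rng.uniform(0.2, 0.8) * w
        edges.remove((u, v))
        edges.extend([(u, mid), (mid, v), (mid, leaf)])
        add_edge(u, mid, max(cut, 0.1))
        add_edge(mid, v, max(w - cut, 0.1))
        add_edge(mid, leaf, rng.uniform(0.1, 2.0))

    # adjacency from edge list
    nbrs: Dict[int, List[int]] = {}
    for u, v in edges:
        nbrs.setdefault(u, []).append(v)
        nbrs.setdefault(v, []).append(u)

    # path distances between leaves
    leaf_ids = sorted(leaf_of)
    D = np.zeros((n, n))
    for i, li in enumerate(leaf_ids):
        dist = {li: 0.0}
        stack = [li]
        while stack:
            u = stack.pop()
            for v in nbrs[u]:
                if v not in dist:
                    dist[v] = dist[u] + lengths[(u, v)]
                    stack.append(v)
        for j, lj in enumerate(leaf_ids):
            D[i, j] = dist[lj]
    ordered = [leaf_of[l] for l in leaf_ids]

    # splits: removing each internal edge
    all_set = frozenset(labels)
    anchor = min(labels)
    splits: Set[frozenset] = set()
    for u, v in edges:
        if u in leaf_of or v in leaf_of:
            continue
        side = set()
        stack = [u]
        seen = {u, v}
        while stack:
            x = stack.pop()
            if x in leaf_of:
                side.add(leaf_of[x])
            for y in nbrs[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        if 1 < len(side) < n - 1:
            s = frozenset(side)
            splits.add(s if anchor not in s else all_set - s)
    # reorder matrix rows to label order
    perm = np.argsort(ordered)
    ordered_sorted = [ordered[i] for i in perm]
    D = D[np.ix_(perm, perm)]
    return D, ordered_sorted, splits
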