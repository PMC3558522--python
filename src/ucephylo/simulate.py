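"""Synthetic data generator for UCE target-enrichment pipelines.

Produces, with known truth: a rapid-radiation species tree (long terminal
branches, short internodes), multispecies-coalescent gene trees, UCE-like
locus alignments (conserved core, variable flanks, deletion-type indels),
and per-taxon contigs with locus dropout and chimeric paralogs.

Branch lengths are in coalescent units throughout; sequence divergence per
branch is ``branch_length * subst_rate`` multiplied by the two-tier
core/flank site-rate profile. Substitution model is HKY85 with configurable
kappa and base frequencies. Indels are deletions only, so true column
homology is preserved in the emitted alignments.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd

from ._seq import BASES, decode
from .matrix import LocusAlignment


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Study-condition knobs for the synthetic data generator.

    Defaults emulate the avian UCE enrichment regime this package targets:
    33 taxa (32 ingroup + 1 deep outgroup), 1,541 loci of mean length 350 bp,
    13% per-taxon-per-locus dropout (an ~87%-complete matrix), and a ~2%
    chimeric-paralog injection rate.
    """

    n_taxa: int = 33
    n_loci: int = 1541
    birth_rate: float = 1.0
    internal_branch_scale: float = 0.1
    min_internal_branch: float = 0.0
    locus_length_mean: float = 350.0
    locus_length_sd: float = 80.0
    core_fraction: float = 0.34
    core_rate: float = 0.05
    flank_rate: float = 1.0
    subst_rate: float = 0.02
    kappa: float = 3.0
    base_freqs: Tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3)
    indel_rate: float = 0.3
    indel_len_min: int = 2
    indel_len_max: int = 10
    indel_branches: str = "all"  # "all" | "internal"
    dropout_prob: float = 0.13
    paralog_prob: float = 0.02
    outgroup_name: Optional[str] = "OUT"
    outgroup_stem: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 4:
            raise ValueError("n_taxa must be >= 4")
        for name in ("birth_rate", "internal_branch_scale", "core_rate",
                     "flank_rate", "subst_rate", "indel_rate", "kappa",
                     "locus_length_mean", "locus_length_sd", "outgroup_stem",
                     "min_internal_branch"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("core_fraction", "dropout_prob", "paralog_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.indel_len_min < 2:
            raise ValueError("indel_len_min must be >= 2")
        if self.indel_len_max < self.indel_len_min:
            raise ValueError("indel_len_max must be >= indel_len_min")
        if self.indel_branches not in ("all", "internal"):
            raise ValueError("indel_branches must be 'all' or 'internal'")
        if abs(sum(self.base_freqs) - 1.0) > 1e-8:
            raise ValueError("base_freqs must sum to 1")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in d.items() if k in known}
        if "base_freqs" in kwargs:
            kwargs["base_freqs"] = tuple(kwargs["base_freqs"])
        return cls(**kwargs)


@dataclass
class IndelTruth:
    """A simulated deletion event: taxa descending from the event's branch
    share an identical gap run over [start, end)."""

    locus_id: str
    start: int
    end: int
    taxa: frozenset

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TruthTable:
    species_tree: dendropy.Tree
    gene_trees: List[dendropy.Tree]
    presence: pd.DataFrame  # taxa x loci, bool
    paralog_injections: List[Tuple[str, str, str, str]]  # taxon, contig, locus_i, locus_j
    indel_events: List[IndelTruth] = field(default_factory=list)


@dataclass
class SimulatedData:
    config: SimulationConfig
    taxa: List[str]
    locus_ids: List[str]
    reference: Dict[str, str]  # locus -> ancestral (root) sequence, ungapped
    alignments: List[LocusAlignment]  # dropout applied; rows only for present taxa
    contigs: Dict[str, Dict[str, str]]  # taxon -> contig_id -> sequence
    truth: TruthTable


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------

def simulate_species_tree(
    n_taxa: int,
    birth_rate: float = 1.0,
    seed: int = 0,
    *,
    internal_branch_scale: float = 1.0,
    min_internal_branch: float = 0.0,
    taxon_prefix: str = "t",
) -> dendropy.Tree:
    """Yule (pure-birth) species tree with branch lengths in coalescent units.

    Internal branch lengths are multiplied by ``internal_branch_scale`` after
    the Yule draw (and floored at ``min_internal_branch``), which is how the
    rapid-radiation regime of short internodes under long terminal branches
    is produced. Deterministic given ``seed``.
    """
    if n_taxa < 3:
        raise ValueError("n_taxa must be >= 3")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    rng = np.random.default_rng(seed)

    # each node: [split_time or None, parent_index, child_a, child_b]
    nodes: List[list] = [[0.0, -1, -1, -1]]  # root splits at time 0
    active = []
    for _ in range(2):
        nodes.append([None, 0, -1, -1])
        active.append(len(nodes) - 1)
    nodes[0][2], nodes[0][3] = active[0], active[1]

    t = 0.0
    while len(active) < n_taxa:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        pick = int(rng.integers(k))
        idx = active.pop(pick)
        nodes[idx][0] = t
        for slot in (2, 3):
            nodes.append([None, idx, -1, -1])
            nodes[idx][slot] = len(nodes) - 1
            active.append(len(nodes) - 1)
    t_present = t + rng.exponential(1.0 / (birth_rate * n_taxa))

    width = max(2, len(str(n_taxa)))
    labels = {idx: f"{taxon_prefix}{i + 1:0{width}d}" for i, idx in enumerate(active)}

    tns = dendropy.TaxonNamespace(sorted(labels.values()))
    tree = dendropy.Tree(taxon_namespace=tns)

    def build(idx: int, dnode: dendropy.Node) -> None:
        split, parent, ca, cb = nodes[idx]
        if ca == -1:  # leaf
            dnode.taxon = tns.get_taxon(labels[idx])
            end_time = t_present
        else:
            end_time = split
            for c in (ca, cb):
                build(c, dnode.new_child())
        if parent >= 0:
            raw = end_time - nodes[parent][0]
            if ca == -1:
                dnode.edge.length = max(raw, 1e-9)
            else:
                dnode.edge.length = max(raw * internal_branch_scale,
                                        min_internal_branch, 1e-9)

    build(0, tree.seed_node)
    return tree


def attach_outgroup(tree: dendropy.Tree, name: str = "OUT",
                    stem_length: float = 5.0) -> dendropy.Tree:
    """Attach a deep outgroup as sister to the whole tree.

    The new root sits ``stem_length`` coalescent units above the old root, so
    the outgroup lineage diverges long before the ingroup radiation.
    """
    taxa = [t.label for t in tree.taxon_namespace] + [name]
    tns = dendropy.TaxonNamespace(sorted(taxa))
    new = dendropy.Tree(taxon_namespace=tns)
    old_newick = tree.as_string(schema="newick").strip()
    ingroup = dendropy.Tree.get(data=old_newick, schema="newick",
                                taxon_namespace=tns)
    h = max(leaf.distance_from_root() for leaf in ingroup.leaf_node_iter())
    root = new.seed_node
    og = root.new_child()
    og.taxon = tns.get_taxon(name)
    og.edge.length = h + stem_length
    root.add_child(ingroup.seed_node)
    ingroup.seed_node.edge.length = stem_length
    return new


def node_ages(tree: dendropy.Tree) -> Dict[dendropy.Node, float]:
    """Age of each node = distance above its deepest descendant tip."""
    ages: Dict[dendropy.Node, float] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            ages[node] = 0.0
        else:
            ages[node] = max(ages[c] + (c.edge.length or 0.0)
                             for c in node.child_nodes())
    return ages


# ---------------------------------------------------------------------------
# multispecies coalescent
# ---------------------------------------------------------------------------

class _GNode:
    __slots__ = ("taxon", "children", "height")

    def __init__(self, taxon=None, children=(), height=0.0):
        self.taxon = taxon
        self.children = list(children)
        self.height = height


def _coalesce(lineages: List[_GNode], t0: float, duration: float,
              rng: np.random.Generator) -> List[_GNode]:
    """Run the coalescent (rate k(k-1)/2 per unit time) within one branch."""
    t = t0
    lineages = list(lineages)
    while len(lineages) > 1:
        k = len(lineages)
        wait = rng.exponential(2.0 / (k * (k - 1)))
        if t + wait > t0 + duration:
            break
        t += wait
        i, j = sorted(rng.choice(k, size=2, replace=False))
        b = lineages.pop(j)
        a = lineages.pop(i)
        lineages.append(_GNode(children=(a, b), height=t))
    return lineages


def simulate_gene_tree(species_tree: dendropy.Tree,
                       rng: np.random.Generator) -> dendropy.Tree:
    """One rooted gene tree under the multispecies coalescent, one sampled
    lineage per species. Unfinished lineages merge above the species root."""
    ages = node_ages(species_tree)
    pending: Dict[dendropy.Node, List[_GNode]] = {}
    for node in species_tree.postorder_node_iter():
        if node.is_leaf():
            exiting = [_GNode(taxon=node.taxon.label, height=ages[node])]
        else:
            incoming: List[_GNode] = []
            for child in node.child_nodes():
                dur = child.edge.length
                if dur is None or dur <= 0:
                    raise ValueError(
                        "species tree has a non-positive branch length")
                incoming.extend(_coalesce(pending.pop(child), ages[child],
                                          dur, rng))
            exiting = incoming
        if node.parent_node is None:
            # ancestral population above the root: coalesce to completion
            t = ages[node]
            while len(exiting) > 1:
                k = len(exiting)
                t += rng.exponential(2.0 / (k * (k - 1)))
                i, j = sorted(rng.choice(k, size=2, replace=False))
                b = exiting.pop(j)
                a = exiting.pop(i)
                exiting.append(_GNode(children=(a, b), height=t))
            root = exiting[0]
        else:
            pending[node] = exiting

    tns = species_tree.taxon_namespace
    gtree = dendropy.Tree(taxon_namespace=tns)

    def build(g: _GNode, dnode: dendropy.Node) -> None:
        if g.taxon is not None:
            dnode.taxon = tns.get_taxon(g.taxon)
        for c in g.children:
            child = dnode.new_child()
            child.edge.length = max(g.height - c.height, 1e-12)
            build(c, child)

    build(root, gtree.seed_node)
    return gtree


def simulate_gene_trees(species_tree: dendropy.Tree, n_loci: int,
                        seed: int = 0) -> List[dendropy.Tree]:
    """``n_loci`` independent coalescent gene trees (per-locus RNG substreams,
    so locus i's tree does not depend on n_loci)."""
    if n_loci < 0:
        raise ValueError("n_loci must be >= 0")
    return [simulate_gene_tree(species_tree,
                               np.random.default_rng([seed, 11, i]))
            for i in range(n_loci)]


# ---------------------------------------------------------------------------
# sequence evolution (HKY85, two-tier core/flank rates, deletion indels)
# ---------------------------------------------------------------------------

def hky_eigensystem(kappa: float, freqs: Sequence[float]):
    """Eigendecomposition of the HKY85 rate matrix, normalised to one
    expected substitution per unit time at stationarity."""
    pi = np.asarray(freqs, dtype=float)
    Q = np.empty((4, 4))
    # order A C G T; transitions: A<->G (0,2), C<->T (1,3)
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            rate = kappa if (i, j) in ((0, 2), (2, 0), (1, 3), (3, 1)) else 1.0
            Q[i, j] = rate * pi[j]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -np.dot(pi, np.diag(Q))
    Q /= mu
    sq = np.sqrt(pi)
    B = (Q * sq[:, None]) / sq[None, :]
    w, U = np.linalg.eigh((B + B.T) / 2.0)
    return w, U, sq


def hky_transition_matrix(t: float, eig) -> np.ndarray:
    w, U, sq = eig
    M = (U * np.exp(w * t)) @ U.T
    P = (M / sq[:, None]) * sq[None, :]
    P = np.clip(P, 0.0, None)
    P /= P.sum(axis=1, keepdims=True)
    return P


def _sample_children(parent: np.ndarray, P: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    cum = np.cumsum(P, axis=1)
    cum[:, -1] = 1.0
    r = rng.random(parent.shape[0])
    child = np.empty_like(parent)
    for s in range(4):
        m = parent == s
        if m.any():
            child[m] = np.searchsorted(cum[s], r[m], side="right")
    return np.minimum(child, 3)


def evolve_locus(
    gene_tree: dendropy.Tree,
    config: SimulationConfig,
    locus_index: int,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[LocusAlignment, str, List[IndelTruth]]:
    """Evolve one locus along a gene tree.

    Returns the gapped alignment over all tree taxa, the ungapped ancestral
    (root) sequence, and the list of deletion events. Column homology is
    exact: deletions insert gap runs, never new columns, and events within a
    locus are kept column-disjoint with non-gap flanks so each event is a
    recoverable maximal gap run.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 1000003, locus_index])
    locus_id = f"uce-{locus_index + 1:05d}"

    L = int(round(rng.normal(config.locus_length_mean, config.locus_length_sd)))
    L = max(L, config.indel_len_max + 6, 40)

    core_len = int(round(config.core_fraction * L))
    core_start = (L - core_len) // 2
    is_core = np.zeros(L, dtype=bool)
    is_core[core_start:core_start + core_len] = True
    if core_len and config.core_rate != config.flank_rate:
        classes = [(config.core_rate, np.flatnonzero(is_core)),
                   (config.flank_rate, np.flatnonzero(~is_core))]
    else:
        classes = [(config.flank_rate, np.arange(L))]

    eig = hky_eigensystem(config.kappa, config.base_freqs)
    pi = np.asarray(config.base_freqs)

    root_states = rng.choice(4, size=L, p=pi).astype(np.uint8)
    states: Dict[dendropy.Node, np.ndarray] = {gene_tree.seed_node: root_states}
    edges = []
    for node in gene_tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        t = (node.edge.length or 0.0) * config.subst_rate
        parent = states[node.parent_node]
        child = parent.copy()
        for rate, idx in classes:
            if len(idx) == 0:
                continue
            if rate * t > 0:
                P = hky_transition_matrix(rate * t, eig)
                child[idx] = _sample_children(parent[idx], P, rng)
        states[node] = child
        edges.append(node)

    # deletion events
    taxa_below = {}
    for node in gene_tree.postorder_node_iter():
        if node.is_leaf():
            taxa_below[node] = frozenset([node.taxon.label])
        else:
            taxa_below[node] = frozenset().union(
                *(taxa_below[c] for c in node.child_nodes()))

    if config.indel_branches == "internal":
        eligible = [n for n in edges if not n.is_leaf()]
    else:
        eligible = edges
    events: List[IndelTruth] = []
    n_events = rng.poisson(config.indel_rate) if config.indel_rate > 0 else 0
    if n_events and eligible:
        weights = np.array([n.edge.length or 0.0 for n in eligible])
        weights = weights / weights.sum()
        occupied = np.zeros(L, dtype=bool)
        for _ in range(n_events):
            node = eligible[int(rng.choice(len(eligible), p=weights))]
            length = int(rng.integers(config.indel_len_min,
                                      config.indel_len_max + 1))
            placed = False
            for _try in range(100):
                start = int(rng.integers(1, L - length))
                if not occupied[start - 1:start + length + 1].any():
                    placed = True
                    break
            if not placed:
                continue
            occupied[start:start + length] = True
            events.append(IndelTruth(locus_id, start, start + length,
                                     taxa_below[node]))

    gap = {}
    for ev in events:
        for tx in ev.taxa:
            gap.setdefault(tx, []).append((ev.start, ev.end))

    seqs: Dict[str, str] = {}
    for leaf in gene_tree.leaf_node_iter():
        tx = leaf.taxon.label
        s = list(decode(states[leaf]))
        for a, b in gap.get(tx, ()):  # apply deletions
            s[a:b] = "-" * (b - a)
        seqs[tx] = "".join(s)

    return (LocusAlignment(locus_id, seqs, L), decode(root_states), events)


# ---------------------------------------------------------------------------
# contigs with dropout and chimeric paralogs
# ---------------------------------------------------------------------------

def make_contigs(
    alignments: List[LocusAlignment],
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[Dict[str, Dict[str, str]], pd.DataFrame,
           List[Tuple[str, str, str, str]]]:
    """Per-taxon ungapped contigs with locus dropout and chimeric paralogs.

    A chimeric paralog is the 5' half of one locus' contig joined to the 3'
    half of another locus' contig from the same taxon, so it shows
    above-threshold similarity to two reference loci (exercising the
    multi-locus duplicate filter). Returns (contigs, presence, injections).
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 4])
    taxa = sorted({tx for aln in alignments for tx in aln.sequences})
    locus_ids = [aln.locus_id for aln in alignments]
    keep = rng.random((len(taxa), len(locus_ids))) >= config.dropout_prob
    presence = pd.DataFrame(keep, index=taxa, columns=locus_ids)

    ungapped = {
        (tx, aln.locus_id): aln.sequences[tx].replace("-", "")
        for aln in alignments for tx in aln.sequences
    }

    contigs: Dict[str, Dict[str, str]] = {tx: {} for tx in taxa}
    injections: List[Tuple[str, str, str, str]] = []
    for ti, tx in enumerate(taxa):
        n = 0
        present = [lid for li, lid in enumerate(locus_ids) if keep[ti, li]]
        for lid in present:
            n += 1
            contigs[tx][f"{tx}_c{n:05d}"] = ungapped[(tx, lid)]
        if config.paralog_prob > 0:
            for lid in present:
                if rng.random() >= config.paralog_prob:
                    continue
                others = [x for x in present if x != lid]
                if not others:
                    continue
                partner = others[int(rng.integers(len(others)))]
                a = ungapped[(tx, lid)]
                b = ungapped[(tx, partner)]
                chimera = a[: len(a) // 2] + b[len(b) // 2:]
                n += 1
                cid = f"{tx}_c{n:05d}"
                contigs[tx][cid] = chimera
                injections.append((tx, cid, lid, partner))
    return contigs, presence, injections


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimulationConfig) -> SimulatedData:
    """Generate a complete synthetic dataset: species tree, gene trees,
    reference loci, per-locus alignments (dropout applied), contigs, truth."""
    n_ingroup = config.n_taxa - (1 if config.outgroup_name else 0)
    sp = simulate_species_tree(
        n_ingroup, config.birth_rate, seed=[config.seed, 0],
        internal_branch_scale=config.internal_branch_scale,
        min_internal_branch=config.min_internal_branch)
    if config.outgroup_name:
        sp = attach_outgroup(sp, config.outgroup_name, config.outgroup_stem)
    gene_trees = simulate_gene_trees(sp, config.n_loci, seed=config.seed)

    full_alignments: List[LocusAlignment] = []
    reference: Dict[str, str] = {}
    all_events: List[IndelTruth] = []
    for i, gt in enumerate(gene_trees):
        aln, ref, events = evolve_locus(gt, config, i)
        full_alignments.append(aln)
        reference[aln.locus_id] = ref
        all_events.extend(events)

    contigs, presence, injections = make_contigs(full_alignments, config)

    taxa = list(presence.index)
    alignments = []
    for aln in full_alignments:
        rows = {tx: s for tx, s in aln.sequences.items()
                if presence.at[tx, aln.locus_id]}
        alignments.append(LocusAlignment(aln.locus_id, rows, aln.length))

    truth = TruthTable(species_tree=sp, gene_trees=gene_trees,
                       presence=presence, paralog_injections=injections,
                       indel_events=all_events)
    return SimulatedData(config=config, taxa=taxa,
                         locus_ids=[a.locus_id for a in full_alignments],
                         reference=reference, alignments=alignments,
                         contigs=contigs, truth=truth)
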