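"""STAR ranks, averaged distances, bootstrap support, and collapsing."""
import dendropy
import numpy as np
import pytest

from ucephylo.matrix import LocusAlignment
from ucephylo.simulate import (SimulationConfig, simulate_dataset,
                               simulate_species_tree)
from ucephylo.star import (average_rank_distance, collapse,
                           multilocus_bootstrap, rank_coalescences,
                           star_tree)
from ucephylo.trees import normalized_splits, same_topology


def _t(newick):
    return dendropy.Tree.get(data=newick, schema="newick")


def test_rank_assignment_asymmetric_four_taxon():
    rt = rank_coalescences(_t("(((A:1,B:1):1,C:2):1,D:3);"))
    assert sorted(rt.ranks.values()) == [1, 2, 3]
    assert rt.pair_distance("A", "B") == 2
    assert rt.pair_distance("A", "C") == 4
    assert rt.pair_distance("A", "D") == 6


def test_rank_assignment_three_taxon():
    rt = rank_coalescences(_t("((A:1,B:1):1,C:2);"))
    assert rt.pair_distance("A", "B") == 2
    assert rt.pair_distance("A", "C") == 4
    assert rt.pair_distance("B", "C") == 4


def test_root_mrca_distance_is_2n_minus_2():
    for n in (5, 9):
        sp = simulate_species_tree(n, seed=n)
        rt = rank_coalescences(sp)
        # pick taxa from the two sides of the root
        sides = [sorted(l.taxon.label for l in c.leaf_iter())
                 for c in sp.seed_node.child_nodes()]
        a, b = sides[0][0], sides[1][0]
        assert rt.pair_distance(a, b) == 2 * (n - 1)


def test_unrooted_or_multifurcating_rejected():
    with pytest.raises(ValueError):
        rank_coalescences(_t("(A:1,B:1,C:1);"))
    with pytest.raises(ValueError):
        rank_coalescences(_t("((A:1,B:1,C:1):1,D:1);"))


def test_star_three_taxon_worked_example():
    gts = [_t("((A:1,B:1):1,C:2);"), _t("((A:1,B:1):1,C:2);"),
           _t("((A:1,C:1):1,B:2);")]
    dm = average_rank_distance(gts)
    taxa = dm.taxa
    get = lambda x, y: dm.matrix[taxa.index(x), taxa.index(y)]
    assert get("A", "B") == pytest.approx(8 / 3)
    assert get("A", "C") == pytest.approx(10 / 3)
    assert get("B", "C") == pytest.approx(4.0)
    # the cherry of the species tree is the closest pair: (A,B)
    tree = star_tree(gts)
    assert get("A", "B") == min(get("A", "B"), get("A", "C"), get("B", "C"))
    assert sorted(l.taxon.label for l in tree.leaf_node_iter()) == \
        ["A", "B", "C"]


def test_star_single_gene_tree_is_identity():
    gt = _t("(((A:1,B:1):1,C:2):1,(D:1,E:1):2);")
    assert same_topology(star_tree([gt]), gt)


def test_star_identity_on_repeated_random_topologies():
    for n, seed in ((5, 1), (9, 2), (15, 3)):
        sp = simulate_species_tree(n, seed=seed)
        for count in (1, 3, 7):
            est = star_tree([sp] * count)
            assert same_topology(est, sp)


def test_average_matrix_bounds_and_symmetry():
    sp = simulate_species_tree(8, seed=4)
    dm = average_rank_distance([sp, sp, sp])
    n = len(dm.taxa)
    off = ~np.eye(n, dtype=bool)
    assert np.allclose(dm.matrix, dm.matrix.T)
    assert np.allclose(np.diag(dm.matrix), 0.0)
    assert (dm.matrix[off] >= 2.0 - 1e-9).all()
    assert (dm.matrix[off] <= 2.0 * (n - 1) + 1e-9).all()


def test_disconnected_pair_raises_naming_taxa():
    g1 = _t("((A:1,B:1):1,C:2);")
    g2 = _t("((D:1,E:1):1,F:2);")
    with pytest.raises(ValueError) as exc:
        star_tree([g1, g2])
    msg = str(exc.value)
    assert any(x in msg for x in "ABC") and any(x in msg for x in "DEF")


def test_label_permutation_equivariance():
    sp = simulate_species_tree(7, seed=9)
    labels = sorted(l.taxon.label for l in sp.leaf_node_iter())
    mapping = dict(zip(labels, labels[1:] + labels[:1]))
    relabeled = _t(sp.as_string(schema="newick"))
    for leaf in relabeled.leaf_node_iter():
        leaf.taxon = dendropy.Taxon(mapping[leaf.taxon.label])
    est = star_tree([sp])
    est_rel = star_tree([relabeled])
    mapped = {frozenset(mapping[x] for x in s) for s in normalized_splits(est)}
    # re-canonicalise mapped splits against the full taxon set
    full = frozenset(mapping.values())
    anchor = min(full)
    mapped = {s if anchor in (full - s) else full - s for s in mapped}
    mapped = {s if anchor not in s else full - s for s in mapped}
    assert mapped == normalized_splits(est_rel)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def _resolving_alignment():
    """One locus that strongly resolves ((A,B),(C,D)) with outgroup O."""
    rows = {
        "A": "AAAAAAAAAACCCCCCCCCCGGGGGGGGGG" * 10,
        "B": "AAAAAAAAAACCCCCCCCCCGGGGGGGGGT" * 10,
        "C": "TTTTTTTTTTCCCCCCCCCCGGGGGGGGGG" * 10,
        "D": "TTTTTTTTTTCCCCCCCCCCGGGGGGGGGT" * 10,
        "O": "TTTTTTTTTTAAAAAAAAAAGGGGGGGGGG" * 10,
    }
    return LocusAlignment("L", rows)


def test_identical_strong_loci_give_full_support():
    aln = _resolving_alignment()
    loci = [LocusAlignment(f"L{i}", aln.sequences) for i in range(6)]
    res = multilocus_bootstrap(loci, 10, seed=3, outgroup="O")
    assert res.support
    assert all(v == 100.0 for v in res.support.values())


def test_single_replicate_support_is_binary():
    cfg = SimulationConfig(n_taxa=6, n_loci=10, seed=17,
                           locus_length_mean=200, locus_length_sd=0.0,
                           dropout_prob=0.0, paralog_prob=0.0,
                           subst_rate=0.02, indel_rate=0.0)
    data = simulate_dataset(cfg)
    res = multilocus_bootstrap(data.alignments, 1, seed=5, outgroup="OUT")
    assert set(res.support.values()) <= {0.0, 100.0}


def test_bootstrap_rejects_empty_and_is_deterministic():
    with pytest.raises(ValueError):
        multilocus_bootstrap([], 10, seed=0, outgroup="O")
    aln = _resolving_alignment()
    loci = [LocusAlignment(f"L{i}", aln.sequences) for i in range(4)]
    r1 = multilocus_bootstrap(loci, 7, seed=11, outgroup="O")
    r2 = multilocus_bootstrap(loci, 7, seed=11, outgroup="O")
    assert r1.support == r2.support
    assert r1.tree.as_string(schema="newick") == \
        r2.tree.as_string(schema="newick")


def test_support_tallies_match_bruteforce_counter():
    cfg = SimulationConfig(n_taxa=6, n_loci=12, seed=23,
                           locus_length_mean=150, locus_length_sd=0.0,
                           internal_branch_scale=0.3, dropout_prob=0.0,
                           paralog_prob=0.0, subst_rate=0.03, indel_rate=0.0)
    data = simulate_dataset(cfg)
    res = multilocus_bootstrap(data.alignments, 25, seed=2, outgroup="OUT",
                               keep_replicates=True)
    assert len(res.replicate_splits) == 25
    for split, pct in res.support.items():
        count = sum(split in reps for reps in res.replicate_splits)
        assert pct == pytest.approx(100.0 * count / 25)


def test_collapse_thresholds():
    tree = _t("((((A,B)95,C)35,D),E);")
    unchanged = collapse(tree, 0.0)
    assert len(normalized_splits(unchanged)) == len(normalized_splits(tree))
    comb = collapse(tree, 101.0)
    assert normalized_splits(comb) == set()
    partial = collapse(tree, 40.0)
    # exactly the support-35 node is contracted, creating one degree-3 node
    assert len(normalized_splits(partial)) == \
        len(normalized_splits(tree)) - 1
    assert sum(1 for n in partial.preorder_internal_node_iter()
               if len(n.child_nodes()) == 3) == 1
    assert sum(1 for _ in partial.leaf_node_iter()) == 5
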