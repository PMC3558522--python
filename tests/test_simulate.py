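"""Generator behaviour: tree shapes, coalescent frequencies, locus
structure, contigs, and determinism."""
import dendropy
import numpy as np
import pytest

from ucephylo.simulate import (IndelTruth, SimulationConfig, evolve_locus,
                               make_contigs, simulate_dataset,
                               simulate_gene_trees, simulate_species_tree)
from ucephylo.trees import normalized_splits, same_topology


@pytest.mark.parametrize("n_taxa", [3, 8, 33])
def test_species_tree_shape(n_taxa):
    tree = simulate_species_tree(n_taxa, seed=1)
    tips = sum(1 for _ in tree.leaf_node_iter())
    internals = sum(1 for _ in tree.preorder_internal_node_iter())
    assert tips == n_taxa
    assert internals == n_taxa - 1  # root included
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node:
            assert edge.length > 0


def test_species_tree_33_tips_has_31_nonroot_internal_nodes():
    """A fully resolved rooted tree on 33 tips has 31 internal nodes below
    the root — the node count over which support is tallied at that
    taxon sampling."""
    tree = simulate_species_tree(33, seed=7)
    non_root = sum(1 for n in tree.preorder_internal_node_iter()
                   if n is not tree.seed_node)
    assert non_root == 31


def test_species_tree_determinism():
    a = simulate_species_tree(10, seed=5).as_string(schema="newick")
    b = simulate_species_tree(10, seed=5).as_string(schema="newick")
    c = simulate_species_tree(10, seed=6).as_string(schema="newick")
    assert a == b
    assert a != c


def test_species_tree_rejects_tiny():
    with pytest.raises(ValueError):
        simulate_species_tree(2, seed=0)


def test_gene_trees_empty_and_leafsets():
    sp = simulate_species_tree(6, seed=3)
    assert simulate_gene_trees(sp, 0, seed=0) == []
    gts = simulate_gene_trees(sp, 4, seed=0)
    sp_leaves = {l.taxon.label for l in sp.leaf_node_iter()}
    for gt in gts:
        assert {l.taxon.label for l in gt.leaf_node_iter()} == sp_leaves


def test_gene_trees_concordant_when_internodes_deep():
    sp = simulate_species_tree(8, seed=2, internal_branch_scale=1000.0)
    gts = simulate_gene_trees(sp, 20, seed=9)
    assert all(same_topology(gt, sp) for gt in gts)


def test_gene_trees_reject_nonpositive_branch():
    sp = simulate_species_tree(5, seed=1)
    for node in sp.preorder_node_iter():
        if node.parent_node is not None and not node.is_leaf():
            node.edge.length = 0.0
            break
    with pytest.raises(ValueError):
        simulate_gene_trees(sp, 1, seed=0)


def test_quartet_minor_topology_frequency_matches_closed_form():
    """For an asymmetric 4-taxon species tree with internal branch t above
    the cherry, each minor quartet topology appears with frequency e^-t/3
    (no coalescence on the branch, then a uniformly random resolution)."""
    t = 0.1
    sp = dendropy.Tree.get(
        data=f"(((A:1.0,B:1.0):{t},C:1.1):1.0,D:2.1);", schema="newick")
    n = 3000
    gts = simulate_gene_trees(sp, n, seed=42)
    anchor_partner = {"B": 0, "C": 0, "D": 0}
    for gt in gts:
        (split,) = normalized_splits(gt)  # side without taxon A
        partner = ({"B", "C", "D"} - set(split)).pop()
        anchor_partner[partner] += 1
    p_minor = np.exp(-t) / 3.0
    se = np.sqrt(p_minor * (1 - p_minor) / n)
    # A paired with C or with D are the two minor resolutions
    for minor in ("C", "D"):
        assert abs(anchor_partner[minor] / n - p_minor) < 3 * se


def test_concordance_monotone_in_internal_branch_scale():
    rates = []
    for scale in (0.05, 0.5, 5.0):
        hits = total = 0
        for seed in range(20):
            sp = simulate_species_tree(6, seed=seed,
                                       internal_branch_scale=scale)
            gts = simulate_gene_trees(sp, 5, seed=seed)
            hits += sum(same_topology(gt, sp) for gt in gts)
            total += len(gts)
        rates.append(hits / total)
    assert rates[0] <= rates[1] <= rates[2]
    assert rates[2] > rates[0]


def _tiny_config(**kw):
    base = dict(n_taxa=6, n_loci=2, seed=13, locus_length_mean=120,
                locus_length_sd=0.0, subst_rate=0.02,
                internal_branch_scale=1.0)
    base.update(kw)
    return SimulationConfig(**base)


def test_zero_core_rate_freezes_core_columns():
    cfg = _tiny_config(core_rate=0.0, core_fraction=0.5, indel_rate=0.0)
    sp = simulate_species_tree(6, seed=1, internal_branch_scale=1.0)
    gt = simulate_gene_trees(sp, 1, seed=1)[0]
    aln, ref, _ = evolve_locus(gt, cfg, 0)
    L = aln.length
    core_len = round(0.5 * L)
    start = (L - core_len) // 2
    rows = list(aln.sequences.values())
    for col in range(start, start + core_len):
        assert len({r[col] for r in rows}) == 1
        assert rows[0][col] == ref[col]


def test_zero_indel_rate_means_no_gaps():
    cfg = _tiny_config(indel_rate=0.0)
    sp = simulate_species_tree(6, seed=2, internal_branch_scale=1.0)
    gt = simulate_gene_trees(sp, 1, seed=2)[0]
    aln, _, events = evolve_locus(gt, cfg, 0)
    assert events == []
    assert all("-" not in s for s in aln.sequences.values())


def test_indel_events_are_exact_shared_runs():
    """Every recorded event is an identical-boundary gap run in exactly the
    event's taxa, with non-gap flanking columns; stripping gaps and
    re-inserting the recorded events reproduces each row exactly."""
    cfg = _tiny_config(indel_rate=3.0, locus_length_mean=300)
    sp = simulate_species_tree(6, seed=3, internal_branch_scale=1.0)
    gt = simulate_gene_trees(sp, 1, seed=3)[0]
    aln, _, events = evolve_locus(gt, cfg, 0)
    assert events, "expected at least one event at rate 3"
    for ev in events:
        for tx, seq in aln.sequences.items():
            run = seq[ev.start:ev.end]
            if tx in ev.taxa:
                assert run == "-" * ev.length
                assert seq[ev.start - 1] != "-" and seq[ev.end] != "-"
            else:
                assert "-" not in run
    # round trip: strip gaps, re-insert recorded events
    for tx, seq in aln.sequences.items():
        rebuilt = list(seq.replace("-", ""))
        for ev in sorted((e for e in events if tx in e.taxa),
                         key=lambda e: e.start):
            rebuilt[ev.start:ev.start] = "-" * ev.length
        assert "".join(rebuilt) == seq


def test_make_contigs_extremes():
    cfg = _tiny_config(dropout_prob=0.0, paralog_prob=0.0, indel_rate=0.0)
    data = simulate_dataset(cfg)
    assert data.truth.presence.values.all()
    assert sum(len(c) for c in data.contigs.values()) == 6 * 2

    cfg_all = _tiny_config(dropout_prob=1.0, paralog_prob=0.0)
    data_all = simulate_dataset(cfg_all)
    assert sum(len(c) for c in data_all.contigs.values()) == 0
    assert not data_all.truth.presence.values.any()


def test_dropout_rate_matches_binomial_expectation():
    fractions = []
    for seed in range(10):
        cfg = SimulationConfig(n_taxa=10, n_loci=50, seed=seed,
                               dropout_prob=0.13, locus_length_mean=60,
                               locus_length_sd=0.0, indel_rate=0.0)
        data = simulate_dataset(cfg)
        fractions.append(data.truth.presence.values.mean())
    n = 10 * 50 * 10
    se = np.sqrt(0.87 * 0.13 / n)
    assert abs(np.mean(fractions) - 0.87) < 3 * se


def test_dataset_seed_determinism():
    cfg = _tiny_config(dropout_prob=0.2, paralog_prob=0.1, indel_rate=0.5)
    d1 = simulate_dataset(cfg)
    d2 = simulate_dataset(cfg)
    assert d1.contigs == d2.contigs
    assert [a.sequences for a in d1.alignments] == \
        [a.sequences for a in d2.alignments]
    assert d1.truth.species_tree.as_string(schema="newick") == \
        d2.truth.species_tree.as_string(schema="newick")


def test_paralog_injections_are_recorded_chimeras():
    cfg = _tiny_config(n_loci=10, dropout_prob=0.0, paralog_prob=0.3,
                       indel_rate=0.0)
    data = simulate_dataset(cfg)
    assert data.truth.paralog_injections
    for taxon, cid, li, lj in data.truth.paralog_injections:
        chimera = data.contigs[taxon][cid]
        a = next(x for x in data.alignments if x.locus_id == li
                 ).sequences[taxon].replace("-", "")
        b = next(x for x in data.alignments if x.locus_id == lj
                 ).sequences[taxon].replace("-", "")
        assert chimera == a[: len(a) // 2] + b[len(b) // 2:]
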