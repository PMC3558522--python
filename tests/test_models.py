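"""Likelihoods, distances, and AICc model selection."""
import numpy as np
import pytest

from ucephylo.matrix import LocusAlignment
from ucephylo.models import (MODEL_NAMES, NoSharedSitesError,
                             SubstitutionModel, TooFewTaxaError,
                             TreeLikelihood, aic_score, aicc_score,
                             candidate_models, fit_all_models, fit_model,
                             group_into_partitions, log_likelihood,
                             pairwise_distance, select_model_aicc)
from ucephylo.simulate import SimulationConfig, simulate_dataset
from ucephylo.trees import Clade

from _oracles import enumeration_log_likelihood

JC = SubstitutionModel("JC69")


def _cherry(bl_a, bl_b):
    return Clade(children=[(Clade(label="a"), bl_a), (Clade(label="b"), bl_b)])


def test_identity_column_zero_path_length():
    aln = LocusAlignment("L", {"a": "A", "b": "A"})
    lnl = log_likelihood(aln, _cherry(0.0, 0.0), JC)
    assert lnl == pytest.approx(np.log(0.25), abs=1e-10)


def test_two_state_jc_closed_form():
    t = 0.3041
    aln = LocusAlignment("L", {"a": "A", "b": "G"})
    expected = np.log(0.25 * (0.25 - 0.25 * np.exp(-4.0 * t / 3.0)))
    lnl = log_likelihood(aln, _cherry(t / 2.0, t / 2.0), JC)
    assert lnl == pytest.approx(expected, abs=1e-10)


def test_missing_states_are_uninformative():
    aln = LocusAlignment("L", {"a": "A?", "b": "AN"})
    t = _cherry(0.1, 0.1)
    one = log_likelihood(LocusAlignment("L", {"a": "A", "b": "A"}), t, JC)
    assert log_likelihood(aln, t, JC) == pytest.approx(one + np.log(1.0))


def test_zero_length_alignment_rejected():
    with pytest.raises(ValueError):
        log_likelihood(LocusAlignment("L", {"a": "", "b": ""}),
                       _cherry(0.1, 0.1), JC)


def _random_clade(labels, rng):
    nodes = [Clade(label=l) for l in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(Clade(children=[(a, rng.uniform(0.02, 0.8)),
                                     (b, rng.uniform(0.02, 0.8))]))
    return nodes[0]


@pytest.mark.parametrize("model", [
    SubstitutionModel("JC69"),
    SubstitutionModel("HKY85", freqs=(0.35, 0.2, 0.15, 0.3), kappa=3.0),
    SubstitutionModel("GTR", freqs=(0.3, 0.25, 0.25, 0.2),
                      rates=(1.2, 2.5, 0.7, 1.1, 3.0, 1.0)),
    SubstitutionModel("K80+G4", kappa=2.0, alpha=0.7),
])
def test_pruning_equals_enumeration(model, rng):
    for ntips in (3, 4, 5):
        labels = [chr(97 + i) for i in range(ntips)]
        tree = _random_clade(labels, rng)
        ncols = int(rng.integers(2, 5))
        rows = {l: "".join("ACGT?"[j] for j in rng.integers(0, 5, ncols))
                for l in labels}
        aln = LocusAlignment("L", rows)
        assert log_likelihood(aln, tree, model) == pytest.approx(
            enumeration_log_likelihood(rows, tree, model), abs=1e-8)


def test_aicc_formula_value():
    assert aicc_score(-50.0, 5, 100) == pytest.approx(100 + 10 + 60 / 94)
    assert aicc_score(-50.0, 5, 100) >= aic_score(-50.0, 5)
    with pytest.raises(ValueError):
        aicc_score(-50.0, 5, 6)


def test_aicc_geq_aic_generally():
    for k in (1, 3, 8):
        for n in (k + 2, 50, 1000):
            assert aicc_score(-10.0, k, n) >= aic_score(-10.0, k)


def test_pairwise_distance_closed_forms():
    assert pairwise_distance("ACGT", "ACGT") == 0.0
    # p = 0.25 under JC69
    d = pairwise_distance("AAAA", "AAAG")
    assert d == pytest.approx(-0.75 * np.log(1 - 4 * 0.25 / 3), abs=1e-12)
    # saturation: p >= 0.75 capped
    assert pairwise_distance("AAAA", "CCCG", max_distance=5.0) == 5.0
    # K80: every site a transition -> log argument <= 0 -> capped
    assert pairwise_distance("AAGG", "GGAA", model="K80") == 5.0
    with pytest.raises(NoSharedSitesError):
        pairwise_distance("A?", "?A")


def test_k80_distance_formula():
    # 2 transitions + 1 transversion in 8 sites: P=0.25, Q=0.125
    a = "AAAAAAAA"
    b = "GGCAAAAA"
    P, Q = 0.25, 0.125
    exp = -0.5 * np.log(1 - 2 * P - Q) - 0.25 * np.log(1 - 2 * Q)
    assert pairwise_distance(a, b, model="K80") == pytest.approx(exp, 1e-12)


def _sim_locus(seed, ncols=300, ntaxa=6, **kw):
    cfg = SimulationConfig(n_taxa=ntaxa, n_loci=1, seed=seed,
                           locus_length_mean=ncols, locus_length_sd=0.0,
                           core_fraction=0.0, indel_rate=0.0,
                           dropout_prob=0.0, paralog_prob=0.0,
                           internal_branch_scale=1.0, subst_rate=0.05, **kw)
    return simulate_dataset(cfg).alignments[0]


def test_nested_models_never_lose_likelihood():
    """JC < K80 < HKY85 < GTR: each added free parameter cannot decrease
    the optimised log-likelihood (small slack for the finite line search)."""
    order = ["JC69", "K80", "HKY85", "GTR"]
    for seed in range(10):
        aln = _sim_locus(seed, ncols=200)
        fits = {f.model.name: f.lnL
                for f in fit_all_models(aln, names=order)}
        for simple, rich in zip(order, order[1:]):
            assert fits[rich] >= fits[simple] - 0.05


def test_aic_fallback_when_sites_scarce():
    full = _sim_locus(3, ncols=60, ntaxa=4)
    aln = LocusAlignment("L", {t: s[:5] for t, s in full.sequences.items()})
    from ucephylo.models import _nj_topology
    topo = _nj_topology(full)
    fit = fit_model(aln, topo, SubstitutionModel("JC69"))
    # 4 taxa unrooted: 5 branches; k=5, n=5 <= k+1 -> AIC fallback
    assert fit.used_aic_fallback


def test_too_few_taxa_skipped():
    aln = LocusAlignment("L", {"a": "ACGT", "b": "ACGT", "c": "ACGT"})
    with pytest.raises(TooFewTaxaError):
        select_model_aicc(aln)


def test_jc_data_selects_jc_or_equivalent():
    """Data simulated under JC69 (kappa=1, equal frequencies): AICc should
    pick JC69 — or K80 with kappa near 1 — in at least 90% of seeds."""
    wins = 0
    n_seeds = 20
    for seed in range(n_seeds):
        aln = _sim_locus(seed + 100, ncols=2000, ntaxa=8, kappa=1.0,
                         base_freqs=(0.25, 0.25, 0.25, 0.25))
        best = select_model_aicc(aln)
        name = best.model.name
        if name == "JC69" or (name.startswith("K80")
                              and abs(best.model.kappa - 1.0) < 0.25):
            wins += 1
    assert wins >= 0.9 * n_seeds


def test_partition_grouping():
    from ucephylo.models import ModelFit

    def fit(lid, name):
        return ModelFit(lid, SubstitutionModel(name), -10.0, 30.0, 100, 5)

    assert group_into_partitions([fit("a", "JC69"), fit("b", "JC69")]) == \
        {"JC69": ["a", "b"]}
    parts = group_into_partitions(
        [fit("a", "JC69"), fit("b", "JC69"), fit("c", "GTR")])
    assert sorted((k, len(v)) for k, v in parts.items()) == \
        [("GTR", 1), ("JC69", 2)]
    assert len(MODEL_NAMES) == 10  # partition count is structurally <= 10
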