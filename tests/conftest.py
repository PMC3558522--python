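import numpy as np
import pytest

from ucephylo.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def easy_data():
    """Small concordant-regime dataset: deep internodes (no ILS to speak
    of), no dropout, no paralogs — downstream stages should recover the
    truth exactly."""
    cfg = SimulationConfig(
        n_taxa=8, n_loci=30, seed=101, locus_length_mean=500,
        locus_length_sd=20, internal_branch_scale=1.0,
        min_internal_branch=2.0, dropout_prob=0.0, paralog_prob=0.0,
        subst_rate=0.01, indel_rate=0.2)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def messy_data():
    """Dataset with dropout and paralogs for the matching/matrix stages."""
    cfg = SimulationConfig(
        n_taxa=10, n_loci=40, seed=202, locus_length_mean=300,
        locus_length_sd=40, internal_branch_scale=1.0,
        dropout_prob=0.15, paralog_prob=0.05, subst_rate=0.01,
        indel_rate=0.0)
    return simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
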