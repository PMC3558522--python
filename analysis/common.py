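"""Shared study configuration for the numbered analysis scripts.

One synthetic cohort emulating the avian UCE enrichment regime: 33 taxa
(32 ingroup + chicken-like deep outgroup), 13% locus dropout, 2% chimeric
paralogs, rapid-radiation species tree. Loci are capped at 200 (vs the
full 1,541-locus regime) so every script runs in seconds; the acceptance
benchmarks exercise the full matrix scale.
"""
from pathlib import Path

from ucephylo.simulate import SimulationConfig, simulate_dataset

RESULTS = Path(__file__).resolve().parent.parent / "results"

STUDY = SimulationConfig(
    n_taxa=33,
    n_loci=200,
    internal_branch_scale=0.2,
    dropout_prob=0.13,
    paralog_prob=0.02,
    subst_rate=0.01,
    indel_rate=0.3,
    seed=1541,
)

# half-locus chimeras cover ~50% of each source locus, so the paralog
# screen runs with a coverage threshold below one half
MIN_LOCUS_FRACTION = 0.45


def study_dataset():
    return simulate_dataset(STUDY)
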