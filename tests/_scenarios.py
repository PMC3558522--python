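"""Benchmark scenarios shared by the acceptance tests and the acceptance
script: each function runs the package under fixed study conditions and
returns measured quantities, comparing against the independent oracles in
``_oracles`` where the check is a dual-route one.
"""
from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np

from ucephylo.indels import find_shared_indels, map_to_tree
from ucephylo.match import ReferenceLocusSet, filter_duplicates, match_contigs
from ucephylo.matrix import (LocusAlignment, build_supermatrix,
                             count_informative_sites)
from ucephylo.models import SubstitutionModel, log_likelihood
from ucephylo.simulate import SimulationConfig, simulate_dataset
from ucephylo.star import multilocus_bootstrap
from ucephylo.trees import Clade, clade_splits, nj_clade, normalized_splits

from _oracles import (enumeration_log_likelihood, naive_informative_sites,
                      naive_shared_indels, random_additive_matrix)


# -- (1) pruning likelihood vs exhaustive enumeration -----------------------

def pruning_vs_enumeration_max_diff(seed: int = 0, n_cases: int = 24) -> float:
    rng = np.random.default_rng(seed)
    models = [SubstitutionModel("JC69"),
              SubstitutionModel("HKY85", freqs=(0.35, 0.2, 0.15, 0.3),
                                kappa=3.0),
              SubstitutionModel("GTR+G4", freqs=(0.3, 0.25, 0.25, 0.2),
                                rates=(1.2, 2.5, 0.7, 1.1, 3.0, 1.0),
                                alpha=0.6)]
    worst = 0.0
    for case in range(n_cases):
        ntips = int(rng.integers(3, 7))  # up to 6 tips
        labels = [chr(97 + i) for i in range(ntips)]
        nodes = [Clade(label=l) for l in labels]
        while len(nodes) > 1:
            i, j = sorted(rng.choice(len(nodes), 2, replace=False))
            b = nodes.pop(j)
            a = nodes.pop(i)
            nodes.append(Clade(children=[(a, rng.uniform(0.02, 0.8)),
                                         (b, rng.uniform(0.02, 0.8))]))
        tree = nodes[0]
        ncols = int(rng.integers(2, 6))  # up to 5 columns
        rows = {l: "".join("ACGT?"[k] for k in rng.integers(0, 5, ncols))
                for l in labels}
        model = models[case % len(models)]
        got = log_likelihood(LocusAlignment("L", rows), tree, model)
        want = enumeration_log_likelihood(rows, tree, model)
        worst = max(worst, abs(got - want))
    return worst


# -- (2) NJ on random additive matrices -------------------------------------

def nj_additive_recovery_rate(seed: int = 0, n_cases: int = 50) -> float:
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_cases):
        n = int(rng.integers(4, 9))
        D, labels, splits = random_additive_matrix(n, rng)
        hits += clade_splits(nj_clade(D, labels)) == splits
    return hits / n_cases


# -- (4) STAR + multilocus bootstrap consistency ----------------------------

def bootstrap_scenario_config(seed: int) -> SimulationConfig:
    """8 taxa, every internode >= 2 coalescent units, 200 loci x 1000 bp."""
    return SimulationConfig(
        n_taxa=8, n_loci=200, seed=seed, locus_length_mean=1000,
        locus_length_sd=0.0, internal_branch_scale=1.0,
        min_internal_branch=2.0, dropout_prob=0.0, paralog_prob=0.0,
        indel_rate=0.0, subst_rate=0.02)


def bootstrap_recovery(seed: int, n_replicates: int = 100
                       ) -> Tuple[bool, float]:
    """One seed of the consistency experiment: does the STAR point estimate
    match the true species tree with every true branch at >= 90 support?
    Returns (all branches >= 90, min support over true branches)."""
    data = simulate_dataset(bootstrap_scenario_config(seed))
    res = multilocus_bootstrap(data.alignments, n_replicates,
                               seed=seed, outgroup="OUT")
    true_splits = normalized_splits(data.truth.species_tree)
    est_splits = set(res.support)
    if true_splits != est_splits:
        return False, 0.0
    min_support = min(res.support[s] for s in true_splits)
    return min_support >= 90.0, min_support


def bootstrap_recovery_count(seeds: List[int], n_replicates: int = 100
                             ) -> Tuple[int, float]:
    oks, mins = zip(*(bootstrap_recovery(s, n_replicates) for s in seeds))
    return sum(oks), min(mins)


# -- (5) paralog filter recall and presence recovery ------------------------

def paralog_scenario_config(seed: int) -> SimulationConfig:
    return SimulationConfig(
        n_taxa=12, n_loci=80, seed=seed, locus_length_mean=350,
        locus_length_sd=60, internal_branch_scale=1.0, dropout_prob=0.13,
        paralog_prob=0.02, subst_rate=0.01, indel_rate=0.0)


def paralog_recall_and_presence(seed: int) -> Tuple[float, float, int]:
    """Returns (chimera recall, presence-cell accuracy, n chimeras)."""
    data = simulate_dataset(paralog_scenario_config(seed))
    ref = ReferenceLocusSet(data.reference)
    matches = match_contigs(data.contigs, ref, min_identity=0.80,
                            min_locus_fraction=0.45)
    db = filter_duplicates(matches)
    injected = data.truth.paralog_injections
    caught = sum(cid in db.removed_multilocus_contigs.get(tx, [])
                 for tx, cid, _i, _j in injected)
    recall = caught / len(injected) if injected else 1.0
    frame = db.presence_frame(data.taxa, data.locus_ids)
    accuracy = (frame.values == data.truth.presence.values).mean()
    return recall, accuracy, len(injected)


# -- (6) indel detector vs brute force; simulator round trip ----------------

def indel_detector_agreement(seed: int = 0, n_cases: int = 100) -> float:
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_cases):
        ntax = int(rng.integers(3, 8))
        ncol = int(rng.integers(10, 50))
        taxa = [f"t{i}" for i in range(ntax)]
        rows = {t: "".join(rng.choice(list("ACGT-"), size=ncol))
                for t in taxa}
        aln = LocusAlignment("L", rows)
        got = {(e.start, e.end): set(e.sharing_taxa)
               for e in find_shared_indels([aln], ingroup=taxa)}
        want = naive_shared_indels(rows, set(aln.present_taxa()))
        agree += got == want
    return agree / n_cases


def indel_roundtrip_recall(n_seeds: int = 50, seed0: int = 0
                           ) -> Tuple[float, int, int]:
    """Internal-branch deletions, concordant regime, no dropout: fraction
    of truth events recovered as validating events on the species tree.
    Returns (recall, n_truth_events, n_misassigned)."""
    recovered = total = misassigned = 0
    for k in range(n_seeds):
        cfg = SimulationConfig(
            n_taxa=8, n_loci=6, seed=seed0 + k, locus_length_mean=300,
            locus_length_sd=0.0, internal_branch_scale=1000.0,
            dropout_prob=0.0, paralog_prob=0.0, indel_rate=1.5,
            indel_branches="internal", subst_rate=0.001)
        data = simulate_dataset(cfg)
        ingroup = [t for t in data.taxa if t != "OUT"]
        events = find_shared_indels(data.alignments, ingroup=ingroup,
                                    outgroup="OUT")
        cm = map_to_tree(events, data.truth.species_tree, ingroup)
        truth = {(e.locus_id, e.start, e.end): e.taxa - {"OUT"}
                 for e in data.truth.indel_events
                 if len(e.taxa - {"OUT"}) >= 2}
        got = {(e.locus_id, e.start, e.end): set(e.sharing_taxa)
               for e in events}
        total += len(truth)
        recovered += sum(1 for key, taxa in truth.items()
                         if got.get(key) == taxa)
        misassigned += len(cm.homoplastic) + len(cm.skipped)
    return (recovered / total if total else 1.0), total, misassigned


# -- (7) informative-site counter vs naive recount --------------------------

def informative_agreement(seed: int = 0, n_cases: int = 100) -> float:
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_cases):
        ntax = int(rng.integers(2, 10))
        ncol = int(rng.integers(1, 40))
        rows = ["".join("ACGT-?N"[j] for j in rng.integers(0, 7, ncol))
                for _ in range(ntax)]
        agree += count_informative_sites(rows) == naive_informative_sites(rows)
    return agree / n_cases


# -- (8) completeness at full matrix scale ----------------------------------

def completeness_at_scale(seed: int) -> Dict[str, float]:
    """33 taxa x 1541 loci at 13% dropout: supermatrix completeness and the
    3-SE binomial band around the expected 0.87."""
    cfg = SimulationConfig(seed=seed, locus_length_mean=120,
                           locus_length_sd=20.0)
    data = simulate_dataset(cfg)
    sm = build_supermatrix(data.alignments, data.taxa)
    p = 1.0 - cfg.dropout_prob
    se = float(np.sqrt(p * (1 - p) / (cfg.n_taxa * cfg.n_loci)))
    return {"completeness": sm.completeness, "expected": p, "se": se,
            "n_cells": cfg.n_taxa * cfg.n_loci}
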