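"""Contig-to-locus matching: alignment verification, strand handling,
thresholds, and the two duplicate-removal rules."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ucephylo._seq import revcomp
from ucephylo.match import (ContigMatch, ReferenceLocusSet, _make_aligner,
                            filter_duplicates, match_contigs)

from _oracles import smith_waterman_score


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="module")
def reference():
    rng = np.random.default_rng(77)
    return ReferenceLocusSet(
        {f"L{i}": _random_seq(rng, 120) for i in range(4)})


def test_identical_contig_matches_perfectly(reference):
    contigs = {"tax1": {"c1": reference["L0"]}}
    (m,) = match_contigs(contigs, reference)
    assert m.locus_id == "L0"
    assert m.identity == pytest.approx(1.0)
    assert m.aligned_fraction_of_locus == pytest.approx(1.0)
    assert m.strand == "+"


def test_reverse_complement_matches_via_strand(reference):
    contigs = {"tax1": {"c1": revcomp(reference["L2"])}}
    (m,) = match_contigs(contigs, reference)
    assert m.locus_id == "L2"
    assert m.identity == pytest.approx(1.0)
    assert m.strand == "-"


def test_empty_reference_rejected():
    with pytest.raises(ValueError):
        match_contigs({"t": {}}, ReferenceLocusSet({}))
    with pytest.raises(ValueError):
        ReferenceLocusSet({"L": ""})


def test_raising_identity_never_adds_matches(reference):
    rng = np.random.default_rng(5)
    # mutate a copy of each locus to ~12% divergence
    contigs = {"t": {}}
    for i, (lid, seq) in enumerate(reference.items()):
        s = list(seq)
        for pos in rng.choice(len(s), size=len(s) // 8, replace=False):
            s[pos] = "ACGT"[rng.integers(4)]
        contigs["t"][f"c{i}"] = "".join(s)
    counts = []
    for thr in (0.5, 0.7, 0.85, 0.95, 1.0):
        counts.append(len(match_contigs(contigs, reference,
                                        min_identity=thr)))
    assert counts == sorted(counts, reverse=True)


def test_aligner_scores_agree_with_smith_waterman():
    """The verification aligner is a local aligner with the documented
    scoring; its optimal scores must equal a plain Gotoh dynamic program."""
    rng = np.random.default_rng(9)
    aligner = _make_aligner()
    for _ in range(10):
        a = _random_seq(rng, int(rng.integers(20, 50)))
        b = _random_seq(rng, int(rng.integers(20, 50)))
        assert aligner.score(a, b) == pytest.approx(
            smith_waterman_score(a, b))


def test_seeding_equals_exhaustive_scan():
    """On small instances, k-mer-seeded matching finds exactly the pairs an
    exhaustive all-pairs local-alignment scan accepts."""
    from ucephylo.match import _verify

    rng = np.random.default_rng(21)
    ref = ReferenceLocusSet({f"L{i}": _random_seq(rng, 60) for i in range(5)})
    contigs = {"t": {}}
    # contigs: mutated copies of some loci plus one random decoy
    for i in range(4):
        s = list(ref[f"L{i}"])
        for pos in rng.choice(60, size=4, replace=False):
            s[pos] = "ACGT"[rng.integers(4)]
        contigs["t"][f"c{i}"] = "".join(s)
    contigs["t"]["decoy"] = _random_seq(rng, 60)

    seeded = {(m.contig_id, m.locus_id)
              for m in match_contigs(contigs, ref, min_identity=0.8,
                                     min_locus_fraction=0.8, kmer_size=15)}
    aligner = _make_aligner()
    exhaustive = set()
    for cid, cseq in contigs["t"].items():
        for lid, lseq in ref.items():
            for s in (cseq, revcomp(cseq)):
                ident, frac = _verify(aligner, lseq, s)
                if ident >= 0.8 and frac >= 0.8:
                    exhaustive.add((cid, lid))
    assert seeded == exhaustive


def _m(taxon, contig, locus):
    return ContigMatch(taxon=taxon, contig_id=contig, locus_id=locus,
                       identity=0.9, aligned_fraction_of_locus=0.9,
                       contig_length=100)


def test_rule_a_contig_matching_two_loci_removed():
    db = filter_duplicates([_m("t", "X", "L1"), _m("t", "X", "L2")])
    assert db.removed_multilocus_contigs == {"t": ["X"]}
    assert db.accepted == {}


def test_rule_b_locus_hit_by_two_contigs_removed():
    db = filter_duplicates([_m("t", "X", "L"), _m("t", "Y", "L")])
    assert db.removed_multicontig_loci == {"t": ["L"]}
    assert db.accepted == {}


def test_rule_order_a_before_b():
    # X hits L1+L2 (removed by rule a); after that Y alone hits L1 and is kept
    db = filter_duplicates([_m("t", "X", "L1"), _m("t", "X", "L2"),
                            _m("t", "Y", "L1")])
    assert db.removed_multilocus_contigs == {"t": ["X"]}
    assert "t" not in db.removed_multicontig_loci
    assert db.contig_for("t", "L1") == "Y"


@given(st.lists(
    st.tuples(st.sampled_from(["t1", "t2"]),
              st.sampled_from([f"c{i}" for i in range(6)]),
              st.sampled_from([f"L{i}" for i in range(6)])),
    max_size=30))
@settings(deadline=None, max_examples=60, derandomize=True)
def test_filter_always_one_to_one(triples):
    db = filter_duplicates([_m(t, c, l) for t, c, l in set(triples)])
    # a contig maps to <= 1 locus and a locus holds <= 1 contig, per taxon
    per_taxon_contigs = {}
    per_taxon_loci = {}
    for (taxon, locus), m in db.accepted.items():
        assert (taxon, m.contig_id) not in per_taxon_contigs
        assert (taxon, locus) not in per_taxon_loci
        per_taxon_contigs[(taxon, m.contig_id)] = locus
        per_taxon_loci[(taxon, locus)] = m.contig_id


def test_truth_recovery_on_controlled_divergence(messy_data):
    """With modest divergence, accepted matches reproduce the simulator's
    presence matrix exactly and every injected chimera is removed."""
    ref = ReferenceLocusSet(messy_data.reference)
    matches = match_contigs(messy_data.contigs, ref, min_identity=0.8,
                            min_locus_fraction=0.45)
    db = filter_duplicates(matches)
    frame = db.presence_frame(messy_data.taxa, messy_data.locus_ids)
    assert (frame.values == messy_data.truth.presence.values).all()
    assert messy_data.truth.paralog_injections
    for taxon, cid, _li, _lj in messy_data.truth.paralog_injections:
        assert cid in db.removed_multilocus_contigs.get(taxon, [])
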