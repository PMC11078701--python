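"""Alignment handling: identity, redundancy filtering, conservation, census."""

import numpy as np
import pytest

from pasdimer.fixtures import FixtureSpec, build_msa
from pasdimer.msa import (Msa, conservation_profile, map_columns_to_query,
                          ncap_census, pairwise_identity, read_msa,
                          remove_redundancy)

GAPPY = [("s1", "ACD-G"), ("s2", "ACE-G"), ("s3", "-CDFG")]


def test_pairwise_identity_examples():
    assert pairwise_identity("ACDEF", "ACDEF") == 100.0
    assert pairwise_identity("AAAAA", "CCCCC") == 0.0
    # 3 identities over 4 columns where at least one sequence is non-gap
    assert pairwise_identity("ACD-G", "ACE-G") == 75.0


def test_pairwise_identity_modes():
    a, b = "AC--D", "ACG-D"
    assert pairwise_identity(a, b, mode="any_nongap") == pytest.approx(300 / 4)
    assert pairwise_identity(a, b, mode="both_nongap") == pytest.approx(100.0)
    assert pairwise_identity(a, b, mode="shorter") == pytest.approx(100.0)
    with pytest.raises(ValueError):
        pairwise_identity("---", "---")
    with pytest.raises(ValueError):
        pairwise_identity("AB", "ABC")


def test_identity_symmetry_and_100_iff_identical():
    m, _ = build_msa(FixtureSpec(kind="msa", n_records=12, rng_seed=3))
    seqs = [s for _, s in m.records]
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            ij = pairwise_identity(seqs[i], seqs[j])
            assert ij == pytest.approx(pairwise_identity(seqs[j], seqs[i]))
            if ij == 100.0:
                assert seqs[i] == seqs[j]


def test_read_msa_fasta_and_stockholm(tmp_path):
    fasta = tmp_path / "a.fasta"
    fasta.write_text(">s1\nACD-G\n>s2\nACE-G\n>s3\n-CDFG\n")
    m = read_msa(fasta)
    assert len(m) == 3 and m.n_columns == 5

    sto = tmp_path / "a.sto"
    sto.write_text("# STOCKHOLM 1.0\n"
                   "s1 ACD-G\n"
                   "s2 ACE-G\n"
                   "#=GC SS_cons xxxxx\n"
                   "//\n")
    m2 = read_msa(sto, format="stockholm")
    assert len(m2) == 2 and m2.records[0][1] == "ACD-G"


def test_ragged_alignment_rejected(tmp_path):
    bad = tmp_path / "bad.fasta"
    bad.write_text(">s1\nACDG\n>s2\nAC\n")
    with pytest.raises(ValueError):
        read_msa(bad)
    with pytest.raises(ValueError):
        Msa(records=[("a", "AC"), ("b", "ACD")])


def test_remove_redundancy_basics():
    m = Msa(records=[("a", "ACDEF"), ("b", "ACDEF"), ("c", "GHIKL")])
    out = remove_redundancy(m, threshold=98.0)
    assert len(out) == 2
    assert {r[0] for r in out.records} == {"a", "c"}
    # all-distinct records below threshold are all retained
    m2 = Msa(records=[("a", "ACDEF"), ("b", "GHIKL"), ("c", "MNPQR")])
    assert len(remove_redundancy(m2, threshold=50.0)) == 3


def _greedy_oracle(records, threshold, query_id=None):
    """Independent replay of the documented greedy rule from the full
    pairwise-identity matrix."""
    def ungapped(seq):
        return sum(1 for c in seq if c not in "-.")

    n = len(records)
    ident = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                ident[i, j] = pairwise_identity(records[i][1], records[j][1])
    order = sorted(range(n), key=lambda i: (records[i][0] != query_id,
                                            -ungapped(records[i][1]), i))
    kept = []
    for i in order:
        if records[i][0] == query_id or all(ident[i, j] < threshold for j in kept):
            kept.append(i)
    return sorted(records[i][0] for i in kept)


def test_redundancy_filter_matches_brute_force_oracle():
    m, _ = build_msa(FixtureSpec(kind="msa", n_records=50, identity_target=99.0,
                                 rng_seed=11))
    out = remove_redundancy(m, threshold=96.0)
    assert len(out) < len(m)  # heavy collapse at 99% identity vs 96% threshold
    assert sorted(r[0] for r in out.records) == _greedy_oracle(
        m.records, 96.0, query_id=m.query_id)


def test_redundancy_filter_certified_and_idempotent():
    m, _ = build_msa(FixtureSpec(kind="msa", n_records=40, identity_target=95.0,
                                 rng_seed=5))
    out = remove_redundancy(m, threshold=96.0)
    seqs = [s for rid, s in out.records if rid != m.query_id]
    # full recomputation certifies every retained non-query pair < threshold
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            assert pairwise_identity(seqs[i], seqs[j]) < 96.0
    again = remove_redundancy(out, threshold=96.0)
    assert again.records == out.records


def test_map_columns_to_query():
    m = Msa(records=[("q", "M-KL"), ("o", "MAKL")], query_id="q")
    assert map_columns_to_query(m) == {0: 1, 2: 2, 3: 3}
    # degapping the query row reproduces the ungapped sequence
    mapping = map_columns_to_query(m)
    degapped = "".join(m.sequence("q")[c] for c in sorted(mapping))
    assert degapped == "MKL"
    with pytest.raises(ValueError):
        map_columns_to_query(Msa(records=[("q", "---")], query_id="q"))
    with pytest.raises(KeyError):
        map_columns_to_query(Msa(records=[("o", "MAKL")], query_id="q"))


def test_conservation_profile_scores():
    m = Msa(records=[("a", "NN"), ("b", "ND"), ("c", "NN"), ("d", "ND")])
    prof = conservation_profile(m)
    assert prof.score[0] == pytest.approx(1.0)
    assert prof.score[1] == pytest.approx(0.5)
    assert not any(prof.low_coverage)
    # invariant under record permutation
    m2 = Msa(records=list(reversed(m.records)))
    assert conservation_profile(m2).score == prof.score


def test_ncap_census_exact_recovery_and_permutation_invariance():
    spec = FixtureSpec(kind="msa", n_records=100, capping_box_freq=0.9,
                       non_traditional_freq=0.08, rng_seed=17)
    m, truth = build_msa(spec)
    census = ncap_census(m, truth.msa_columns["ncap"], truth.msa_columns["preceding"])
    assert census.n_capping_box == truth.msa_counts["capping_box"] == 90
    assert census.n_non_traditional == truth.msa_counts["non_traditional"] == 8
    assert census.n_preceding_LI == truth.msa_counts["preceding_LI"]
    assert census.fractions["capping_box"] == pytest.approx(0.9)
    shuffled = Msa(records=list(reversed(m.records)))
    census2 = ncap_census(shuffled, truth.msa_columns["ncap"],
                          truth.msa_columns["preceding"])
    assert census2.n_capping_box == census.n_capping_box


def test_ncap_census_gap_and_column_handling():
    m = Msa(records=[("a", "LAS"), ("b", "LA-"), ("c", "MAT")])
    census = ncap_census(m, ncap_column=2, preceding_column=0)
    assert census.n_total == 2 and census.n_unscored == 1
    assert census.n_capping_box == 2
    assert census.n_preceding_LI == 1 and census.n_preceding_MV == 1
    with pytest.raises(IndexError):
        ncap_census(m, ncap_column=5, preceding_column=0)


def test_all_leucine_preceding_column():
    m = Msa(records=[(f"s{i}", "LxS".replace("x", "A")) for i in range(4)])
    census = ncap_census(m, ncap_column=2, preceding_column=0)
    assert census.fractions["preceding_LI"] == pytest.approx(1.0)
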