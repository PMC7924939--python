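import math

import numpy as np
import pytest

from carrierphylo.domain_scan import (Profile, ProfileError, build_profile,
                                      calibrate_threshold, composition_null,
                                      filter_proteome, read_hmmer_tblout,
                                      scan_sequence)
from carrierphylo.io_formats import Alignment, SeqRecord
from carrierphylo.simulate import SimConfig, simulate_dataset


def aln(*rows):
    return Alignment([SeqRecord(f"s{i}", r) for i, r in enumerate(rows)])


class TestBuildProfile:
    def test_pure_column_zero_pseudocount_gives_log2_20(self):
        p = build_profile(aln("A", "A", "A"), pseudocount=0.0,
                          allow_neginf=True)
        assert p.scores[0, 0] == pytest.approx(math.log2(20), abs=1e-9)

    def test_zero_pseudocount_neginf_is_error_unless_allowed(self):
        with pytest.raises(ProfileError):
            build_profile(aln("A", "A"), pseudocount=0.0)
        p = build_profile(aln("A", "A"), pseudocount=0.0, allow_neginf=True)
        assert np.isneginf(p.scores[0, 1:]).all()

    def test_unit_pseudocount_all_finite(self):
        p = build_profile(aln("AW", "CY", "DR"), pseudocount=1.0)
        assert np.isfinite(p.scores).all()

    def test_conserved_column_scores_higher(self):
        pure = build_profile(aln("A", "A"))
        mixed = build_profile(aln("A", "C"))
        assert pure.scores[0, 0] > mixed.scores[0, 0]

    def test_gap_majority_columns_dropped(self):
        p = build_profile(aln("A-W", "A-Y", "A-R", "ACW"))
        assert p.length == 2


@pytest.fixture(scope="module")
def toy_profile():
    seed = aln("ACDEFGHW", "ACDEFGHW", "ACDEFGHW", "ACDEFGHY")
    return build_profile(seed)


def _substring_score(sub, profile: Profile) -> float:
    """Best alignment consuming the whole substring, local in the profile."""
    L = profile.length
    go, ge = profile.gap_open, profile.gap_extend
    n = len(sub)
    NEG = -1e18
    M = np.full((L + 1, n + 1), NEG)
    Ix = np.full((L + 1, n + 1), NEG)   # gap in sequence
    Iy = np.full((L + 1, n + 1), NEG)   # gap in profile
    M[:, 0] = 0.0                       # free leading profile skip
    for i in range(L + 1):
        for j in range(1, n + 1):
            if i > 0:
                Ix[i, j] = max(M[i-1, j] - go, Ix[i-1, j] - ge)
            Iy[i, j] = max(M[i, j-1] - go, Iy[i, j-1] - ge)
            if i > 0:
                s = profile.scores[i-1][sub[j-1]] if sub[j-1] >= 0 else 0.0
                M[i, j] = max(M[i-1, j-1], Ix[i-1, j-1], Iy[i-1, j-1]) + s
    return float(max(M[:, n].max(), Iy[:, n].max()))


def brute_force_best_interval(seq: str, profile: Profile):
    """Oracle: exhaustive scan over every (start, end) interval."""
    from carrierphylo.domain_scan import _encode
    enc = _encode(seq)
    best_score, best_iv = -np.inf, None
    for start in range(len(seq)):
        for end in range(start + 1, len(seq) + 1):
            score = _substring_score(enc[start:end], profile)
            if score > best_score + 1e-9:
                best_score, best_iv = score, (start + 1, end)
    return best_score, best_iv


class TestScan:
    def test_consensus_scores_sum_of_column_maxima(self, toy_profile):
        cons = toy_profile.consensus() + "KK"  # padding to reach length 10
        hit = scan_sequence(SeqRecord("c", cons), toy_profile)
        expected = toy_profile.scores.max(axis=1).sum()
        assert hit.score == pytest.approx(expected, abs=1e-9)
        assert (hit.start, hit.end) == (1, toy_profile.length)

    def test_planted_consensus_recovered_vs_bruteforce(self, toy_profile,
                                                       rng):
        aa = "ARNDCQEGHILKMFPSTWYV"
        flank1 = "".join(rng.choice(list(aa), 20))
        flank2 = "".join(rng.choice(list(aa), 25))
        seq = flank1 + toy_profile.consensus() + flank2
        hit = scan_sequence(SeqRecord("p", seq), toy_profile)
        oracle_score, oracle_iv = brute_force_best_interval(seq, toy_profile)
        assert hit.score == pytest.approx(oracle_score, abs=1e-6)
        assert (hit.start, hit.end) == oracle_iv
        # the hit covers the planted consensus
        assert hit.start <= 21 and hit.end >= 28

    def test_score_ignores_description(self, toy_profile):
        a = scan_sequence(SeqRecord("x", "ACDEFGHWKK", "desc one"),
                          toy_profile)
        b = scan_sequence(SeqRecord("y", "ACDEFGHWKK", "another"),
                          toy_profile)
        assert a.score == b.score

    def test_short_sequence_rejected(self, toy_profile):
        with pytest.raises(ProfileError):
            scan_sequence(SeqRecord("s", "ACDEF"), toy_profile)


class TestFilter:
    def test_threshold_monotonicity(self, toy_profile, rng):
        aa = "ARNDCQEGHILKMFPSTWYV"
        seqs = [SeqRecord(f"r{i}", "".join(rng.choice(list(aa), 30)))
                for i in range(20)]
        seqs.append(SeqRecord("hit", toy_profile.consensus() + "KK"))
        lo = Profile(toy_profile.scores, toy_profile.background, threshold=1.0)
        hi = Profile(toy_profile.scores, toy_profile.background, threshold=20.0)
        ids_lo = {h.seq_id for h in filter_proteome(seqs, lo)}
        ids_hi = {h.seq_id for h in filter_proteome(seqs, hi)}
        assert ids_hi <= ids_lo

    def test_unreachable_threshold_empty(self, toy_profile):
        p = Profile(toy_profile.scores, toy_profile.background,
                    threshold=1e6)
        assert filter_proteome([SeqRecord("a", "ACDEFGHWKK")], p) == []

    def test_deterministic(self, toy_profile):
        seqs = [SeqRecord("a", "ACDEFGHWKK"), SeqRecord("b", "WWWWYYYYFF")]
        p = Profile(toy_profile.scores, toy_profile.background, threshold=5.0)
        first = [(h.seq_id, h.score) for h in filter_proteome(seqs, p)]
        second = [(h.seq_id, h.score) for h in filter_proteome(seqs, p)]
        assert first == second

    def test_empty_proteome_ok(self, toy_profile):
        assert filter_proteome([], toy_profile) == []


class TestSimulatedProteomes:
    def test_planted_members_recovered(self, sim_truth):
        taxa = sim_truth.species_tree.leaf_names()[:6]
        seed_rows = [r for r in sim_truth.alignment.rows
                     if r.id.split("|")[0] in set(taxa)]
        profile = build_profile(Alignment(seed_rows))
        pool = [s for prot in sim_truth.proteomes.values() for s in prot]
        null = composition_null(pool, 200, seed=1)
        profile.threshold = calibrate_threshold(profile, null)
        tp = fp = fn = 0
        for taxon, prot in sim_truth.proteomes.items():
            got = {h.seq_id for h in filter_proteome(prot, profile)}
            want = {s.id for s in prot
                    if s.id not in sim_truth.decoy_ids}
            tp += len(got & want)
            fp += len(got - want)
            fn += len(want - got)
        assert tp / (tp + fn) >= 0.95      # recall
        assert tp / (tp + fp) >= 0.95      # precision


def test_hmmer_tblout_adapter():
    text = ("#\n"
            "seq1  -  PF00153  -  1e-30  105.2  0.1  more fields\n"
            "seq2  -  PF00153  -  0.5    8.0    0.0  more fields\n")
    hits = read_hmmer_tblout(text, threshold=50.0)
    assert [(h.seq_id, h.passed) for h in hits] == [("seq1", True),
                                                    ("seq2", False)]
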