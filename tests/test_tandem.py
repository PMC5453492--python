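import numpy as np
import pytest
from hypothesis import given, strategies as st

import tandemscout as ts
from conftest import cyclic_edit_distance, random_seq
from tandemscout.assemble import Contig
from tandemscout.params import ScoringParams


def bruteforce_wraparound(seq, mon, match=2, mis=-7, gap=-7):
    """Independent oracle: full DP of seq (global) against a long linear
    concatenation of the monomer, free at both monomer ends."""
    R = len(seq) // len(mon) + 3
    M = mon * R
    NEG = -(10**9)
    prev = [0] * (len(M) + 1)
    for i in range(1, len(seq) + 1):
        cur = [NEG] * (len(M) + 1)
        for j in range(1, len(M) + 1):
            sub = match if seq[i - 1] == M[j - 1] else mis
            cur[j] = max(prev[j - 1] + sub, prev[j] + gap, cur[j - 1] + gap)
        prev = cur
    return max(prev)


class TestWraparoundAlign:
    def test_perfect_array_scores_two_per_base(self):
        score, pairs = ts.wraparound_align("ACGT" * 10, "ACGT")
        assert score == 80
        assert len(pairs) == 40

    def test_single_substitution_costs_match_plus_mismatch(self):
        seq = list("ACGT" * 10)
        seq[13] = "G"
        score, _ = ts.wraparound_align("".join(seq), "ACGT")
        assert score == 2 * 39 - 7  # 71

    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 25))
            p = int(rng.integers(1, 9))
            seq, mon = random_seq(rng, n), random_seq(rng, p)
            got, _ = ts.wraparound_align(seq, mon)
            assert got == bruteforce_wraparound(seq, mon), (seq, mon)

    def test_errors(self):
        with pytest.raises(ValueError):
            ts.wraparound_align("", "ACGT")
        with pytest.raises(ValueError):
            ts.wraparound_align("ACGT", "")
        with pytest.raises(ValueError):
            ts.wraparound_align("ACGT", "A" * 2001)

    @pytest.mark.parametrize("p,copies", [(3, 10), (7, 5), (12, 4)])
    def test_score_identity_for_perfect_arrays(self, rng, p, copies):
        mon = ts.generate_monomer(p, seed=int(rng.integers(1000)))
        score, _ = ts.wraparound_align(mon * copies, mon)
        assert score == 2 * p * copies


class TestConsensusMonomer:
    def test_perfect_array_recovers_monomer(self):
        assert ts.consensus_monomer("ACGT" * 12, 4) == "ACGT"

    def test_majority_vote_fixes_single_mutant_copy(self, rng):
        mon = ts.generate_monomer(20, seed=1)
        copies = [mon] * 5
        mutant = list(mon)
        mutant[7] = "A" if mon[7] != "A" else "C"
        copies[2] = "".join(mutant)
        assert ts.consensus_monomer("".join(copies), 20) == mon

    def test_two_copy_tie_breaks_alphabetically(self):
        # column 1 disagrees: C vs G, no majority -> alphabetical (C)
        seq = "ACTT" + "AGTT"
        assert ts.consensus_monomer(seq, 4) == "ACTT"

    def test_period_bounds(self):
        with pytest.raises(ValueError):
            ts.consensus_monomer("ACGTACGT", 5)


class TestCandidatePeriods:
    def test_exact_repeat_has_maximal_support_at_period(self):
        seq = "ACGT" * 20
        cands = ts.find_candidate_periods(seq, k=4)
        assert cands, "expected at least one candidate"
        best_d, best_support = cands[0]
        assert best_d == 4
        assert best_support == len(seq) - 4 - 4 + 1  # every position matches

    def test_random_sequence_yields_no_candidates(self, rng):
        seq = random_seq(rng, 200)
        # brute-force check that no lag passes the support filter ...
        n, k, pm = len(seq), 4, 0.8
        for d in range(1, n - k):
            support = sum(seq[i : i + k] == seq[i + d : i + d + k] for i in range(n - d - k + 1))
            assert support < np.ceil(pm * (n - d - k))
        # ... and the detector agrees
        assert ts.find_candidate_periods(seq, k=4) == []

    def test_max_period_is_never_exceeded(self, rng):
        block = random_seq(rng, 2001)
        cands = ts.find_candidate_periods(block * 3, k=12)
        assert all(d <= 2000 for d, _ in cands)


class TestDetect:
    def test_short_perfect_array_passes_min_score(self):
        anns = ts.detect_tandem_repeats(Contig("c", "ACGT" * 12))
        assert len(anns) == 1
        a = anns[0]
        assert (a.period, a.score) == (4, 96)
        assert (a.start, a.end) == (0, 48)
        assert a.copy_number == pytest.approx(12.0)
        assert ts.canonical_monomer(a.consensus) == ts.canonical_monomer("ACGT")

    def test_array_below_score_floor_is_not_annotated(self):
        # 24 perfect bases score 48 < 50
        assert ts.detect_tandem_repeats(Contig("c", "ACGT" * 6)) == []

    def test_planted_mutated_array_recovers_period_and_consensus(self):
        mon = ts.generate_monomer(184, seed=42)
        rng = np.random.default_rng(7)
        copies = []
        for _ in range(10):
            c = list(mon)
            for j in np.nonzero(rng.random(184) < 0.01)[0]:
                c[j] = "ACGT"[int(rng.integers(4))]
            copies.append("".join(c))
        anns = ts.detect_tandem_repeats(Contig("c", "".join(copies)))
        assert anns
        a = max(anns, key=lambda x: x.score)
        assert abs(a.period - 184) <= 1
        assert cyclic_edit_distance(ts.canonical_monomer(a.consensus), mon) <= 2

    def test_filter_partitions_contigs(self, rng):
        tandem_contig = Contig("t", "ACGTACGTTT" * 30)
        noise = [Contig(f"n{i}", random_seq(rng, 400)) for i in range(5)]
        kept, discarded = ts.filter_tandem_contigs([tandem_contig] + noise)
        assert [c.id for c, _ in kept] == ["t"]
        assert {c.id for c in discarded} == {f"n{i}" for i in range(5)}
        assert ts.filter_tandem_contigs([]) == ([], [])


class TestCanonicalMonomer:
    def test_least_rotation_example(self):
        assert ts.canonical_monomer("CGTA") == "ACGT"

    monomers = st.text(alphabet=st.sampled_from("ACGT"), min_size=1, max_size=30)

    @given(monomers)
    def test_strand_invariance(self, m):
        assert ts.canonical_monomer(m) == ts.canonical_monomer(ts.reverse_complement(m))

    @given(monomers)
    def test_idempotent_and_a_rotation(self, m):
        c = ts.canonical_monomer(m)
        assert ts.canonical_monomer(c) == c
        assert c in (m + m) or c in ts.reverse_complement(m + m)


def test_scoring_params_invariants():
    with pytest.raises(ValueError):
        ScoringParams(match=-1)
    with pytest.raises(ValueError):
        ScoringParams(min_score=0)
    with pytest.raises(ValueError):
        ScoringParams(max_period=3000)
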