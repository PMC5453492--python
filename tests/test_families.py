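import numpy as np
import pytest

import tandemscout as ts
from conftest import random_seq
from tandemscout.assemble import Contig
from tandemscout.families import (
    _best_ungapped_score,
    evalue,
    min_significant_score,
)
from tandemscout.params import HomologyParams
from tandemscout.recruit import ReadKmerIndex
from tandemscout.seq_io import SequenceRecord
from tandemscout.tandem import TandemAnnotation


def make_family(monomer, members):
    return ts.RepeatFamily(
        rank=1,
        seed_contig_id=next(iter(members)),
        seed_monomer=ts.canonical_monomer(monomer),
        members=set(members),
        recruited_reads=0,
        genomic_fraction=0.0,
        seed_monomer_raw=monomer,
        member_seqs=dict(members),
    )


class TestKarlinAltschul:
    def test_lambda_solves_the_moment_equation(self):
        p = HomologyParams()
        lam = p.karlin_lambda
        assert 0.25 * np.exp(lam * p.match) + 0.75 * np.exp(lam * p.mismatch) == pytest.approx(1.0, abs=1e-9)

    def test_evalue_decreases_with_score_and_increases_with_space(self):
        p = HomologyParams()
        assert evalue(30, 360, 1000, p) < evalue(20, 360, 1000, p)
        assert evalue(20, 360, 10_000, p) > evalue(20, 360, 1000, p)
        assert min_significant_score(360, 100_000, p) > min_significant_score(360, 1000, p)


class TestFindHomologs:
    def test_contig_with_exact_monomer_copies_is_a_homolog(self, rng):
        mon = ts.generate_monomer(180, seed=1)
        homolog = Contig("h", mon * 3)
        noise = Contig("n", random_seq(rng, 540))
        out = ts.find_homologs(mon, [homolog, noise])
        assert out == {"h"}

    def test_rotated_and_reverse_complement_copies_are_found(self, rng):
        mon = ts.generate_monomer(180, seed=2)
        rot = mon[90:] + mon[:90]
        out = ts.find_homologs(mon, [
            Contig("rot", rot * 3),
            Contig("rc", ts.reverse_complement(mon * 3)),
        ])
        assert out == {"rot", "rc"}

    def test_random_contigs_are_almost_never_homologs(self, rng):
        mon = ts.generate_monomer(180, seed=3)
        contigs = [Contig(f"c{i}", random_seq(rng, 500)) for i in range(100)]
        out = ts.find_homologs(mon, contigs)
        assert len(out) <= 1  # >= 99 non-homologs at E <= 0.1

    def test_empty_seed_is_an_error(self):
        with pytest.raises(ValueError):
            ts.find_homologs("", [])


class TestExtractTopFamilies:
    def tandem_pool(self, rng):
        monA = ts.generate_monomer(180, seed=10)
        monB = ts.generate_monomer(350, seed=11)
        contigs = [
            (Contig("a1", monA * 3), [TandemAnnotation("a1", 0, 540, 180, monA, 1080, 3.0)]),
            (Contig("a2", (monA[30:] + monA[:30]) * 3), [TandemAnnotation("a2", 0, 540, 180, monA[30:] + monA[:30], 1080, 3.0)]),
            (Contig("b1", monB * 3), [TandemAnnotation("b1", 0, 1050, 350, monB, 2100, 3.0)]),
        ]
        counts = {"a1": 100, "a2": 40, "b1": 60}
        recruitment = ts.RecruitmentResult(
            counts=counts,
            read_hits=[{"a1": 1.0}] * 100 + [{"a2": 1.0}] * 40 + [{"b1": 1.0}] * 60,
            total_reads=400,
            total_tandem_reads=200,
            contig_lengths={cid: len(c.seq) for (c, _), cid in zip(contigs, ["a1", "a2", "b1"])},
        )
        return contigs, recruitment

    def test_homologous_contigs_grouped_under_top_seed(self, rng):
        contigs, recruitment = self.tandem_pool(rng)
        fams = ts.extract_top_families(contigs, recruitment, n_families=4)
        assert len(fams) == 2  # pool empties before the 4th iteration
        assert fams[0].seed_contig_id == "a1"
        assert fams[0].members == {"a1", "a2"}
        assert fams[1].members == {"b1"}
        assert fams[0].recruited_reads == 140

    def test_families_are_disjoint_and_greedy(self, rng):
        contigs, recruitment = self.tandem_pool(rng)
        fams = ts.extract_top_families(contigs, recruitment, n_families=2)
        assert fams[0].members & fams[1].members == set()
        top_count = max(recruitment.counts.values())
        assert recruitment.counts[fams[0].seed_contig_id] == top_count

    def test_empty_pool_gives_empty_list(self, rng):
        _, recruitment = self.tandem_pool(rng)
        assert ts.extract_top_families([], recruitment) == []
        with pytest.raises(ValueError):
            ts.extract_top_families([], recruitment, n_families=0)


class TestFamilyComposition:
    def test_zero_reads_zero_fraction(self):
        fam = make_family("ACGTACGTTT", {"m": "ACGTACGTTT" * 3})
        assert ts.family_composition(fam, []) == 0.0

    def test_recovers_planted_fraction(self):
        fam_spec = ts.RepeatFamilySpec(
            name="f", monomer_length=180, n_arrays=2, copies_per_array=28
        )
        genome, truth = ts.build_genome(
            ts.GenomeSpec(length=100_000, families=[fam_spec], seed=21)
        )
        reads = ts.shotgun_reads(genome, coverage=7.5, read_length=150, seed=22)
        res = ts.run_from_reads(reads, truth=truth)
        assert len(res.families) == 1
        p = truth.families[0].true_fraction
        sd = np.sqrt(p * (1 - p) / len(reads))
        assert res.families[0].genomic_fraction == pytest.approx(p, abs=3 * sd)

    def test_monomer_only_vs_full_reference_agree_within_noise(self):
        fam_spec = ts.RepeatFamilySpec(
            name="f", monomer_length=180, n_arrays=2, copies_per_array=28,
            per_copy_mutation_rate=0.005,
        )
        genome, truth = ts.build_genome(
            ts.GenomeSpec(length=100_000, families=[fam_spec], seed=23)
        )
        reads = ts.shotgun_reads(genome, coverage=7.5, read_length=150, seed=24)
        res = ts.run_from_reads(reads, truth=truth)
        fam = res.families[0]
        full = fam.genomic_fraction
        monomer_only = make_family(fam.seed_monomer_raw, {"x": fam.seed_monomer_raw})
        monomer_only.member_seqs = {}
        mono = ts.family_composition(monomer_only, reads)
        p = truth.families[0].true_fraction
        sd = np.sqrt(p * (1 - p) / len(reads))
        assert abs(full - mono) < sd

    def test_composition_uses_shared_index(self):
        fam = make_family("ACGTACGTTT" * 4, {"m": "ACGTACGTTT" * 12})
        reads = [SequenceRecord("r", ("ACGTACGTTT" * 20)[:150], None)]
        idx = ReadKmerIndex(reads, 15)
        assert ts.family_composition(fam, reads, index=idx) == 1.0


class TestClassifyTopRepeat:
    def test_identical_known_monomer_matches_with_zero_length_diff(self):
        mon = ts.generate_monomer(180, seed=30)
        fam = make_family(mon, {"m": mon * 3})
        got = ts.classify_top_repeat(fam, [("CentX", mon), ("Other", ts.generate_monomer(170, seed=31))])
        assert got is not None
        name, e, diff = got
        assert name == "CentX" and diff == 0 and e <= 0.1

    def test_empty_known_set_gives_none(self):
        fam = make_family("ACGTACGTTT", {"m": "ACGTACGTTT" * 3})
        assert ts.classify_top_repeat(fam, []) is None

    def test_diverged_seed_still_matches(self):
        rng = np.random.default_rng(5)
        mon = ts.generate_monomer(180, seed=32)
        diverged = list(mon)
        for j in np.nonzero(rng.random(180) < 0.05)[0]:
            diverged[j] = "ACGT"[int(rng.integers(4))]
        fam = make_family("".join(diverged), {"m": "".join(diverged) * 3})
        got = ts.classify_top_repeat(fam, [("CentX", mon)])
        assert got is not None and got[0] == "CentX"

    def test_unrelated_known_repeats_give_none(self, rng):
        fam = make_family(ts.generate_monomer(180, seed=33), {"m": "A"})
        got = ts.classify_top_repeat(fam, [("Rnd", random_seq(rng, 180))])
        assert got is None
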