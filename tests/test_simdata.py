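"""Synthetic population and read generator behaviour."""

import io

import numpy as np
import pytest

from pooltag import popgen, simdata
from pooltag.haplotypes import HaplotypeSet
from pooltag.simdata import (
    LocusModel,
    SimConfig,
    _apply_homopolymer_indels,
    homopolymer_runs,
)


class TestLocusModel:
    def test_two_amplicons_must_share_start(self):
        with pytest.raises(ValueError):
            LocusModel("x", "ACGT" * 50, ((0, 100), (10, 200)))

    def test_amplicon_must_fit_reference(self):
        with pytest.raises(ValueError):
            LocusModel("x", "ACGT", ((0, 10),))

    def test_presets(self):
        single = simdata.single_amplicon_locus()
        assert single.length == 420 and single.amplicons == ((0, 420),)
        two = simdata.two_amplicon_locus()
        assert two.length == 830 and two.amplicons == ((0, 570), (0, 830))


class TestStructuredPopulations:
    def test_no_mutation_case_gives_zero_diversity_and_structure(self, small_locus):
        truths = simdata.generate_structured_populations(
            3, [4, 4, 4], small_locus, within_div=0.0, between_div=0.0, seed=1
        )
        assert all(len(t.haplotypes) == 1 for t in truths)
        assert len({t.haplotypes[0][0] for t in truths}) == 1
        sets = [
            HaplotypeSet(t.pool_id, t.N, t.haplotypes, sites=None) for t in truths
        ]
        assert popgen.nucleotide_diversity(sets[0], small_locus.length) == 0.0
        assert popgen.pairwise_fst_hudson(sets[0], sets[1]) == 0.0

    def test_study_design_pool_count_and_total(self, study_truths):
        _, truths = study_truths
        assert len(truths) == 20
        assert sum(t.N for t in truths) == 93
        assert all(2 <= t.N <= 13 for t in truths)

    def test_full_between_divergence_gives_phist_one(self, small_locus):
        truths = simdata.generate_structured_populations(
            4, [3, 3, 3, 3], small_locus, n_site_pool=8,
            within_div=0.0, between_div=1.0, seed=2,
        )
        sets = [
            HaplotypeSet(t.pool_id, t.N, t.haplotypes, sites=None) for t in truths
        ]
        phi, _ = popgen.amova_phist(sets, n_perm=20, seed=0)
        assert phi == pytest.approx(1.0)

    def test_deterministic_for_seed(self, small_locus):
        a = simdata.generate_structured_populations(3, [3, 4, 5], small_locus, seed=9)
        b = simdata.generate_structured_populations(3, [3, 4, 5], small_locus, seed=9)
        assert a == b

    def test_pool_size_validation(self, small_locus):
        with pytest.raises(ValueError):
            simdata.generate_structured_populations(2, [1, 4], small_locus, seed=0)


class TestStudyPoolSizes:
    def test_sum_and_range(self):
        sizes = simdata.study_pool_sizes(20, 93, seed=3)
        assert sum(sizes) == 93 and len(sizes) == 20
        assert all(2 <= s <= 13 for s in sizes)

    def test_infeasible_total(self):
        with pytest.raises(ValueError):
            simdata.study_pool_sizes(20, 300)


class TestReadSimulation:
    def test_fastq_byte_identical_for_fixed_seed(self, study_truths):
        locus, truths = study_truths
        cfg = SimConfig(reads_per_pool=30, per_base_error_rate=0.01, seed=5)
        out = []
        for _ in range(2):
            buf = io.StringIO()
            simdata.write_fastq(
                simdata.simulate_pool_reads(truths[0], locus, cfg), buf
            )
            out.append(buf.getvalue())
        assert out[0] == out[1] and out[0]

    def test_error_free_reads_are_exact_substrings(self, study_truths):
        locus, truths = study_truths
        cfg = SimConfig(reads_per_pool=50, seed=5)
        truth = truths[0]
        haps = [h for h, _ in truth.haplotypes]
        for rec in simdata.simulate_pool_reads(truth, locus, cfg):
            payload = str(rec.seq)[len(truth.barcode):]
            rc = str(rec.seq[len(truth.barcode):].reverse_complement())
            assert any(payload in h or rc in h for h in haps)

    def test_allele_frequency_converges_to_multiplicity(self, small_locus):
        # one pool, N=4 with a 1/4-frequency variant; no errors, equimolar
        ref = small_locus.reference
        derived = "T" if ref[30] != "T" else "A"
        hap = ref[:30] + derived + ref[31:]
        truth = simdata.PoolTruth(
            "p1", 4, ((ref, 3), (hap, 1)), barcode="ACGTACGT"
        )
        cfg = SimConfig(modal_read_length=60, read_length_sd=0.0,
                        reads_per_pool=4000, seed=8)
        reads = simdata.simulate_pool_reads(truth, small_locus, cfg)
        # every read is full-length here: strand-normalise and count
        from Bio.Seq import Seq
        hits = 0
        n = 0
        for rec in reads:
            s = str(rec.seq[8:])
            if s not in (ref, hap):
                s = str(Seq(s).reverse_complement())
            n += 1
            hits += s[30] == derived
        p_hat = hits / n
        se = np.sqrt(0.25 * 0.75 / n)
        assert abs(p_hat - 0.25) < 3 * se

    def test_read_count_tracks_pool_size(self, study_truths):
        locus, truths = study_truths
        cfg = SimConfig(reads_per_individual=10.0, seed=5)
        counts = [len(simdata.simulate_pool_reads(t, locus, cfg)) for t in truths]
        sizes = [t.N for t in truths]
        assert np.corrcoef(counts, sizes)[0, 1] > 0
        assert counts == [10 * n for n in sizes]

    def test_barcode_shorter_than_amplicon_required(self):
        locus = LocusModel("tiny", "ACGTAC", ((0, 6),))
        truth = simdata.PoolTruth("p", 2, (("ACGTAC", 2),), barcode="ACGTACGT")
        with pytest.raises(ValueError):
            simdata.simulate_pool_reads(truth, locus, SimConfig(seed=0))

    def test_quality_matches_error_rate(self):
        assert SimConfig(per_base_error_rate=0.01).quality == 20
        assert SimConfig(per_base_error_rate=0.0).quality == 40


class TestHomopolymerModel:
    def test_runs_detector(self):
        assert homopolymer_runs("AAACCG") == [(0, 3), (3, 5)]
        assert homopolymer_runs("ACGT") == []

    def test_indels_only_inside_runs(self):
        rng = np.random.default_rng(0)
        seq = "ACGTAAAACGTA"  # single run at [4,8)
        seen_lengths = set()
        for _ in range(200):
            out = _apply_homopolymer_indels(seq, rate=0.15, rng=rng)
            seen_lengths.add(len(out))
            # outside the run the sequence is untouched
            assert out.startswith("ACGT")
            assert out.endswith("CGTA")
            core = out[4:-4]
            assert set(core) == {"A"}
        assert seen_lengths == {len(seq) - 1, len(seq), len(seq) + 1}

    def test_no_runs_never_mutates(self):
        rng = np.random.default_rng(1)
        seq = "ACACACACAC"
        assert all(
            _apply_homopolymer_indels(seq, 1.0, rng) == seq for _ in range(50)
        )


def test_config_round_trip(tmp_path):
    cfg = SimConfig(modal_read_length=300, per_base_error_rate=0.004,
                    reads_per_individual=12.5, seed=42)
    path = tmp_path / "sim.config"
    simdata.write_config(cfg, path)
    assert simdata.read_config(path) == cfg
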