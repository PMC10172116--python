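"""Simulator ground truth: genomes, planted sites, ChIP reads, amplicons."""

import numpy as np
import pytest

from dsbdiscover.align_io import write_sam
from dsbdiscover.genome import make_genome
from dsbdiscover.indel_call import locate_flanks, summarize_indels
from dsbdiscover.simdata import (
    SimConfig,
    plant_sites,
    simulate_amplicon_reads,
    simulate_chip_reads,
)

from conftest import TRAC_GUIDE


class TestMakeGenome:
    def test_deterministic_and_total_length(self):
        g1 = make_genome(1, [1000], seed=7)
        g2 = make_genome(1, [1000], seed=7)
        assert g1.seq("chr1") == g2.seq("chr1")
        assert make_genome(3, [500_000, 300_000, 200_000], seed=1).total_length == 1_000_000

    def test_base_composition_near_uniform(self):
        seq = make_genome(1, [2_000_000], seed=3).seq("chr1")
        for base in "ACGT":
            assert abs(seq.count(base) / len(seq) - 0.25) < 0.01

    @pytest.mark.parametrize("args", [(1, [0]), (1, [-5]), (2, [100])])
    def test_invalid_arguments(self, args):
        with pytest.raises(ValueError):
            make_genome(args[0], args[1], seed=0)


class TestPlantSites:
    def test_zero_mismatch_plants_guide_exactly(self, small_genome):
        genome, sites = plant_sites(
            small_genome, TRAC_GUIDE, "NGG",
            [("chr1", 1000, "+", 0, 1.0)], seed=0)
        assert sites[0].protospacer == TRAC_GUIDE
        assert genome.fetch("chr1", 1000, 1020) == TRAC_GUIDE
        assert genome.fetch("chr1", 1021, 1023) == "GG"  # NGG PAM
        # blunt cut 3 bp 5' of the PAM
        assert sites[0].cut_pos == 1017

    def test_mismatch_count_recomputed(self, small_genome):
        genome, sites = plant_sites(
            small_genome, TRAC_GUIDE, "NGG",
            [("chr1", 5000, "+", 2, 0.5), ("chr1", 9000, "-", 4, 0.5)],
            seed=1)
        assert [s.n_mismatch for s in sites] == [2, 4]
        assert sum(a != b for a, b in zip(sites[0].protospacer, TRAC_GUIDE)) == 2
        assert sum(a != b for a, b in zip(sites[1].protospacer, TRAC_GUIDE)) == 4

    def test_minus_strand_geometry(self, small_genome):
        from dsbdiscover._util import revcomp

        genome, sites = plant_sites(
            small_genome, TRAC_GUIDE, "NGG",
            [("chr1", 2000, "-", 0, 1.0)], seed=0)
        assert genome.fetch("chr1", 2000, 2020) == revcomp(TRAC_GUIDE)
        assert genome.fetch("chr1", 1997, 1999) == "CC"  # revcomp of GG
        assert sites[0].cut_pos == 2003

    def test_overlapping_requests_rejected(self, small_genome):
        with pytest.raises(ValueError, match="overlap"):
            plant_sites(small_genome, TRAC_GUIDE, "NGG",
                        [("chr1", 1000, "+", 0, 1.0),
                         ("chr1", 1010, "+", 0, 1.0)], seed=0)

    def test_out_of_bounds_and_bad_mismatch(self, small_genome):
        with pytest.raises(ValueError):
            plant_sites(small_genome, TRAC_GUIDE, "NGG",
                        [("chr1", 199_995, "+", 0, 1.0)], seed=0)
        with pytest.raises(ValueError):
            plant_sites(small_genome, TRAC_GUIDE, "NGG",
                        [("chr1", 1000, "+", 21, 1.0)], seed=0)


class TestSimulateChipReads:
    def test_sam_byte_identical_under_seed(self, planted_env, tmp_path):
        genome, sites = planted_env
        cfg = SimConfig(bg_pairs=200, seed=9)
        p1, p2 = tmp_path / "a.sam", tmp_path / "b.sam"
        write_sam(simulate_chip_reads(genome, sites, cfg, "treated_inhibited"), str(p1))
        write_sam(simulate_chip_reads(genome, sites, cfg, "treated_inhibited"), str(p2))
        assert p1.read_bytes() == p2.read_bytes()

    def test_residence_multiplier_scales_site_pairs(self, planted_env):
        genome, sites = planted_env
        ratios = []
        for seed in range(5):
            hi = simulate_chip_reads(genome, sites,
                                     SimConfig(residence_multiplier=5.0, bg_pairs=0, seed=seed),
                                     "treated_inhibited")
            lo = simulate_chip_reads(genome, sites,
                                     SimConfig(residence_multiplier=5.0, bg_pairs=0, seed=seed),
                                     "treated_no_drug")
            ratios.append(sum(hi.ledger["n_site_pairs"]) / sum(lo.ledger["n_site_pairs"]))
        # expected pair counts 400 vs 80 per seed: ratio 5 within Poisson error
        assert abs(np.mean(ratios) - 5.0) < 0.75

    def test_multiplier_one_reproduces_no_drug_exactly(self, planted_env):
        genome, sites = planted_env
        cfg = SimConfig(residence_multiplier=1.0, bg_pairs=300, seed=4)
        a = simulate_chip_reads(genome, sites, cfg, "treated_inhibited")
        b = simulate_chip_reads(genome, sites, cfg, "treated_no_drug")
        assert a.records == b.records

    def test_no_cas9_has_only_background(self, planted_env):
        genome, sites = planted_env
        aln = simulate_chip_reads(genome, sites, SimConfig(bg_pairs=100, seed=2),
                                  "no_cas9")
        assert all(r.provenance == "bg" for r in aln.records)
        assert aln.ledger["n_site_pairs"] == [0] * len(sites)

    def test_background_identical_across_conditions(self, planted_env):
        genome, sites = planted_env
        cfg = SimConfig(bg_pairs=500, seed=31)
        arms = [simulate_chip_reads(genome, sites, cfg, c)
                for c in ("treated_inhibited", "treated_no_drug", "no_cas9")]
        bg = [[r for r in a.records if r.provenance == "bg"] for a in arms]
        assert bg[0] == bg[1] == bg[2]

    def test_provenance_ledger_conserves_pairs(self, planted_env):
        genome, sites = planted_env
        cfg = SimConfig(bg_pairs=400, dup_rate=0.1, lowmapq_rate=0.05,
                        orphan_rate=0.05, seed=13)
        aln = simulate_chip_reads(genome, sites, cfg, "treated_inhibited")
        led = aln.ledger
        n_source = sum(led["n_site_pairs"]) + led["n_bg_pairs"]
        assert led["n_pairs_emitted"] == n_source + led["n_dup"]
        assert len(aln.records) == led["n_pairs_emitted"]
        assert sum(r.is_singleton for r in aln.records) == led["n_orphan"]
        assert aln.total_reads == 2 * len(aln.records) - led["n_orphan"]

    def test_coverage_symmetric_with_dip_at_cut(self, small_genome):
        from dsbdiscover.quantify import coverage_track

        genome, sites = plant_sites(small_genome, TRAC_GUIDE, "NGG",
                                    [("chr1", 100_000, "+", 0, 1.0)], seed=8)
        cfg = SimConfig(lambda0=2000, residence_multiplier=1.0, bg_pairs=0,
                        dup_rate=0, lowmapq_rate=0, orphan_rate=0, seed=17)
        aln = simulate_chip_reads(genome, sites, cfg, "treated_no_drug")
        assert aln.n_pairs >= 1000
        cut = sites[0].cut_pos
        track = coverage_track(aln, "chr1", cut - 600, cut + 600)
        cov = np.zeros(1200, dtype=int)
        for _, s, e, v in track:
            cov[s - (cut - 600):e - (cut - 600)] = v
        left_max, right_max = cov[:600].max(), cov[600:].max()
        assert cov[600] < left_max and cov[600] < right_max
        assert abs(left_max - right_max) / max(left_max, right_max) < 0.10


@pytest.fixture(scope="module")
def spec():
    ref = make_genome(1, [200], seed=41).seq("chr1")
    return locate_flanks(ref, 90, 110)


class TestSimulateAmpliconReads:
    def test_no_indels_means_reference_length(self, spec):
        reads, truth = simulate_amplicon_reads(spec, 0.0, {}, n_reads=50, seed=1)
        summary = summarize_indels(reads, spec)
        assert summary.histogram == {0: 50}

    def test_size_spectrum_matches_request(self, spec):
        reads, truth = simulate_amplicon_reads(
            spec, 0.5, {1: 0.8, -3: 0.2}, n_reads=10_000, seed=2)
        plus1 = sum(1 for t in truth if t["size"] == 1)
        minus3 = sum(1 for t in truth if t["size"] == -3)
        # binomial sanity on the 4:1 planted ratio
        assert abs(plus1 / (plus1 + minus3) - 0.8) < 0.02
        assert abs((plus1 + minus3) / len(truth) - 0.5) < 0.02

    def test_full_flank_corruption_excludes_everything(self, spec):
        reads, _ = simulate_amplicon_reads(spec, 0.0, {}, n_reads=200,
                                           flank_corrupt_rate=1.0, seed=3)
        summary = summarize_indels(reads, spec)
        assert summary.n_excluded_no_flank == 200

    def test_oversized_deletion_rejected(self, spec):
        with pytest.raises(ValueError, match="exceeds"):
            simulate_amplicon_reads(spec, 0.5, {-70: 1.0}, n_reads=10, seed=0)
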