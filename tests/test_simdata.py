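"""Generator behaviour: drift calibration, LD blocks, selfing, sweeps,
trait planting, genotyping noise and truth-set round trips."""

import numpy as np
import pytest

from peachgwas.core import MISSING, Region, allele_frequencies
from peachgwas.ldscan import pairwise_ld
from peachgwas.simdata import (
    SimConfig,
    TruthSet,
    degrade_genotypes,
    diploids_from_selfing,
    draw_subpop_frequencies,
    expected_inbreeding,
    hudson_fst,
    plant_sweep,
    simulate,
    simulate_haplotypes,
    simulate_qualitative_trait,
    simulate_quantitative_trait,
)
from peachgwas.sweepscan import per_site_pi

from .conftest import make_genotype_matrix


class TestSubpopFrequencies:
    def test_no_drift_limit_frequencies_nearly_equal(self):
        cfg = SimConfig(seed=1, n_chrom=1, chrom_length=2_000_000, snp_spacing_mean=200,
                        fst_wild_landrace=1e-4, fst_landrace_improved=1e-4)
        ft = draw_subpop_frequencies(cfg)
        assert np.abs(ft.for_subpop("wild") - ft.for_subpop("landrace")).mean() < 0.02

    def test_hudson_fst_matches_nominal_drift(self):
        cfg = SimConfig(seed=2, n_chrom=1, chrom_length=10_000_000, snp_spacing_mean=100,
                        fst_wild_landrace=0.2)
        ft = draw_subpop_frequencies(cfg)
        assert ft.freqs.shape[1] >= 1e5 * 0.9
        fst = hudson_fst(ft.for_subpop("wild"), ft.for_subpop("landrace"))
        assert fst == pytest.approx(0.2, abs=0.02)

    def test_same_seed_identical_tables(self):
        cfg = SimConfig(seed=5, n_chrom=1, chrom_length=200_000)
        a = draw_subpop_frequencies(cfg)
        b = draw_subpop_frequencies(cfg)
        np.testing.assert_array_equal(a.freqs, b.freqs)
        np.testing.assert_array_equal(a.pos, b.pos)

    def test_invalid_fst_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(fst_wild_landrace=0.0)
        with pytest.raises(ValueError):
            SimConfig(fst_wild_landrace=1.0)


class TestHaplotypes:
    def test_single_founder_gives_zero_diversity(self):
        cfg = SimConfig(seed=3, n_chrom=1, chrom_length=200_000, n_founder_haplotypes=1)
        pool = simulate_haplotypes(draw_subpop_frequencies(cfg), cfg)
        for haps in pool.haplotypes.values():
            assert (haps == haps[0]).all()

    def test_ld_decays_across_block_boundaries(self):
        cfg = SimConfig(seed=4, n_chrom=1, chrom_length=1_000_000, snp_spacing_mean=2_000,
                        block_length_mean=50_000, n_landrace=100)
        pool = simulate_haplotypes(draw_subpop_frequencies(cfg), cfg)
        haps = pool.haplotypes["landrace"].astype(float)
        pos = pool.pos
        rng = np.random.default_rng(0)

        def mean_r2(lo, hi, n_pairs=300):
            vals = []
            tries = 0
            while len(vals) < n_pairs and tries < 20 * n_pairs:
                tries += 1
                i, j = rng.choice(len(pos), 2, replace=False)
                if not lo <= abs(pos[i] - pos[j]) < hi:
                    continue
                a, b = haps[:, i], haps[:, j]
                if a.std() == 0 or b.std() == 0:
                    continue
                vals.append(np.corrcoef(a, b)[0, 1] ** 2)
            return np.mean(vals)

        assert mean_r2(0, 10_000) > mean_r2(200_000, 10**9)

    def test_variant_count_tracks_spacing(self):
        cfg = SimConfig(seed=6, n_chrom=1, chrom_length=1_000_000, snp_spacing_mean=1_000)
        ft = draw_subpop_frequencies(cfg)
        assert 900 < ft.freqs.shape[1] < 1100  # ~1000 +/- Poisson error


class TestSelfing:
    def test_no_selfing_gives_hardy_weinberg_heterozygosity(self):
        # large founder pool: the HW closed form assumes unrelated haplotypes
        cfg = SimConfig(seed=7, n_chrom=1, chrom_length=2_000_000, snp_spacing_mean=200,
                        n_landrace=200, selfing_generations=0, n_founder_haplotypes=400)
        pool = simulate_haplotypes(draw_subpop_frequencies(cfg), cfg)
        G, f = diploids_from_selfing(pool, 0, cfg.rng("diploids"))
        assert f == 0.0
        p = allele_frequencies(G.genotypes)
        het = (G.genotypes == 1).mean(axis=0)
        ok = (p > 0.1) & (p < 0.9)
        ratio = het[ok].sum() / (2 * p[ok] * (1 - p[ok])).sum()
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_three_generations_het_deficit(self):
        # F = 0.875 after three selfing rounds; het/2pq ~ 0.125
        cfg = SimConfig(seed=8, n_chrom=1, chrom_length=2_000_000, snp_spacing_mean=100,
                        n_wild=40, n_landrace=200, n_improved=100, selfing_generations=3,
                        n_founder_haplotypes=400)
        pool = simulate_haplotypes(draw_subpop_frequencies(cfg), cfg)
        G, _ = diploids_from_selfing(pool, 3, cfg.rng("diploids"))
        assert G.genotypes.size >= 1e5
        p = allele_frequencies(G.genotypes)
        het = (G.genotypes == 1).mean(axis=0)
        ok = (p > 0.1) & (p < 0.9)
        ratio = het[ok].sum() / (2 * p[ok] * (1 - p[ok])).sum()
        assert expected_inbreeding(3) == 0.875
        assert ratio == pytest.approx(0.125, abs=0.02)

    def test_many_generations_all_homozygous(self):
        cfg = SimConfig(seed=9, n_chrom=1, chrom_length=200_000, selfing_generations=60)
        pool = simulate_haplotypes(draw_subpop_frequencies(cfg), cfg)
        G, _ = diploids_from_selfing(pool, 60, cfg.rng("diploids"))
        assert (G.genotypes != 1).all()

    def test_negative_generations_rejected(self):
        with pytest.raises(ValueError):
            expected_inbreeding(-1)


@pytest.fixture(scope="module")
def pool():
    cfg = SimConfig(seed=10, n_chrom=1, chrom_length=1_000_000, snp_spacing_mean=500)
    return cfg, simulate_haplotypes(draw_subpop_frequencies(cfg), cfg)


class TestPlantSweep:

    def test_full_carrier_fraction_zeroes_diversity(self, pool):
        cfg, p = pool
        region = Region("scaffold_1", 200_000, 300_000)
        out = plant_sweep(p, region, "domestication", 1.0, np.random.default_rng(0))
        cols = (p.chrom == "scaffold_1") & (p.pos >= 200_000) & (p.pos < 300_000)
        haps = out.haplotypes["landrace"][:, cols]
        assert (haps == haps[0]).all()

    def test_zero_carrier_fraction_is_identity(self, pool):
        _, p = pool
        out = plant_sweep(p, Region("scaffold_1", 200_000, 300_000), "domestication",
                          0.0, np.random.default_rng(0))
        np.testing.assert_array_equal(out.haplotypes["landrace"], p.haplotypes["landrace"])

    def test_wild_pool_untouched(self, pool):
        _, p = pool
        out = plant_sweep(p, Region("scaffold_1", 200_000, 300_000), "domestication",
                          1.0, np.random.default_rng(0))
        np.testing.assert_array_equal(out.haplotypes["wild"], p.haplotypes["wild"])

    def test_pi_monotone_in_carrier_fraction(self, pool):
        cfg, p = pool
        region = Region("scaffold_1", 200_000, 300_000)
        cols = (p.chrom == "scaffold_1") & (p.pos >= 200_000) & (p.pos < 300_000)
        pis = []
        for cf in (0.0, 0.5, 0.9, 1.0):
            out = plant_sweep(p, region, "domestication", cf, np.random.default_rng(1))
            G, _ = diploids_from_selfing(out, 0, np.random.default_rng(2))
            idx = G.sample_indices("landrace")
            pis.append(per_site_pi(G.genotypes[idx][:, cols]).sum())
        assert all(a >= b for a, b in zip(pis, pis[1:]))

    def test_unknown_stage_rejected(self, pool):
        _, p = pool
        with pytest.raises(ValueError):
            plant_sweep(p, Region("scaffold_1", 0, 1000), "bottleneck", 0.5,
                        np.random.default_rng(0))


class TestQualitativeTrait:
    def test_dominant_alt_definition(self):
        G = make_genotype_matrix([[0], [1], [2]])
        y = simulate_qualitative_trait(G, 0, "alt", 0.0, np.random.default_rng(0))
        np.testing.assert_array_equal(y, [0.0, 1.0, 1.0])

    def test_dominant_ref_symmetry(self):
        G = make_genotype_matrix([[0], [1], [2]])
        y = simulate_qualitative_trait(G, 0, "ref", 0.0, np.random.default_rng(0))
        np.testing.assert_array_equal(y, [1.0, 1.0, 0.0])

    def test_missing_genotype_gives_missing_phenotype(self):
        G = make_genotype_matrix([[0], [MISSING], [2]])
        y = simulate_qualitative_trait(G, 0, "alt", 0.0, np.random.default_rng(0))
        assert np.isnan(y[1]) and not np.isnan(y[0])

    def test_misclassification_rate_realized(self):
        n = 10_000
        G = make_genotype_matrix(np.tile([[0], [2]], (n // 2, 1)))
        clean = simulate_qualitative_trait(G, 0, "alt", 0.0, np.random.default_rng(1))
        noisy = simulate_qualitative_trait(G, 0, "alt", 0.05, np.random.default_rng(1))
        assert (clean != noisy).mean() == pytest.approx(0.05, abs=0.01)

    def test_monomorphic_locus_warns(self):
        G = make_genotype_matrix([[0], [0], [0]])
        with pytest.warns(UserWarning, match="monomorphic"):
            simulate_qualitative_trait(G, 0, "alt", 0.0, np.random.default_rng(0))


class TestQuantitativeTrait:
    def test_full_heritability_is_exact_linear_function(self):
        G = make_genotype_matrix([[0, 1], [1, 2], [2, 0], [1, 1]])
        y = simulate_quantitative_trait(G, [0, 1], [2.0, -1.0], 1.0,
                                        rng=np.random.default_rng(0))
        np.testing.assert_allclose(y, G.genotypes @ np.array([2.0, -1.0]))

    def test_single_locus_r2_matches_heritability(self):
        rng = np.random.default_rng(12)
        g = rng.choice([0, 1, 2], size=2000, p=[0.25, 0.5, 0.25])
        G = make_genotype_matrix(g[:, None])
        y = simulate_quantitative_trait(G, [0], [1.0], 0.5, rng=np.random.default_rng(13))
        r = np.corrcoef(g.astype(float), y)[0, 1]
        assert r * r == pytest.approx(0.5, abs=0.05)

    def test_zero_genetic_variance_rejected(self):
        G = make_genotype_matrix([[1], [1], [1]])
        with pytest.raises(ValueError, match="genetic variance"):
            simulate_quantitative_trait(G, [0], [1.0], 0.5, rng=np.random.default_rng(0))


class TestDegradeGenotypes:
    def test_perfect_accuracy_is_identity(self):
        G = make_genotype_matrix(np.random.default_rng(0).choice([0, 1, 2], size=(20, 50)))
        out = degrade_genotypes(G, 1.0, 1.0, 0.0, np.random.default_rng(1))
        np.testing.assert_array_equal(out.genotypes, G.genotypes)

    def test_default_concordances_recovered(self):
        rng = np.random.default_rng(2)
        g = rng.choice([0, 1, 2], size=(100, 2000), p=[0.4, 0.3, 0.3])
        G = make_genotype_matrix(g)
        assert g.size >= 1e5
        out = degrade_genotypes(G, 0.9359, 0.8382, 0.0, np.random.default_rng(3))
        hom = (g == 0) | (g == 2)
        het = g == 1
        assert (out.genotypes[hom] == g[hom]).mean() == pytest.approx(0.9359, abs=0.005)
        assert (out.genotypes[het] == g[het]).mean() == pytest.approx(0.8382, abs=0.005)

    def test_all_missing_at_rate_one(self):
        G = make_genotype_matrix([[0, 1], [2, 1]])
        out = degrade_genotypes(G, 1.0, 1.0, 1.0, np.random.default_rng(0))
        assert (out.genotypes == MISSING).all()

    def test_gq_mask_enriched_for_errors(self):
        rng = np.random.default_rng(4)
        g = rng.choice([0, 1, 2], size=(100, 1000), p=[0.4, 0.3, 0.3])
        G = make_genotype_matrix(g)
        out = degrade_genotypes(G, 0.9, 0.8, 0.0, np.random.default_rng(5))
        err = out.genotypes != g
        low_gq = out.gq <= 3
        err_rate_low = err[low_gq].mean()
        err_rate_high = err[~low_gq].mean()
        assert err_rate_low > 5 * err_rate_high


class TestTruthSet:
    def test_round_trip_lossless(self, sim_result):
        t = sim_result.truth
        back = TruthSet.from_json(t.to_json())
        assert back == t

    def test_frequency_conservation(self):
        # realized sample frequencies converge to the drawn table values
        cfg = SimConfig(seed=20, n_chrom=1, chrom_length=500_000, snp_spacing_mean=500,
                        n_wild=0, n_landrace=500, n_improved=0, selfing_generations=0,
                        n_founder_haplotypes=1000)
        ft = draw_subpop_frequencies(cfg)
        pool = simulate_haplotypes(ft, cfg)
        G, _ = diploids_from_selfing(pool, 0, cfg.rng("diploids"))
        realized = allele_frequencies(G.genotypes)
        p = ft.for_subpop("landrace")
        se = np.sqrt(p * (1 - p) / (2 * 500))
        # founder sampling adds variance beyond binomial; allow a wide multiple
        frac_within = (np.abs(realized - p) < 5 * se).mean()
        assert frac_within > 0.9

    def test_simulation_deterministic(self, small_config, sim_result):
        from peachgwas.simdata import simulate

        again = simulate(small_config)
        np.testing.assert_array_equal(again.genotypes.genotypes,
                                      sim_result.genotypes.genotypes)
        np.testing.assert_array_equal(again.genotypes.gq, sim_result.genotypes.gq)
        assert again.truth == sim_result.truth
        assert again.phenotypes.equals(sim_result.phenotypes)
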