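"""Association models: OLS oracle checks, REML variance components,
P3D mixed-model vs dense GLS, thresholds, leads, QQ and ratios."""

import math

import numpy as np
import pytest
from scipy import stats

from peachgwas.assoc import (
    VarianceComponents,
    bonferroni_cutoff,
    find_lead_snps,
    glm_scan,
    marker_r2,
    mlm_scan,
    qq_curve,
    reml_null,
    round_1sf,
    segregation_ratio,
)
from peachgwas.core import MISSING

from .conftest import make_genotype_matrix


def dense_gls_ftest(y, X0, Xm, V):
    """Independent oracle: whitened OLS F test with the full covariance."""
    L = np.linalg.cholesky(V)
    yw = np.linalg.solve(L, y)
    X0w = np.linalg.solve(L, X0)
    X1w = np.linalg.solve(L, np.column_stack([X0, Xm]))
    b0, *_ = np.linalg.lstsq(X0w, yw, rcond=None)
    b1, *_ = np.linalg.lstsq(X1w, yw, rcond=None)
    sse0 = np.sum((yw - X0w @ b0) ** 2)
    sse1 = np.sum((yw - X1w @ b1) ** 2)
    q = X1w.shape[1] - X0w.shape[1]
    dfe = len(y) - X1w.shape[1]
    F = ((sse0 - sse1) / q) / (sse1 / dfe)
    return F, stats.f.sf(F, q, dfe)


class TestGLM:
    def test_closed_form_ols_toy(self):
        # y on additive dosage: slope 1.5, R^2 0.9, F(1,2)=18, p~0.0513
        G = make_genotype_matrix(np.array([[0], [1], [1], [2]], dtype=np.int8))
        y = np.array([1.0, 2.0, 3.0, 4.0])
        res = glm_scan(G, y, coding="additive")
        assert res.loc[0, "effect"] == pytest.approx(1.5)
        assert res.loc[0, "F"] == pytest.approx(18.0)
        assert res.loc[0, "p"] == pytest.approx(stats.f.sf(18, 1, 2), rel=1e-10)
        assert res.loc[0, "p"] == pytest.approx(0.0513, abs=5e-4)
        assert marker_r2(y, G.genotypes[:, 0]) == pytest.approx(90.0)

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(40)
        n, m = 60, 4000
        g = rng.choice([0, 1, 2], size=(n, m), p=[0.25, 0.5, 0.25]).astype(np.int8)
        y = rng.normal(size=n)
        res = glm_scan(make_genotype_matrix(g), y, coding="additive")
        rate = (res["p"] < 0.05).mean()
        se = math.sqrt(0.05 * 0.95 / m)
        assert rate == pytest.approx(0.05, abs=3.5 * se)

    def test_saturating_covariate_gives_null_marker(self):
        G = make_genotype_matrix(np.array([[0], [1], [2], [1], [0]], dtype=np.int8))
        y = np.array([0.3, 1.2, -0.5, 2.0, 0.9])
        res = glm_scan(G, y, covariates=y[:, None], coding="additive")
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_degenerate_marker_reported_missing(self):
        G = make_genotype_matrix(np.array([[1], [1], [1]], dtype=np.int8))
        res = glm_scan(G, np.array([1.0, 2.0, 3.0]))
        assert np.isnan(res.loc[0, "p"]) and res.loc[0, "df"] == 0

    def test_constant_covariate_equals_no_covariate(self):
        rng = np.random.default_rng(41)
        g = rng.choice([0, 1, 2], size=(30, 20)).astype(np.int8)
        y = rng.normal(size=30)
        G = make_genotype_matrix(g)
        a = glm_scan(G, y, coding="additive")
        b = glm_scan(G, y, covariates=np.ones((30, 1)), coding="additive")
        np.testing.assert_allclose(a["p"].to_numpy(), b["p"].to_numpy(), rtol=1e-8)

    def test_genotypic_coding_uses_two_df(self):
        rng = np.random.default_rng(42)
        g = rng.choice([0, 1, 2], size=(50, 5)).astype(np.int8)
        res = glm_scan(make_genotype_matrix(g), rng.normal(size=50), coding="genotypic")
        assert (res["df"] == 2).all()

    def test_listwise_deletion_on_missing_phenotype(self):
        g = np.array([[0], [1], [2], [1]], dtype=np.int8)
        y = np.array([1.0, 2.0, np.nan, 4.0])
        res = glm_scan(make_genotype_matrix(g), y)
        assert res.loc[0, "n_used"] == 3


class TestREML:
    def test_recovers_equal_variance_components(self):
        # block-diagonal kinship, sigma_g = sigma_e = 1
        rng = np.random.default_rng(43)
        n, blocks = 200, 20
        K = np.zeros((n, n))
        size = n // blocks
        for b in range(blocks):
            K[b * size:(b + 1) * size, b * size:(b + 1) * size] = 1.0
        np.fill_diagonal(K, 1.0)
        deltas = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            L = np.linalg.cholesky(K + 1e-8 * np.eye(n))
            u = L @ r.normal(size=n)
            y = 1.0 + u + r.normal(size=n)
            vc = reml_null(y, np.ones((n, 1)), K)
            deltas.append(vc.delta)
        med = np.median(deltas)
        assert 0.5 <= med <= 2.0

    def test_pure_noise_pushes_genetic_variance_to_zero(self):
        rng = np.random.default_rng(44)
        n = 100
        A = rng.normal(size=(n, n))
        K = A @ A.T / n
        small, boundary = 0, 0
        for seed in range(5):
            y = np.random.default_rng(100 + seed).normal(size=n)
            vc = reml_null(y, np.ones((n, 1)), K)
            small += vc.sigma_g2 < 0.2 * vc.sigma_e2
            boundary += vc.boundary
        assert small >= 4  # genetic variance collapses toward zero
        assert boundary >= 1  # and sometimes hits the search boundary exactly

    def test_optimum_beats_dense_grid(self):
        rng = np.random.default_rng(45)
        n = 60
        A = rng.normal(size=(n, n // 2))
        K = A @ A.T / (n // 2)
        y = rng.normal(size=n) + K @ rng.normal(size=n) * 0.1
        X = np.ones((n, 1))
        vc = reml_null(y, X, K)
        # independent dense grid on delta
        Q, _ = np.linalg.qr(X)
        S = np.eye(n) - Q @ Q.T
        vals, vecs = np.linalg.eigh((S @ K @ S + (S @ K @ S).T) / 2)
        lam = np.clip(np.sort(vals)[::-1][: n - 1], 0, None)
        U = vecs[:, np.argsort(vals)[::-1]][:, : n - 1]
        eta2 = (U.T @ y) ** 2
        m = n - 1

        def ll(d):
            denom = lam + d
            return 0.5 * (m * (math.log(m / (2 * math.pi)) - 1
                               - math.log(np.sum(eta2 / denom)))
                          - np.sum(np.log(denom)))

        grid = np.logspace(-5, 5, 2000)
        assert vc.loglik >= max(ll(d) for d in grid) - 1e-6

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            reml_null(np.zeros(5), np.ones((5, 1)), np.eye(4))


class TestMLM:
    def test_zero_genetic_variance_reduces_to_glm(self):
        rng = np.random.default_rng(46)
        g = rng.choice([0, 1, 2], size=(40, 30)).astype(np.int8)
        G = make_genotype_matrix(g)
        y = rng.normal(size=40)
        K = np.eye(40)
        vc = VarianceComponents(sigma_g2=0.0, sigma_e2=1.0, loglik=0.0)
        a = mlm_scan(G, y, None, K, vc, coding="additive")
        b = glm_scan(G, y, coding="additive")
        np.testing.assert_allclose(a["p"].to_numpy(), b["p"].to_numpy(), rtol=1e-6)

    def test_matches_dense_gls_oracle(self):
        rng = np.random.default_rng(47)
        n, m = 30, 25
        g = rng.choice([0, 1, 2], size=(n, m)).astype(np.int8)
        G = make_genotype_matrix(g)
        A = rng.normal(size=(n, n))
        K = A @ A.T / n
        y = rng.normal(size=n)
        pcs = rng.normal(size=(n, 2))
        vc = VarianceComponents(sigma_g2=0.7, sigma_e2=0.4, loglik=0.0)
        res = mlm_scan(G, y, pcs, K, vc, coding="additive")
        V = 0.7 * K + 0.4 * np.eye(n)
        X0 = np.column_stack([np.ones(n), pcs])
        for j in range(m):
            F_oracle, p_oracle = dense_gls_ftest(y, X0, g[:, j].astype(float)[:, None], V)
            assert res.loc[j, "F"] == pytest.approx(F_oracle, rel=1e-8)
            assert res.loc[j, "p"] == pytest.approx(p_oracle, rel=1e-8)

    def test_missing_genotypes_fall_back_to_subset_gls(self):
        rng = np.random.default_rng(48)
        n = 30
        g = rng.choice([0, 1, 2], size=(n, 3)).astype(np.int8)
        g[:5, 1] = MISSING
        G = make_genotype_matrix(g)
        A = rng.normal(size=(n, n))
        K = A @ A.T / n
        y = rng.normal(size=n)
        vc = VarianceComponents(sigma_g2=0.5, sigma_e2=0.5, loglik=0.0)
        res = mlm_scan(G, y, None, K, vc, coding="additive")
        assert res.loc[1, "n_used"] == n - 5
        sub = np.arange(5, n)
        V = 0.5 * K[np.ix_(sub, sub)] + 0.5 * np.eye(n - 5)
        F_oracle, p_oracle = dense_gls_ftest(
            y[sub], np.ones((n - 5, 1)), g[sub, 1].astype(float)[:, None], V)
        assert res.loc[1, "p"] == pytest.approx(p_oracle, rel=1e-8)


class TestThresholdsAndLeads:
    def test_bonferroni_values(self):
        assert bonferroni_cutoff(0.05, 4_063_377) == pytest.approx(1.2305e-8, rel=1e-4)
        assert round_1sf(bonferroni_cutoff(0.05, 4_063_377)) == 1e-8
        assert bonferroni_cutoff(0.05, 5) == 0.01
        assert bonferroni_cutoff(1, 1) == 1
        with pytest.raises(ValueError):
            bonferroni_cutoff(0.05, 0)

    def _result_df(self, positions, pvals, chrom="scaffold_1"):
        import pandas as pd

        return pd.DataFrame({
            "chrom": chrom, "pos": positions, "model": "glm", "df": 1,
            "effect": 0.0, "F": 1.0, "p": pvals,
            "mlog10p": [-math.log10(p) for p in pvals], "maf": 0.2,
            "n_used": 100,
        })

    def test_no_significant_variants_empty(self):
        res = self._result_df([100, 200], [0.5, 0.9])
        assert find_lead_snps(res, cutoff=1e-8) == []

    def test_gap_rule_splits_clusters(self):
        res = self._result_df([100_000, 160_001], [1e-9, 1e-9])
        assert len(find_lead_snps(res, cutoff=1e-8, min_gap=50_000)) == 2
        res2 = self._result_df([100_000, 150_000], [1e-9, 1e-9])
        assert len(find_lead_snps(res2, cutoff=1e-8, min_gap=50_000)) == 1

    def test_lead_is_cluster_argmin(self):
        res = self._result_df([1000, 2000, 3000], [1e-9, 1e-12, 1e-10])
        leads = find_lead_snps(res, cutoff=1e-8, min_gap=50_000)
        assert len(leads) == 1 and leads[0].pos == 2000

    def test_candidate_region_is_lead_plus_minus_flank(self):
        res = self._result_df([100_000], [1e-10])
        lead = find_lead_snps(res, cutoff=1e-8, flank=25_000)[0]
        assert (lead.region.start, lead.region.end) == (75_000, 125_000)


class TestExplainedVariation:
    def test_exact_linear_gives_100(self):
        g = np.array([0, 1, 2, 1, 0], dtype=np.int8)
        assert marker_r2(g.astype(float) * 2.0, g) == pytest.approx(100.0)

    def test_independent_marker_near_zero(self):
        rng = np.random.default_rng(49)
        g = rng.choice([0, 1, 2], size=5000).astype(np.int8)
        y = rng.normal(size=5000)
        assert abs(marker_r2(y, g)) < 0.5


class TestQQ:
    def test_single_value_plug_in(self):
        exp, obs = qq_curve(np.array([0.5]))
        assert exp[0] == pytest.approx(-math.log10(0.5))
        assert obs[0] == pytest.approx(-math.log10(0.5))

    def test_uniform_pvalues_slope_one(self):
        rng = np.random.default_rng(50)
        p = rng.uniform(size=10_000)
        exp, obs = qq_curve(p)
        slope = np.sum(exp * obs) / np.sum(exp * exp)
        assert slope == pytest.approx(1.0, abs=0.05)

    def test_all_ones_observed_zero(self):
        _, obs = qq_curve(np.ones(5))
        np.testing.assert_array_equal(obs, 0.0)

    def test_monotone_non_decreasing(self):
        rng = np.random.default_rng(51)
        exp, obs = qq_curve(rng.uniform(size=100))
        assert (np.diff(exp) >= 0).all() and (np.diff(obs) >= 0).all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            qq_curve(np.array([]))


class TestSegregation:
    @pytest.mark.parametrize(
        "n_dom,n_rec,expected",
        [(78, 6, 13.00), (50, 50, 1.00), (0, 5, 0.00)],
    )
    def test_ratios(self, n_dom, n_rec, expected):
        y = np.concatenate([np.ones(n_dom), np.zeros(n_rec)])
        ratio, flagged = segregation_ratio(y)
        assert ratio == expected
        assert flagged == (n_dom == 0)

    def test_no_recessives_flagged_infinite(self):
        ratio, flagged = segregation_ratio(np.ones(10))
        assert math.isinf(ratio) and flagged
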