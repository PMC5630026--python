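"""Unit and property tests for the NB-GLM statistical core."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, optimize, stats

from crevol.glm import (
    ALPHA_MIN,
    CountMatrix,
    ComparisonError,
    bh_adjust,
    diff_expression,
    diff_histone,
    estimate_dispersion,
    estimate_size_factors,
    fit_nb_glm,
    nb_loglik,
    wald_test,
)


# ---------------------------------------------------------------------------
# size factors


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        X = np.tile([[10], [20], [30]], (1, 4))
        np.testing.assert_allclose(estimate_size_factors(X), np.ones(4))

    def test_doubled_column_splits_symmetrically(self):
        X = np.array([[10, 20], [30, 60], [5, 10]])
        np.testing.assert_allclose(
            estimate_size_factors(X), [1 / np.sqrt(2), np.sqrt(2)]
        )

    def test_hand_computed_median_of_ratios(self):
        X = np.array([[4, 8, 16], [9, 9, 9], [25, 5, 5]], dtype=float)
        geo = np.exp(np.log(X).mean(axis=1, keepdims=True))
        expected = np.median(X / geo, axis=0)
        expected /= np.exp(np.log(expected).mean())
        np.testing.assert_allclose(estimate_size_factors(X), expected)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(50, size=(30, 4)).astype(float) + 1
        f0 = estimate_size_factors(X)
        X2 = X.copy()
        X2[:, 2] *= 3.0
        f1 = estimate_size_factors(X2)
        # relative factor of the scaled sample triples (up to renormalisation)
        np.testing.assert_allclose((f1[2] / f1[0]) / (f0[2] / f0[0]), 3.0, rtol=1e-9)

    def test_fallback_when_no_common_positive_feature(self):
        X = np.array([[5, 0], [0, 5]], dtype=float)
        with pytest.warns(RuntimeWarning):
            f = estimate_size_factors(X)
        assert np.all(f > 0)


# ---------------------------------------------------------------------------
# dispersion


class TestDispersion:
    def test_poisson_data_hits_lower_bound(self):
        rng = np.random.default_rng(1)
        y = rng.poisson(200, size=2000)
        a = estimate_dispersion(y, np.full(len(y), 200.0))
        assert a < 1e-3

    def test_recovers_alpha_half(self):
        rng = np.random.default_rng(2)
        n = 1.0 / 0.5
        y = rng.negative_binomial(n, n / (n + 100.0), size=200)
        a = estimate_dispersion(y, np.full(200, y.mean()))
        assert 0.4 <= a <= 0.6

    def test_matches_grid_search(self):
        rng = np.random.default_rng(3)
        n = 1.0 / 0.2
        y = rng.negative_binomial(n, n / (n + 50.0), size=60)
        mu = np.full(60, y.mean())
        a = estimate_dispersion(y, mu)
        grid = np.exp(np.linspace(np.log(1e-8), np.log(10), 200))
        best = grid[np.argmax([nb_loglik(y, mu, g) for g in grid])]
        assert nb_loglik(y, mu, a) >= nb_loglik(y, mu, best) - 1e-6

    def test_all_zero_row_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            estimate_dispersion(np.zeros(10), np.full(10, 1.0))


# ---------------------------------------------------------------------------
# IRLS fit


class TestFit:
    def test_intercept_only_equals_log_mean(self):
        f = fit_nb_glm(np.full(6, 7.0), np.ones((6, 1)), 0.0, alpha=ALPHA_MIN)
        assert abs(f.coef[0] - np.log(7)) < 1e-10

    @pytest.mark.parametrize("alpha", [ALPHA_MIN, 0.1, 1.0])
    def test_two_group_means_equal_sample_means(self, alpha):
        rng = np.random.default_rng(4)
        y = rng.poisson(40, 12).astype(float)
        X = np.column_stack([np.ones(12), np.repeat([0.0, 1.0], 6)])
        f = fit_nb_glm(y, X, 0.0, alpha=alpha)
        np.testing.assert_allclose(np.exp(f.coef[0]), y[:6].mean(), rtol=1e-7)
        np.testing.assert_allclose(np.exp(f.coef.sum()), y[6:].mean(), rtol=1e-7)

    def test_matches_nelder_mead_oracle(self):
        rng = np.random.default_rng(5)
        X = np.column_stack(
            [np.ones(12), np.repeat([0.0, 1.0], 6), np.tile([0, 0, 0, 1, 1, 1], 2)]
        )
        for _ in range(10):
            beta = np.array([3.0, *rng.normal(0, 0.5, 2)])
            mu = np.exp(X @ beta)
            n = 1.0 / 0.1
            y = rng.negative_binomial(n, n / (n + mu)).astype(float)
            if not y.any():
                continue
            fit = fit_nb_glm(y, X, 0.0, alpha=0.1)
            res = optimize.minimize(
                lambda b: -nb_loglik(y, np.exp(np.clip(X @ b, -30, 30)), 0.1),
                fit.coef + 0.05,
                method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000},
            )
            np.testing.assert_allclose(fit.coef, res.x, atol=1e-6)

    def test_offsets_shift_intercept(self):
        y = np.full(5, 20.0)
        f0 = fit_nb_glm(y, np.ones((5, 1)), 0.0, alpha=ALPHA_MIN)
        f1 = fit_nb_glm(y, np.ones((5, 1)), np.full(5, np.log(2.0)), alpha=ALPHA_MIN)
        np.testing.assert_allclose(f0.coef[0] - f1.coef[0], np.log(2.0), atol=1e-8)

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(8), np.ones(8)])
        with pytest.raises(ValueError, match="full rank"):
            fit_nb_glm(np.arange(8.0) + 1, X, 0.0, alpha=0.1)

    def test_deviance_no_worse_than_start_on_random_toys(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            n_samp = int(rng.integers(6, 16))
            X = np.column_stack([np.ones(n_samp), rng.normal(size=n_samp)])
            y = rng.poisson(30, n_samp).astype(float)
            f = fit_nb_glm(y, X, 0.0, alpha=0.2)
            assert f.converged
            assert np.isfinite(f.deviance)


# ---------------------------------------------------------------------------
# Wald / BH


class TestWaldBH:
    def test_zero_coefficient_gives_p_one(self):
        z, p = wald_test(0.0, 1.0)
        assert z == 0.0 and p == 1.0

    def test_normal_quantile(self):
        _, p = wald_test(1.959964, 1.0)
        assert abs(p - 0.05) < 1e-6

    def test_matches_quadrature_at_z27(self):
        _, p = wald_test(2.7, 1.0)
        tail, _ = integrate.quad(stats.norm.pdf, 2.7, np.inf)
        assert abs(p - 2 * tail) < 1e-10

    def test_zero_se_rejected(self):
        with pytest.raises(ValueError):
            wald_test(1.0, 0.0)

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.031]), [0.031])

    def test_stepup_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0] * 3)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=6))
    def test_matches_stepup_oracle_on_random_vectors(self, ps):
        def oracle(p):
            p = np.asarray(p, dtype=float)
            m = len(p)
            order = np.argsort(p, kind="mergesort")
            adj = np.empty(m)
            running = 1.0
            for rank in range(m - 1, -1, -1):
                i = order[rank]
                running = min(running, p[i] * m / (rank + 1))
                adj[i] = running
            return adj

        np.testing.assert_allclose(bh_adjust(ps), oracle(ps), atol=1e-12)


# ---------------------------------------------------------------------------
# differential drivers


def _two_group_chip(rng, n_regions, depth, effect_log2fc, alpha=0.05, n_per=3,
                    affected_fraction=0.2):
    """Human-vs-chimp style IP/input matrix with a known interaction effect.

    Only the first ``affected_fraction`` of regions carry the effect, so
    median-of-ratios size factors stay anchored on the null majority.
    """
    samples, meta = [], []
    for sp in ("human", "chimp"):
        for ind in range(n_per):
            for assay in ("IP", "input"):
                samples.append(f"{sp}_{ind}_{assay}")
                meta.append({"species": sp, "individual": f"{sp}_{ind}", "assay": assay,
                             "mark": "H3K27ac", "sex": "M"})
    meta = pd.DataFrame(meta, index=samples)
    n_samp = len(samples)
    n_affected = int(round(affected_fraction * n_regions))
    counts = np.zeros((n_regions, n_samp), dtype=np.int64)
    n_nb = 1.0 / alpha
    for j, s in enumerate(samples):
        ip = s.endswith("_IP")
        human = s.startswith("human")
        mu = np.full(n_regions, depth * (4.0 if ip else 1.0))
        if ip and human:
            mu[:n_affected] *= 2.0 ** effect_log2fc
        counts[:, j] = rng.negative_binomial(n_nb, n_nb / (n_nb + mu), size=n_regions)
    cm = CountMatrix(pd.DataFrame(counts, index=[f"r{i}" for i in range(n_regions)], columns=samples), meta)
    return cm, n_affected


class TestDiffHistone:
    def test_symmetric_null_centred_at_zero(self):
        rng = np.random.default_rng(7)
        cm, _ = _two_group_chip(rng, 200, depth=100, effect_log2fc=0.0)
        res = diff_histone(cm, {"human"}, {"chimp"}, "hvc")
        assert abs(res["log2fc"].median()) < 0.15

    def test_recovers_interaction_effect(self):
        rng = np.random.default_rng(8)
        cm, n_aff = _two_group_chip(rng, 150, depth=100, effect_log2fc=2.0)
        res = diff_histone(cm, {"human"}, {"chimp"}, "hvc")
        affected = res.iloc[:n_aff]
        assert abs(affected["log2fc"].median() - 2.0) < 0.3
        assert (affected["padj"] < 0.10).mean() > 0.8

    def test_all_zero_ip_region_untested(self):
        rng = np.random.default_rng(9)
        cm, _ = _two_group_chip(rng, 10, depth=50, effect_log2fc=0.0)
        counts = cm.counts.copy()
        ip_cols = [c for c in counts.columns if c.endswith("_IP")]
        counts.loc["r0", ip_cols] = 0
        cm2 = CountMatrix(counts, cm.metadata)
        res = diff_histone(cm2, {"human"}, {"chimp"}, "hvc").set_index("feature_id")
        assert res.loc["r0", "status"] == "untested"
        assert not bool(res.loc["r0", "significant"])

    def test_small_group_refused(self):
        rng = np.random.default_rng(10)
        cm, _ = _two_group_chip(rng, 5, depth=50, effect_log2fc=0.0)
        keep = [c for c in cm.counts.columns if not c.startswith("chimp_0")]
        keep = [c for c in keep if not c.startswith("chimp_1")]
        with pytest.raises(ComparisonError):
            diff_histone(cm.subset_samples(keep), {"human"}, {"chimp"}, "hvc")


class TestDiffExpression:
    def test_doubling_one_group_shifts_log2fc_by_one(self):
        # with offsets fixed at zero (identical size factors forced), doubling
        # group A's counts adds exactly +1 to the estimated log2 fold change
        rng = np.random.default_rng(11)
        y = rng.poisson(100, 12).astype(float)
        X = np.column_stack([np.ones(12), np.repeat([1.0, 0.0], 6)])
        f0 = fit_nb_glm(y, X, 0.0, alpha=0.05)
        y2 = y.copy()
        y2[:6] *= 2
        f1 = fit_nb_glm(y2, X, 0.0, alpha=0.05)
        np.testing.assert_allclose(f1.coef[1] - f0.coef[1], np.log(2), atol=1e-6)

    def test_strong_downregulation_recovered(self):
        # a JARID2-scale effect: log2fc = -3.33 in one species vs the rest
        rng = np.random.default_rng(12)
        species = ["human"] * 4 + ["chimp"] * 4 + ["rhesus"] * 4 + ["marmoset"] * 3 + ["bushbaby"] * 3
        samples = [f"s{i}" for i in range(len(species))]
        meta = pd.DataFrame(
            {"species": species, "individual": samples, "assay": "RNA", "mark": "none", "sex": "M"},
            index=samples,
        )
        is_human = np.array(species) == "human"
        n_nb = 1 / 0.05
        counts = np.zeros((100, len(samples)), dtype=np.int64)
        for i in range(100):
            mu = np.where(is_human & (i < 20), 200 * 2 ** -3.33, 200.0)
            counts[i] = rng.negative_binomial(n_nb, n_nb / (n_nb + mu))
        cm = CountMatrix(pd.DataFrame(counts, index=[f"g{i}" for i in range(100)], columns=samples), meta)
        res = diff_expression(cm, {"human"}, set(species) - {"human"}, "hvrest")
        assert abs(res["log2fc"].iloc[:20].median() + 3.33) < 0.5
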