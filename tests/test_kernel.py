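"""Null model, quadratic-form p-values and the SKAT-O statistic family."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2, kstest

from pathkat.errors import (
    CollinearityError,
    DegenerateFitError,
    DegenerateSetError,
)
from pathkat.geno_io import GenotypeMatrix
from pathkat.kernel_test import (
    DEFAULT_RHO_GRID,
    SkatOTest,
    WeightSpec,
    beta_weights,
    fit_null,
    mean_impute,
    mixture_lambdas,
    q_statistic,
    single_variant_scan,
    skat_o,
)
from pathkat.qforms import davies_pvalue, liu_pvalue
from tests.conftest import make_design, make_genotypes


class TestFitNull:
    def test_intercept_only_centres(self, rng):
        y = rng.standard_normal(30)
        null = fit_null(y, np.ones((30, 1)))
        np.testing.assert_allclose(null.residuals, y - y.mean())

    def test_perfect_fit_flagged(self, rng):
        X = make_design(20, 2, rng)
        y = X @ np.array([1.0, 2.0, -0.5])
        with pytest.raises(DegenerateFitError):
            fit_null(y, X)

    def test_matches_normal_equations_and_statsmodels(self, rng):
        X = make_design(50, 2, rng)
        y = rng.standard_normal(50)
        null = fit_null(y, X)
        expect = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(null.alpha_hat, expect, rtol=1e-10)
        sm = pytest.importorskip("statsmodels.api")
        fit = sm.OLS(y, X).fit()
        np.testing.assert_allclose(null.alpha_hat, fit.params, rtol=1e-9)
        np.testing.assert_allclose(
            null.sigma2_hat, fit.mse_resid, rtol=1e-9
        )

    def test_residuals_orthogonal_to_design(self, rng):
        X = make_design(40, 3, rng)
        null = fit_null(rng.standard_normal(40), X)
        np.testing.assert_allclose(X.T @ null.residuals, 0.0, atol=1e-9)

    def test_collinear_columns_named(self, rng):
        X = make_design(30, 2, rng)
        X = np.column_stack([X, X[:, 1]])
        with pytest.raises(CollinearityError) as err:
            fit_null(rng.standard_normal(30), X, column_names=["i", "a", "b", "a2"])
        assert set(err.value.columns) & {"a", "a2"}


class TestBetaWeights:
    def test_default_closed_form(self):
        assert beta_weights([0.01])[0] == pytest.approx(25 * 0.99**24)
        assert beta_weights([1e-9])[0] == pytest.approx(25.0, rel=1e-6)

    def test_flat_spec(self):
        np.testing.assert_allclose(
            beta_weights([0.01, 0.3, 0.5], WeightSpec(1, 1)), 1.0
        )

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError):
            beta_weights([0.0, 0.01])

    def test_rarer_never_downweighted(self, rng):
        maf = np.sort(rng.uniform(1e-4, 0.5, 50))
        w = beta_weights(maf)
        assert (np.diff(w) <= 1e-12).all()


class TestQStatistic:
    @pytest.fixture
    def setup(self, rng):
        X = make_design(30, 2, rng)
        null = fit_null(rng.standard_normal(30), X)
        G = make_genotypes(30, [0.2, 0.3, 0.1], rng)
        w = beta_weights([0.2, 0.3, 0.1])
        return null, G, w

    def test_endpoints(self, setup):
        null, G, w = setup
        s = (G.T @ null.residuals) * w
        assert q_statistic(null, G, w, 0.0) == pytest.approx(np.sum(s**2))
        assert q_statistic(null, G, w, 1.0) == pytest.approx(np.sum(s) ** 2)

    def test_linear_in_rho(self, setup):
        null, G, w = setup
        q0 = q_statistic(null, G, w, 0.0)
        q1 = q_statistic(null, G, w, 1.0)
        for rho in (0.2, 0.5, 0.8):
            assert q_statistic(null, G, w, rho) == pytest.approx(
                (1 - rho) * q0 + rho * q1
            )

    def test_single_variant_rho_invariant(self, rng):
        X = make_design(25, 1, rng)
        null = fit_null(rng.standard_normal(25), X)
        G = make_genotypes(25, [0.3], rng)
        qs = {q_statistic(null, G, [1.0], r) for r in (0.0, 0.4, 1.0)}
        assert max(qs) - min(qs) < 1e-9 * max(qs)

    def test_bruteforce_scalar_oracle(self, setup):
        null, G, w = setup
        s = G.T @ null.residuals
        brute = 0.5 * sum((w[j] * s[j]) ** 2 for j in range(3)) + 0.5 * (
            sum(w[j] * s[j] for j in range(3))
        ) ** 2
        assert q_statistic(null, G, w, 0.5) == pytest.approx(brute)


class TestMixtureLambdas:
    def test_scalar_closed_form(self, rng):
        y = rng.standard_normal(40)
        null = fit_null(y, np.ones((40, 1)))
        g = make_genotypes(40, [0.3], rng)
        lam = mixture_lambdas(null, g, [1.0], rho=0.0)
        expect = null.sigma2_hat * np.sum((g - g.mean()) ** 2)
        assert lam == pytest.approx([expect])

    def test_orthonormal_columns_give_equal_lambdas(self, rng):
        n = 40
        null = fit_null(rng.standard_normal(n), np.ones((n, 1)))
        M = rng.standard_normal((n, 4))
        M -= M.mean(axis=0)  # orthogonal to the intercept
        Q, _ = np.linalg.qr(M)
        lam = mixture_lambdas(null, Q, np.ones(4), rho=0.0)
        np.testing.assert_allclose(lam, null.sigma2_hat, rtol=1e-8)

    def test_null_distribution_matches_mixture(self, rng):
        """Monte-Carlo: Q under simulated null traits follows sum lam chi2."""
        n, m = 40, 4
        X = np.ones((n, 1))
        G = make_genotypes(n, [0.2, 0.3, 0.25, 0.4], rng)
        w = np.ones(m)
        sigma = 1.3
        reps = 20000
        qs = np.empty(reps)
        lam_ref = None
        Qx = X / np.sqrt(n)
        P = np.eye(n) - Qx @ Qx.T
        Z = P @ G
        lam_unscaled = np.linalg.eigvalsh(Z.T @ Z)
        lam_unscaled = lam_unscaled[lam_unscaled > 1e-10 * lam_unscaled.max()]
        for i in range(reps):
            y = sigma * rng.standard_normal(n)
            r = y - y.mean()
            s = G.T @ r
            qs[i] = np.sum(s**2)
        # exact-sigma mixture (plug-in sigma2_hat varies per rep; use truth)
        lam = sigma**2 * lam_unscaled
        # compare tail probabilities at a few quantiles
        for p_target in (0.5, 0.1, 0.01):
            from pathkat.qforms import liu_quantile

            q = liu_quantile(p_target, lam)
            p_exact = davies_pvalue(q, lam).pvalue
            emp = (qs >= q).mean()
            se = np.sqrt(p_exact * (1 - p_exact) / reps)
            assert abs(emp - p_exact) < 4 * se + 1e-4

    def test_burden_rank_one(self, rng):
        n = 30
        null = fit_null(rng.standard_normal(n), np.ones((n, 1)))
        G = make_genotypes(n, [0.2, 0.3], rng)
        lam = mixture_lambdas(null, G, np.ones(2), rho=1.0)
        assert len(lam) == 1

    def test_constant_genotype_degenerate(self, rng):
        null = fit_null(rng.standard_normal(20), np.ones((20, 1)))
        with pytest.raises(DegenerateSetError):
            mixture_lambdas(null, np.ones((20, 2)), np.ones(2), 0.0)


class TestDaviesPvalue:
    @pytest.mark.parametrize(
        "q,lam,df",
        [(3.841459, [1.0], 1), (5.991465, [1.0, 1.0], 2), (11.0705, [1.0] * 5, 5)],
    )
    def test_chi_square_identities(self, q, lam, df):
        assert davies_pvalue(q, lam).pvalue == pytest.approx(
            chi2.sf(q, df), abs=1e-8
        )

    def test_against_monte_carlo(self, rng):
        lam = np.array([2.0, 1.0, 0.5])
        reps = 2_000_000
        draws = (lam[None, :] * rng.chisquare(1, size=(reps, 3))).sum(axis=1)
        p = davies_pvalue(5.0, lam).pvalue
        emp = (draws >= 5.0).mean()
        se = np.sqrt(p * (1 - p) / reps)
        assert abs(p - emp) < 3 * se

    def test_negative_eigenvalue_rejected(self):
        with pytest.raises(ValueError):
            davies_pvalue(1.0, [1.0, -0.5])

    def test_tiny_q_near_one(self):
        assert davies_pvalue(1e-12, [1.0, 2.0]).pvalue == pytest.approx(1.0, abs=1e-5)

    def test_deep_tail_monotone(self):
        lam = [1.5, 0.7, 0.3]
        ps = [davies_pvalue(q, lam).pvalue for q in (10, 50, 100, 200)]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        assert ps[-1] < 1e-12


class TestLiuPvalue:
    def test_single_component_exact(self, rng):
        for q in (0.5, 2.0, 7.0):
            assert liu_pvalue(q, [1.7]) == pytest.approx(
                chi2.sf(q / 1.7, 1), rel=1e-9
            )

    def test_equal_lambdas_exact(self):
        c, m, q = 0.8, 6, 9.0
        assert liu_pvalue(q, [c] * m) == pytest.approx(chi2.sf(q / c, m), rel=1e-6)

    def test_close_to_davies_in_central_region(self, rng):
        for _ in range(25):
            m = int(rng.integers(2, 11))
            lam = rng.uniform(0.1, 3.0, m)
            from pathkat.qforms import liu_quantile

            q = liu_quantile(float(rng.uniform(0.01, 0.5)), lam)
            pd_ = davies_pvalue(q, lam).pvalue
            pl = liu_pvalue(q, lam)
            assert abs(pd_ - pl) / pd_ < 0.10

    def test_example_within_ten_percent(self):
        pd_ = davies_pvalue(4.0, [3, 1, 0.2]).pvalue
        assert liu_pvalue(4.0, [3, 1, 0.2]) == pytest.approx(pd_, rel=0.10)


class TestSkatO:
    def _random_case(self, rng, n=120, m=None, signal=0.0):
        m = m or int(rng.integers(2, 9))
        X = make_design(n, 3, rng)
        maf = rng.uniform(0.01, 0.2, m)
        G = make_genotypes(n, maf, rng)
        while (G.std(axis=0) == 0).any():
            G = make_genotypes(n, maf, rng)
        beta = signal * rng.standard_normal(m)
        y = G @ beta + X @ rng.standard_normal(X.shape[1]) + rng.standard_normal(n)
        null = fit_null(y, X)
        w = beta_weights(np.minimum(maf, 0.5))
        return null, G, w

    def test_min_p_bound_invariant(self, rng):
        for _ in range(20):
            null, G, w = self._random_case(rng, signal=float(rng.uniform(0, 0.4)))
            res = skat_o(null, G, w)
            t = res.p_per_rho.min()
            assert t <= res.p_skato <= min(1.0, len(res.rho_grid) * t) + 1e-12

    def test_fast_path_matches_direct(self, rng):
        for _ in range(5):
            null, G, w = self._random_case(rng, signal=0.2)
            eng = SkatOTest(G, w, null.X)
            direct = eng.test(null.y)
            fast = eng.prepare_fast().test(null.y, fast=True)
            assert fast.p_skato == pytest.approx(direct.p_skato, rel=1e-3, abs=1e-9)
            np.testing.assert_allclose(
                fast.p_per_rho, direct.p_per_rho, rtol=1e-3, atol=1e-9
            )

    def test_null_pvalues_uniform(self, rng):
        n, m = 150, 6
        X = make_design(n, 3, rng)
        maf = rng.uniform(0.02, 0.2, m)
        G = make_genotypes(n, maf, rng)
        eng = SkatOTest(G, beta_weights(maf), X).prepare_fast()
        ps = np.array(
            [eng.test(rng.standard_normal(n), fast=True).p_skato for _ in range(400)]
        )
        assert kstest(ps, "uniform").pvalue > 0.001

    def test_mixed_signs_favour_skat_over_burden(self, rng):
        """With half-negative effects the variance-component end of the grid
        should typically beat the burden end."""
        n, m = 250, 8
        X = make_design(n, 2, rng)
        maf = np.full(m, 0.1)
        wins = 0
        reps = 60
        for _ in range(reps):
            G = make_genotypes(n, maf, rng)
            beta = 0.4 * np.where(np.arange(m) % 2 == 0, 1.0, -1.0)
            y = G @ beta + rng.standard_normal(n)
            null = fit_null(y, X)
            res = skat_o(null, G, beta_weights(maf))
            wins += res.p_per_rho[0] < res.p_per_rho[-1]
        assert wins > reps * 0.7

    def test_empty_set_rejected(self, rng):
        null = fit_null(rng.standard_normal(20), np.ones((20, 1)))
        with pytest.raises(DegenerateSetError):
            skat_o(null, np.empty((20, 0)), np.empty(0))

    def test_strong_signal_small_p(self, rng):
        n, m = 300, 6
        X = make_design(n, 2, rng)
        maf = np.full(m, 0.1)
        G = make_genotypes(n, maf, rng)
        y = G @ np.full(m, 0.8) + rng.standard_normal(n)
        null = fit_null(y, X)
        res = skat_o(null, G, beta_weights(maf))
        assert res.p_skato < 1e-6
        assert res.converged


class TestSingleVariantScan:
    def _gm(self, G):
        n, m = G.shape
        return GenotypeMatrix(
            samples=[f"s{i}" for i in range(n)],
            variants=pd.DataFrame(
                {"chrom": "1", "pos": np.arange(1, m + 1), "ref": "A",
                 "alt": "G", "info": np.nan}
            ),
            dosage=G,
        )

    def test_orthogonal_variant_null_effect(self, rng):
        n = 60
        X = np.ones((n, 1))
        y = rng.standard_normal(n)
        null = fit_null(y, X)
        g = rng.standard_normal(n)
        g -= g.mean()
        g -= (g @ null.residuals) / (null.residuals @ null.residuals) * null.residuals
        g = (g - g.min()) / (g.max() - g.min()) * 2  # rescale into [0, 2]
        # orthogonalize again after affine rescale (affine keeps orthogonality
        # up to the intercept which the projector removes)
        out = single_variant_scan(null, self._gm(g[:, None]))
        assert abs(out["beta"].iloc[0]) < 1e-9 or out["p"].iloc[0] > 0.9

    def test_planted_effect_recovered(self, rng):
        n = 100
        X = make_design(n, 2, rng)
        g = make_genotypes(n, [0.3], rng)[:, 0]
        y = 0.5 * g + X @ rng.standard_normal(X.shape[1]) + rng.standard_normal(n)
        null = fit_null(y, X)
        out = single_variant_scan(null, self._gm(g[:, None]))
        assert abs(out["beta"].iloc[0] - 0.5) < 3 * out["se"].iloc[0]

    def test_matches_statsmodels_joint_fit(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        n = 80
        X = make_design(n, 2, rng)
        G = make_genotypes(n, [0.2, 0.4], rng)
        y = rng.standard_normal(n) + 0.3 * G[:, 0]
        null = fit_null(y, X)
        out = single_variant_scan(null, self._gm(G))
        for j in range(2):
            fit = sm.OLS(y, np.column_stack([X, G[:, j]])).fit()
            assert out["beta"].iloc[j] == pytest.approx(fit.params[-1], rel=1e-8)
            assert out["se"].iloc[j] == pytest.approx(fit.bse[-1], rel=1e-8)
            assert out["p"].iloc[j] == pytest.approx(fit.pvalues[-1], rel=1e-6)

    def test_monomorphic_and_collinear_flagged(self, rng):
        n = 50
        X = make_design(n, 1, rng)
        mono = np.zeros(n)
        collinear = X[:, 1].copy()
        collinear = (collinear - collinear.min())
        collinear = 2 * collinear / collinear.max()
        G = np.column_stack([mono, collinear])
        null = fit_null(rng.standard_normal(n), X)
        out = single_variant_scan(null, self._gm(G))
        assert out["flag"].iloc[0] == "monomorphic"
        assert np.isnan(out["p"].iloc[0])
        assert out["flag"].iloc[1] == "collinear"


class TestMeanImpute:
    def test_fills_column_means(self):
        G = np.array([[0.0, 1.0], [2.0, np.nan], [1.0, np.nan]])
        out = mean_impute(G)
        np.testing.assert_allclose(out[:, 1], [1.0, 1.0, 1.0])
        np.testing.assert_allclose(out[:, 0], G[:, 0])
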