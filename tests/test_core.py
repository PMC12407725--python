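"""Unit tests for the standardization / site-effect / adjustment core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import combatpredict as cp
from combatpredict.core import SitePrior
from combatpredict.exceptions import (
    DataValidationError,
    DegenerateFeatureError,
    DegeneratePosteriorError,
    DegeneratePriorError,
    RankDeficientDesignError,
)


def _input(Y, sites, X=None, **kw):
    return cp.HarmonizationInput(
        Y=np.asarray(Y, float),
        sites=np.asarray(sites),
        X=np.asarray(X, float) if X is not None else np.empty((len(Y), 0)),
        **kw,
    )


# ---------------------------------------------------------------------------
# fit_standardization


class TestFitStandardization:
    def test_constant_within_site_raises_zero_variance(self):
        # site means 1 and 3 are fit exactly -> zero residual variance
        inp = _input([[1.0], [1.0], [3.0], [3.0]], ["A", "A", "B", "B"])
        with pytest.raises(DegenerateFeatureError, match="feature_0"):
            cp.fit_standardization(inp)

    def test_grand_mean_is_weighted_site_mean(self):
        rng = np.random.default_rng(0)
        Y = np.concatenate([rng.normal(1, 0.1, 4), rng.normal(3, 0.1, 4)])[:, None]
        inp = _input(Y, ["A"] * 4 + ["B"] * 4)
        std = cp.fit_standardization(inp)
        # equal n: alpha is the average of the two site means
        site_means = [Y[:4].mean(), Y[4:].mean()]
        assert std.alpha[0] == pytest.approx(np.mean(site_means), abs=1e-12)

    def test_beta_recovery_vs_normal_equations(self):
        rng = np.random.default_rng(1)
        n, p = 500, 3
        X = rng.normal(size=(n, p))
        b_true = np.array([0.5, -1.2, 0.3])
        Y = (2.0 + X @ b_true + rng.normal(0, 0.5, n))[:, None]
        inp = _input(Y, ["S"] * n, X)
        std = cp.fit_standardization(inp)
        # independent oracle: normal equations on [1 | X]
        D = np.column_stack([np.ones(n), X])
        b_ols = np.linalg.solve(D.T @ D, D.T @ Y).ravel()
        np.testing.assert_allclose(std.beta[:, 0], b_ols[1:], atol=1e-10)
        # recovers the truth within 3 standard errors
        resid_var = np.var(Y.ravel() - D @ b_ols, ddof=p + 1)
        se = np.sqrt(resid_var * np.diag(np.linalg.inv(D.T @ D))[1:])
        assert np.all(np.abs(std.beta[:, 0] - b_true) < 3 * se)

    def test_62_feature_layout(self):
        spec = cp.SimulationSpec(n_sites=6, n_features=62, site_sizes=8, seed=3)
        inp, _ = cp.generate_combat_data(spec)
        std = cp.fit_standardization(inp)
        assert std.alpha.shape == (62,) and std.sigma.shape == (62,)
        assert (std.sigma > 0).all()

    def test_confounded_covariate_named(self):
        rng = np.random.default_rng(2)
        sites = np.array(["A"] * 5 + ["B"] * 5)
        # covariate identical to the site-A indicator
        X = np.column_stack([rng.normal(size=10), (sites == "A").astype(float)])
        Y = rng.normal(size=(10, 2))
        inp = _input(Y, sites, X, covariate_names=["age", "scanner_flag"])
        with pytest.raises(RankDeficientDesignError, match="scanner_flag"):
            cp.fit_standardization(inp)

    def test_sigma_uses_divisor_n(self):
        # no covariates, 2 sites: sigma^2 must be SSR/N, not SSR/(N-K)
        rng = np.random.default_rng(4)
        Y = rng.normal(size=(8, 1))
        sites = np.array(["A"] * 4 + ["B"] * 4)
        inp = _input(Y, sites)
        std = cp.fit_standardization(inp)
        resid = Y.copy()
        for s in ("A", "B"):
            resid[sites == s] -= Y[sites == s].mean()
        assert std.sigma[0] ** 2 == pytest.approx(np.mean(resid**2), abs=1e-14)


# ---------------------------------------------------------------------------
# standardize


class TestStandardize:
    def test_exact_mean_surface_gives_zero(self):
        model = cp.StandardizationModel(
            alpha=[1.0, 2.0],
            beta=[[0.5, -0.5]],
            sigma=[1.0, 2.0],
            covariate_names=["x"],
            feature_names=["a", "b"],
        )
        X = np.array([[2.0], [4.0]])
        Y = model.mean(X)
        np.testing.assert_array_equal(cp.standardize(Y, X, model), 0.0)

    def test_direct_arithmetic(self):
        model = cp.StandardizationModel(
            alpha=[0.0], beta=np.empty((0, 1)), sigma=[2.0],
            covariate_names=[], feature_names=["a"],
        )
        Z = cp.standardize([[1.0]], np.empty((1, 0)), model)
        assert Z[0, 0] == 0.5

    def test_covariate_name_mismatch(self):
        model = cp.StandardizationModel(
            alpha=[0.0], beta=[[1.0]], sigma=[1.0],
            covariate_names=["age"], feature_names=["a"],
        )
        with pytest.raises(DataValidationError, match="covariate"):
            cp.standardize([[1.0]], [[1.0]], model, covariate_names=["sex"])

    def test_nonfinite_rejected(self):
        model = cp.StandardizationModel(
            alpha=[0.0], beta=np.empty((0, 1)), sigma=[1.0],
            covariate_names=[], feature_names=["a"],
        )
        with pytest.raises(DataValidationError):
            cp.standardize([[np.nan]], np.empty((1, 0)), model)


# ---------------------------------------------------------------------------
# mom_site_estimates


class TestMomSiteEstimates:
    def test_hand_arithmetic(self):
        mom = cp.mom_site_estimates(np.array([[1.0], [3.0]]), ["A", "A"])
        g, d2 = mom["A"]
        assert g[0] == 2.0 and d2[0] == 2.0

    def test_identical_values_zero_variance(self):
        mom = cp.mom_site_estimates(np.full((3, 2), 7.0), ["A"] * 3)
        g, d2 = mom["A"]
        np.testing.assert_array_equal(g, 7.0)
        np.testing.assert_array_equal(d2, 0.0)

    def test_site_of_one_rejected(self):
        with pytest.raises(DataValidationError, match="too small"):
            cp.mom_site_estimates(np.ones((3, 1)), ["A", "A", "B"])

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n, G = rng.integers(2, 8), rng.integers(1, 5)
        Z = rng.normal(size=(n, G))
        sites = ["S"] * n
        g, d2 = cp.mom_site_estimates(Z, sites)["S"]
        for gg in range(G):
            mean = sum(Z[j, gg] for j in range(n)) / n
            var = sum((Z[j, gg] - mean) ** 2 for j in range(n)) / (n - 1)
            assert g[gg] == pytest.approx(mean, rel=1e-12)
            assert d2[gg] == pytest.approx(var, rel=1e-9)


# ---------------------------------------------------------------------------
# estimate_priors


class TestEstimatePriors:
    def test_constant_gamma(self):
        prior = cp.estimate_priors([0.5, 0.5, 0.5], [1.0, 2.0, 3.0])
        assert prior.gamma_bar == 0.5 and prior.tau2 == 0.0

    def test_moment_round_trip(self):
        rng = np.random.default_rng(5)
        d2 = rng.uniform(0.5, 2.0, 50)
        prior = cp.estimate_priors(rng.normal(size=50), d2)
        m, s2 = d2.mean(), d2.var(ddof=1)
        # plug back into the InvGamma moments
        assert prior.theta / (prior.lam - 1) == pytest.approx(m, rel=1e-12)
        assert prior.theta**2 / ((prior.lam - 1) ** 2 * (prior.lam - 2)) == (
            pytest.approx(s2, rel=1e-12)
        )

    def test_simulation_recovery(self):
        rng = np.random.default_rng(6)
        d2 = 1.0 / rng.gamma(shape=4.0, scale=1.0 / 6.0, size=10_000)
        prior = cp.estimate_priors(rng.normal(size=10_000), d2)
        assert prior.lam == pytest.approx(4.0, rel=0.1)
        assert prior.theta == pytest.approx(6.0, rel=0.1)

    def test_degenerate_and_small(self):
        with pytest.raises(DegeneratePriorError):
            cp.estimate_priors([0.1, 0.2, 0.3], [1.0, 1.0, 1.0])
        with pytest.raises(DataValidationError):
            cp.estimate_priors([0.1], [1.0])


# ---------------------------------------------------------------------------
# eb_posterior


class TestEbPosterior:
    def _z(self, seed=7, n=6, G=4):
        return np.random.default_rng(seed).normal(0.3, 1.1, size=(n, G))

    def test_huge_tau2_no_shrinkage(self):
        Z = self._z()
        prior = SitePrior(gamma_bar=0.0, tau2=1e12, lam=4.0, theta=3.0)
        g, d, *_ = cp.eb_posterior(Z, prior)
        np.testing.assert_allclose(g, Z.mean(axis=0), atol=1e-8)

    def test_zero_tau2_total_shrinkage(self):
        Z = self._z()
        prior = SitePrior(gamma_bar=0.25, tau2=0.0, lam=4.0, theta=3.0)
        g, d, *_ = cp.eb_posterior(Z, prior)
        np.testing.assert_array_equal(g, 0.25)

    def test_degenerate_posterior_rejected(self):
        prior = SitePrior(gamma_bar=0.0, tau2=0.1, lam=-2.0, theta=3.0)
        with pytest.raises(DegeneratePosteriorError):
            cp.eb_posterior(self._z(n=4), prior)

    def test_first_update_is_convex_combination(self):
        # |gamma* - gamma_bar| <= |gamma_hat - gamma_bar| at the first
        # gamma update, for every feature
        Z = self._z(seed=8)
        n = Z.shape[0]
        gamma_hat = Z.mean(axis=0)
        d2 = Z.var(axis=0, ddof=1)
        prior = SitePrior(gamma_bar=0.1, tau2=0.05, lam=5.0, theta=4.0)
        g1 = (n * prior.tau2 * gamma_hat + d2 * prior.gamma_bar) / (
            n * prior.tau2 + d2
        )
        assert np.all(
            np.abs(g1 - prior.gamma_bar) <= np.abs(gamma_hat - prior.gamma_bar) + 1e-15
        )

    def test_fixed_point_satisfies_update_equations(self):
        Z = self._z(seed=9)
        n = Z.shape[0]
        prior = SitePrior(gamma_bar=0.1, tau2=0.05, lam=5.0, theta=4.0)
        g, d, it, conv = cp.eb_posterior(Z, prior, tol=1e-12, max_iter=2000)
        assert conv
        d2 = d**2
        g_next = (n * prior.tau2 * Z.mean(axis=0) + d2 * prior.gamma_bar) / (
            n * prior.tau2 + d2
        )
        d2_next = (prior.theta + 0.5 * ((Z - g_next) ** 2).sum(axis=0)) / (
            n / 2 + prior.lam - 1
        )
        np.testing.assert_allclose(g, g_next, rtol=1e-9)
        np.testing.assert_allclose(d2, d2_next, rtol=1e-9)

    def test_delta_update_is_conditional_posterior_mean(self):
        """The delta^2 update must equal the InvGamma conditional posterior
        mean, checked by 1-D quadrature."""
        Z = self._z(seed=10, n=4, G=2)
        prior = SitePrior(gamma_bar=0.1, tau2=0.002, lam=5.0, theta=4.0)
        g, d, *_ = cp.eb_posterior(Z, prior)
        n = Z.shape[0]
        for k in range(2):
            shape = prior.lam + n / 2
            scale = prior.theta + 0.5 * ((Z[:, k] - g[k]) ** 2).sum()
            grid = np.linspace(1e-5, 60, 600_001)
            w = stats.invgamma.pdf(grid, shape, scale=scale)
            cond_mean = np.trapezoid(w * grid, grid) / np.trapezoid(w, grid)
            assert d[k] ** 2 == pytest.approx(cond_mean, rel=1e-6)


# ---------------------------------------------------------------------------
# adjust


class TestAdjust:
    def _model(self, sigma=1.0):
        return cp.StandardizationModel(
            alpha=[10.0], beta=np.empty((0, 1)), sigma=[sigma],
            covariate_names=[], feature_names=["a"],
        )

    def test_identity_adjustment(self):
        model = self._model(sigma=2.0)
        Z = np.array([[1.5]])
        out = cp.adjust(Z, np.zeros(1), np.ones(1), model, np.empty((1, 0)))
        assert out[0, 0] == 10.0 + 2.0 * 1.5

    def test_hand_arithmetic(self):
        out = cp.adjust(
            np.array([[3.0]]), np.array([1.0]), np.array([2.0]),
            self._model(), np.empty((1, 0)),
        )
        assert out[0, 0] == pytest.approx(11.0)

    def test_nonpositive_delta_rejected(self):
        with pytest.raises(DataValidationError):
            cp.adjust(np.array([[1.0]]), np.zeros(1), np.zeros(1),
                      self._model(), np.empty((1, 0)))


# ---------------------------------------------------------------------------
# full fit invariants


class TestFitCombat:
    def test_constraint_weighted_gamma_sum(self, small_fit):
        resid = sum(e.n * e.gamma_hat for e in small_fit.site_effects.values())
        assert np.max(np.abs(resid)) < 1e-8

    def test_no_eb_restandardized_is_unit(self, small_input, small_fit_no_eb):
        inp, _ = small_input
        res = small_fit_no_eb
        Z = cp.standardize(res.harmonized, inp.X, res.standardization)
        for lab in res.site_effects:
            m = inp.sites == lab
            assert np.max(np.abs(Z[m].mean(axis=0))) < 1e-8
            assert np.max(np.abs(Z[m].var(axis=0, ddof=1) - 1)) < 1e-8

    def test_no_eb_stars_equal_raw(self, small_fit_no_eb):
        for e in small_fit_no_eb.site_effects.values():
            assert not e.eb_used
            np.testing.assert_array_equal(e.gamma_star, e.gamma_hat)
            np.testing.assert_allclose(e.delta_star**2, e.delta2_hat, rtol=1e-12)

    def test_shrinkage_ordering_at_fixed_point_gamma(self, small_fit):
        # the gamma fixed point stays a convex combination of gamma_hat and
        # the prior mean, hence never overshoots the raw estimate
        for e in small_fit.site_effects.values():
            assert np.all(
                np.abs(e.gamma_star - e.prior.gamma_bar)
                <= np.abs(e.gamma_hat - e.prior.gamma_bar) + 1e-12
            )

    def test_single_site_zscore_rescale(self):
        rng = np.random.default_rng(11)
        Y = rng.normal(5, 2, size=(40, 3))
        inp = _input(Y, ["S"] * 40)
        res = cp.CombatModel(inp).fit(eb=False)
        # alpha + sigma*(Z - gamma)/delta is a z-score re-scale: the mean is
        # preserved and the sd becomes the pooled sigma
        mu = Y.mean(0)
        np.testing.assert_allclose(res.harmonized.mean(0), mu, atol=1e-10)
        np.testing.assert_allclose(
            res.harmonized.std(0, ddof=1), res.standardization.sigma, rtol=1e-10
        )

    def test_harmonization_reduces_site_mean_deviation(self, small_input):
        inp, truth = small_input
        res = cp.CombatModel(inp).fit()
        # site-wise means of residuals from the covariate surface move
        # toward 0 for every site
        surface = truth.alpha[None, :] + inp.X @ truth.beta
        before = inp.Y - surface
        after = res.harmonized - surface
        for lab in res.site_effects:
            m = inp.sites == lab
            assert np.mean(np.abs(after[m].mean(0))) < np.mean(np.abs(before[m].mean(0)))

    def test_min_site_n_enforced(self):
        inp = _input(np.random.default_rng(0).normal(size=(5, 2)),
                     ["A", "A", "A", "B", "B"])
        with pytest.raises(DataValidationError, match="minimum size"):
            cp.CombatModel(inp).fit(min_site_n=3)

    def test_reference_site_rows_unchanged(self, small_input):
        inp, _ = small_input
        ref = inp.site_labels()[0]
        res = cp.CombatModel(inp).fit(reference_site=ref)
        m = inp.sites == ref
        np.testing.assert_allclose(res.harmonized[m], inp.Y[m], atol=1e-10)
        eff = res.site_effects[ref]
        assert eff.is_reference and not eff.eb_used
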