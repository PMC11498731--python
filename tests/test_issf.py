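"""Movement kernel, random steps, strata and conditional logistic estimation."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tigermove import issf, landscape as ls


def toy_strata(rng, n_strata, n_random=15, beta=(0.8,), names=("z",), diel=False):
    """Softmax-selection strata with iid N(0,1) covariates (no landscape)."""
    rows = []
    for i in range(n_strata):
        X = rng.normal(size=(n_random + 1, len(names)))
        w = np.exp(X @ np.asarray(beta))
        pick = rng.choice(len(w), p=w / w.sum())
        # reorder so the chosen row is first (the used step)
        order = np.r_[pick, np.delete(np.arange(len(w)), pick)]
        d = pd.DataFrame(X[order], columns=list(names))
        d.insert(0, "stratum", i)
        d.insert(1, "used", [1] + [0] * n_random)
        d["diel"] = rng.choice(["day", "night"]) if diel else "day"
        rows.append(d)
    return pd.concat(rows, ignore_index=True)


def oracle_clogit_loglik(beta, strata, names):
    """Direct per-stratum evaluation, independent of the package's vector code."""
    ll = 0.0
    for _, g in strata.groupby("stratum"):
        eta = g[list(names)].to_numpy() @ np.asarray(beta)
        ll += eta[g["used"].to_numpy() == 1][0] - math.log(np.exp(eta).sum())
    return ll


class TestKernelFit:
    def test_gamma_mle_recovers_parameters(self, rng):
        steps = pd.DataFrame({"step": rng.gamma(2.0, 100.0, 10_000),
                              "angle": rng.vonmises(0.0, 1.0, 10_000)})
        k = issf.fit_kernel(steps)
        assert k.shape == pytest.approx(2.0, rel=0.05)
        assert k.rate == pytest.approx(0.01, rel=0.05)
        assert k.mean_step == pytest.approx(k.shape / k.rate)

    def test_uniform_angles_give_near_zero_concentration(self, rng):
        steps = pd.DataFrame({"step": rng.gamma(2.0, 100.0, 10_000),
                              "angle": rng.uniform(-np.pi, np.pi, 10_000)})
        assert issf.fit_kernel(steps).kappa < 0.1

    def test_all_zero_steps_rejected(self):
        steps = pd.DataFrame({"step": np.zeros(100),
                              "angle": np.full(100, 0.1)})
        with pytest.raises(issf.SsfError):
            issf.fit_kernel(steps)


class TestRandomSteps:
    def test_monte_carlo_mean_step_matches_gamma_mean(self, rng):
        k = issf.MovementKernel(shape=2.0, rate=0.005, vm_mean=0.0, kappa=1.0)
        x, y, lens, _ = issf.generate_random_steps(0.0, 0.0, 0.3, k, n=100_000,
                                                   rng=rng)
        assert lens.mean() == pytest.approx(k.mean_step, rel=0.01)
        np.testing.assert_allclose(np.hypot(x, y), lens, atol=1e-9)

    def test_degenerate_kernel_projects_straight_ahead(self, rng):
        # near-infinite turn concentration + near-degenerate gamma
        k = issf.MovementKernel(shape=1e6, rate=1e4, vm_mean=0.0, kappa=1e8)
        bearing = 0.9
        x, y, lens, _ = issf.generate_random_steps(10.0, -5.0, bearing, k, n=50,
                                                   rng=rng)
        np.testing.assert_allclose(x, 10.0 + 100.0 * math.cos(bearing), rtol=1e-2)
        np.testing.assert_allclose(y, -5.0 + 100.0 * math.sin(bearing), rtol=1e-2)

    def test_undefined_bearing_rejected(self):
        k = issf.MovementKernel(shape=2.0, rate=0.01)
        with pytest.raises(issf.SsfError):
            issf.generate_random_steps(0.0, 0.0, np.nan, k)


@pytest.fixture(scope="module")
def built(ssf_steps, stack):
    k = issf.MovementKernel(shape=2.0, rate=0.005, vm_mean=0.0, kappa=1.0)
    return issf.build_strata(ssf_steps, stack, k, n_random=15, seed=4)


class TestBuildStrata:
    def test_exactly_one_used_row_per_stratum(self, built):
        strata, _ = built
        assert (strata.groupby("stratum")["used"].sum() == 1).all()

    def test_full_strata_have_sixteen_rows(self, built):
        strata, counts = built
        sizes = strata.groupby("stratum").size()
        assert sizes.max() == 16
        assert (sizes >= 2).all()
        assert counts["strata"] == sizes.size

    def test_dropping_candidates_never_removes_used_rows(self, built, ssf_steps):
        strata, counts = built
        usable = np.isfinite(ssf_steps["angle"])
        assert counts["strata"] + counts["strata_dropped"] == usable.sum()
        assert strata["used"].sum() == counts["strata"]

    def test_reproducible_under_seed(self, ssf_steps, stack):
        k = issf.MovementKernel(shape=2.0, rate=0.005, vm_mean=0.0, kappa=1.0)
        a, _ = issf.build_strata(ssf_steps.head(80), stack, k, seed=4)
        b, _ = issf.build_strata(ssf_steps.head(80), stack, k, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_forest_onehot_yields_two_columns_per_diel(self, built):
        strata, _ = built
        X, _ = issf.build_design(strata, ("forest:day", "forest:night",
                                          "open_forest:day", "open_forest:night"))
        assert list(X.columns) == ["forest:day", "forest:night",
                                   "open_forest:day", "open_forest:night"]
        # interactions partition the plain dummies
        X2, _ = issf.build_design(strata, ("forest", "open_forest"))
        np.testing.assert_allclose(X["forest:day"] + X["forest:night"], X2["forest"])


class TestClogit:
    def test_null_loglik_is_minus_n_log_sixteen(self, rng):
        strata = toy_strata(rng, 40)
        X = strata[["z"]].to_numpy()
        ll0 = issf.clogit_loglik(np.zeros(1), X, strata["used"].to_numpy(),
                                 strata["stratum"].to_numpy())
        assert ll0 == pytest.approx(-40 * math.log(16), abs=1e-10)

    def test_matches_dense_grid_search_on_toy_problem(self, rng):
        """Newton optimum within 1e-6 log-likelihood of a dense grid scan."""
        strata = toy_strata(rng, 3, beta=(1.2,))
        fit = issf.fit_clogit(strata, ("z",), standardizer=None)
        grid = np.linspace(-6, 6, 120_001)
        lls = [oracle_clogit_loglik([b], strata, ("z",)) for b in grid[::400]]
        coarse = grid[::400][int(np.argmax(lls))]
        fine = np.linspace(coarse - 0.1, coarse + 0.1, 20_001)
        ll_grid = max(oracle_clogit_loglik([b], strata, ("z",)) for b in fine)
        assert fit.loglik == pytest.approx(ll_grid, abs=1e-6)
        assert fit.loglik >= ll_grid - 1e-12

    def test_agrees_with_statsmodels_conditional_logit(self, rng):
        strata = toy_strata(rng, 150, beta=(0.7, -0.4), names=("z1", "z2"))
        fit = issf.fit_clogit(strata, ("z1", "z2"), standardizer=None)
        from statsmodels.discrete.conditional_models import ConditionalLogit

        res = ConditionalLogit(strata["used"].to_numpy(),
                               strata[["z1", "z2"]].to_numpy(),
                               groups=strata["stratum"].to_numpy()).fit(disp=False)
        np.testing.assert_allclose(fit.coef.to_numpy(), res.params, atol=2e-4)
        np.testing.assert_allclose(fit.se.to_numpy(), res.bse, rtol=2e-3)
        assert fit.loglik >= res.llf - 1e-6

    def test_stratum_constant_covariate_leaves_likelihood_unchanged(self, rng):
        strata = toy_strata(rng, 30, beta=(0.5,))
        X = strata[["z"]].to_numpy()
        y = strata["used"].to_numpy()
        g = strata["stratum"].to_numpy()
        base = issf.clogit_loglik(np.array([0.73]), X, y, g)
        shift = X + g[:, None] * 3.1  # constant within each stratum
        assert issf.clogit_loglik(np.array([0.73]), shift, y, g) == \
            pytest.approx(base, abs=1e-9)

    def test_complete_separation_raises(self, rng):
        rows = []
        for i in range(30):
            z = np.r_[5.0, rng.normal(size=15)]  # used always dominates
            rows.append(pd.DataFrame({"stratum": i, "used": [1] + [0] * 15,
                                      "z": z, "diel": "day"}))
        strata = pd.concat(rows, ignore_index=True)
        with pytest.raises(issf.SsfError):
            issf.fit_clogit(strata, ("z",), standardizer=None)


class TestCompareModels:
    def test_duplicated_spec_gives_identical_aic_and_definition_holds(self, rng):
        strata = toy_strata(rng, 60, beta=(0.6,))
        tab, fits = issf.compare_models(strata, {"a": ("z",), "b": ("z",)})
        assert tab["AIC"].iloc[0] == pytest.approx(tab["AIC"].iloc[1], abs=1e-8)
        f = fits["a"]
        assert f.aic == pytest.approx(2 * len(f.coef) - 2 * f.loglik)

    def test_pure_noise_covariate_worsens_aic_on_average(self, rng):
        deltas = []
        for _ in range(20):
            strata = toy_strata(rng, 80, beta=(0.6,))
            strata["noise"] = rng.normal(size=len(strata))
            tab, fits = issf.compare_models(
                strata, {"base": ("z",), "noisy": ("z", "noise")})
            deltas.append(fits["noisy"].aic - fits["base"].aic)
            # chi-square scale: the noise term buys < ~4 log-lik units
            assert fits["noisy"].loglik - fits["base"].loglik < 8.0
        assert np.mean(deltas) > 0


@pytest.fixture(scope="module")
def rss_fit():
    rng = np.random.default_rng(5)
    return issf.fit_clogit(toy_strata(rng, 400, beta=(0.9,)), ("z",),
                           standardizer=None)


class TestRss:
    def test_null_contrast_is_exactly_one(self, rss_fit):
        val, lo, hi = issf.rss(rss_fit, {"z": 0.4}, {"z": 0.4})
        assert (val, lo, hi) == (1.0, 1.0, 1.0)

    def test_doubling_the_contrast_squares_the_rss(self, rss_fit):
        r1, *_ = issf.rss(rss_fit, {"z": 1.0}, {"z": 0.0})
        r2, *_ = issf.rss(rss_fit, {"z": 2.0}, {"z": 0.0})
        assert r2 == pytest.approx(r1 ** 2)

    def test_unit_contrast_equals_exp_beta_with_wald_interval(self, rss_fit):
        val, lo, hi = issf.rss(rss_fit, {"z": 1.0}, {"z": 0.0})
        b, se = rss_fit.coef["z"], rss_fit.se["z"]
        assert val == pytest.approx(math.exp(b))
        assert lo == pytest.approx(math.exp(b - 1.959963984540054 * se))
        assert hi == pytest.approx(math.exp(b + 1.959963984540054 * se))

    def test_term_absent_from_model_rejected(self, rss_fit):
        with pytest.raises(issf.SsfError):
            issf.rss(rss_fit, {"ndvi": 1.0}, {"ndvi": 0.0})

    def test_monotone_in_the_contrast_direction(self, rss_fit):
        vals = [issf.rss(rss_fit, {"z": d}, {"z": 0.0})[0] for d in (0.0, 0.5, 1.0, 2.0)]
        assert all(a < b for a, b in zip(vals, vals[1:]))
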