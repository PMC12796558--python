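import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from krillscape.grids import GridSpec, GridStack
from krillscape.sdm import (
    ModelSpec,
    SDMFit,
    _LaplaceNLL,
    _build_design,
    aic_select,
    check_convergence,
    concurvity_screen,
    fit,
    fitted_values,
    predict,
    r2_decompose,
)
from krillscape.tweedie import tweedie_rvs

from oracles import tweedie_nll_oracle


def glm_oracle(y):
    """Independent Tweedie GLM maximum likelihood (intercept only)."""

    def nll(v):
        b0, lp, lphi = v
        p = 1.01 + 0.98 / (1 + np.exp(-lp))
        phi = np.exp(lphi)
        return tweedie_nll_oracle(y, float(np.exp(b0)), p, phi)

    res = minimize(
        nll,
        [np.log(y.mean()), 0.0, 0.0],
        method="Nelder-Mead",
        options={"xatol": 1e-9, "fatol": 1e-10, "maxiter": 3000},
    )
    b0, lp, lphi = res.x
    return np.exp(b0), 1.01 + 0.98 / (1 + np.exp(-lp)), np.exp(lphi)


class TestModelSpec:
    def test_small_k_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(smooth_terms=(("sst", 2),))

    def test_mesh_control_exclusive(self):
        with pytest.raises(ValueError):
            ModelSpec(include_spatial_field=True)
        with pytest.raises(ValueError):
            ModelSpec(include_spatial_field=True, n_knots=50, cutoff_km=15.0)


class TestReducedModelEquivalence:
    def test_intercept_only_matches_glm_oracle(self, glm_obs):
        f = fit(glm_obs.iloc[:600], ModelSpec())
        y = glm_obs["nasc"].to_numpy()[:600]
        mu_o, p_o, phi_o = glm_oracle(y)
        assert f.mu_intercept == pytest.approx(mu_o, abs=1e-3 * mu_o)
        assert f.tweedie_p == pytest.approx(p_o, abs=1e-3)
        assert f.tweedie_phi == pytest.approx(phi_o, abs=1e-3 * phi_o)

    def test_aic_identity(self, glm_obs):
        f = fit(glm_obs, ModelSpec())
        assert f.aic == pytest.approx(-2 * f.loglik + 2 * f.n_params, abs=1e-9)

    def test_gradient_small_at_optimum(self, glm_obs):
        f = fit(glm_obs, ModelSpec())
        assert f.gradient_max < 0.01


class TestConcurvity:
    def test_correlated_pair_never_cooccurs(self, rng):
        x = rng.normal(size=500)
        tbl = pd.DataFrame(
            {
                "a": x,
                "b": 0.97 * x + 0.1 * rng.normal(size=500),  # r2 ~ 0.9
                "c": rng.normal(size=500),
            }
        )
        assert tbl[["a", "b"]].corr().iloc[0, 1] ** 2 > 0.7
        subsets = concurvity_screen(tbl)
        for s in subsets:
            assert not ({"a", "b"} <= set(s))

    def test_duplicate_excluded(self, rng):
        x = rng.normal(size=200)
        subsets = concurvity_screen(pd.DataFrame({"a": x, "a2": x.copy()}))
        assert ("a",) in subsets and ("a2",) in subsets
        assert ("a", "a2") not in subsets

    def test_independent_full_set_admissible(self, rng):
        tbl = pd.DataFrame(rng.normal(size=(2000, 3)), columns=["u", "v", "w"])
        r2 = tbl.corr().to_numpy() ** 2
        assert r2[np.triu_indices(3, 1)].max() < 0.1
        subsets = concurvity_screen(tbl)
        assert ("u", "v", "w") in subsets

    def test_constant_covariate_warned(self, rng):
        tbl = pd.DataFrame({"a": rng.normal(size=50), "b": np.ones(50)})
        with pytest.warns(UserWarning, match="constant"):
            subsets = concurvity_screen(tbl)
        assert all("b" not in s for s in subsets)

    def test_too_few_covariates(self):
        with pytest.raises(ValueError):
            concurvity_screen(pd.DataFrame({"a": [1.0, 2.0]}))


def _dummy_fit(gradient_max=0.005, hessian_pd=True, sigmas=(0.3, 0.8), name="m", loglik=-100.0, n_params=4):
    theta = {"p": 1.5, "phi": 1.0}
    for key, sd in zip(("sigma_spatial", "sigma_st"), sigmas):
        if sd is not None:
            theta[key] = sd
    return SDMFit(
        spec=ModelSpec(name=name),
        theta=theta,
        loglik=loglik,
        aic=-2 * loglik + 2 * n_params,
        n_params=n_params,
        gradient_max=gradient_max,
        hessian_pd=hessian_pd,
    )


class TestConvergenceChecks:
    def test_pass_case(self):
        rep = check_convergence(_dummy_fit())
        assert rep["passed"]

    def test_gradient_failure(self):
        rep = check_convergence(_dummy_fit(gradient_max=0.02))
        assert not rep["passed"] and "gradient" in rep["reasons"]

    def test_degenerate_field_failure(self):
        rep = check_convergence(_dummy_fit(sigmas=(0.001, 0.8)))
        assert not rep["passed"]
        assert any("degenerate" in r for r in rep["reasons"])

    def test_hessian_failure(self):
        rep = check_convergence(_dummy_fit(hessian_pd=False))
        assert "hessian" in rep["reasons"]


class TestAicSelect:
    def test_same_model_twice_delta_zero(self):
        tbl = aic_select([_dummy_fit(name="a"), _dummy_fit(name="b")])
        assert (tbl["delta_aic"] == 0).all()

    def test_one_extra_param_identical_loglik(self):
        tbl = aic_select(
            [_dummy_fit(name="small", n_params=4), _dummy_fit(name="big", n_params=5)]
        )
        assert tbl.iloc[0]["name"] == "small"
        assert tbl.iloc[1]["delta_aic"] == pytest.approx(2.0)

    def test_nonconverged_excluded(self):
        with pytest.warns(UserWarning, match="non-converged"):
            tbl = aic_select([_dummy_fit(name="good"), _dummy_fit(name="bad", gradient_max=1.0)])
        assert list(tbl["name"]) == ["good"]

    def test_all_nonconverged_raises(self):
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                aic_select([_dummy_fit(gradient_max=1.0)])


@pytest.fixture(scope="module")
def spatial_fit_and_obs():
    """Spatial-field fit on cell-center observations (shared: fitting is slow)."""
    rng = np.random.default_rng(7)
    grid = GridSpec(0, 0, 3.0, 20, 20)
    centers = grid.cell_centers()
    # smooth latent surface on the grid
    latent = 0.8 * np.sin(centers[:, 0] / 15.0) + 0.6 * np.cos(centers[:, 1] / 20.0)
    mu = np.exp(0.3 + latent)
    y = tweedie_rvs(mu, 1.5, 0.3, rng)
    obs = pd.DataFrame(
        {"x_km": centers[:, 0], "y_km": centers[:, 1], "year": 2018, "nasc": y}
    )
    spec = ModelSpec(include_spatial_field=True, n_knots=60, name="spatial")
    return fit(obs, spec, seed=0), obs, grid, latent


class TestFitWithFields:
    def test_degenerate_spatial_field_flagged(self):
        # truth has no spatial field; the estimated SD collapses below
        # the 0.01 degeneracy threshold
        rng = np.random.default_rng(0)
        n = 1500
        obs = pd.DataFrame(
            {
                "x_km": rng.uniform(0, 60, n),
                "y_km": rng.uniform(0, 60, n),
                "year": 2018,
                "nasc": tweedie_rvs(2.0, 1.5, 0.8, rng, size=n),
            }
        )
        f = fit(obs, ModelSpec(include_spatial_field=True, n_knots=15))
        assert f.sigma_spatial < 0.01
        rep = check_convergence(f)
        assert any("degenerate" in r for r in rep["reasons"])

    def test_prediction_matches_fitted_at_observations(self, spatial_fit_and_obs):
        f, obs, grid, _ = spatial_fit_and_obs
        pred = predict(f, GridStack(grid, [2018], {}), years=[2018])
        fitted = fitted_values(f, obs)
        np.testing.assert_allclose(pred.data["response"][0].ravel(), fitted, rtol=1e-8)

    def test_response_is_exp_link(self, spatial_fit_and_obs):
        f, obs, grid, _ = spatial_fit_and_obs
        pred = predict(f, GridStack(grid, [2018], {}), years=[2018])
        np.testing.assert_allclose(
            pred.data["response"], np.exp(pred.data["link"]), rtol=1e-12
        )
        assert (pred.data["response"] > 0).all()

    def test_latent_surface_recovered(self, spatial_fit_and_obs):
        f, obs, grid, latent = spatial_fit_and_obs
        pred = predict(f, GridStack(grid, [2018], {}), years=[2018])
        r = np.corrcoef(pred.data["link"][0].ravel(), latent)[0, 1]
        assert r > 0.8

    def test_translation_equivariance(self, rng):
        n = 300
        base = pd.DataFrame(
            {
                "x_km": rng.uniform(0, 50, n),
                "y_km": rng.uniform(0, 50, n),
                "year": 2018,
                "nasc": tweedie_rvs(1.5, 1.5, 0.5, rng, size=n),
            }
        )
        shifted = base.copy()
        shifted["x_km"] += 1000.0
        shifted["y_km"] += 2000.0
        spec = ModelSpec(include_spatial_field=True, n_knots=20)
        f1 = fit(base, spec, seed=0)
        f2 = fit(shifted, spec, seed=0)
        np.testing.assert_allclose(
            fitted_values(f1, base), fitted_values(f2, shifted), rtol=1e-5
        )

    def test_likelihood_never_below_initialization(self, glm_obs):
        spec = ModelSpec(include_spatial_field=True, n_knots=20)
        design = _build_design(glm_obs, spec, seed=0)
        nll = _LaplaceNLL(glm_obs["nasc"].to_numpy(float), design, glm_obs)
        psi0 = np.zeros(nll.n_beta + len(nll.theta_names))
        psi0[0] = np.log(glm_obs["nasc"].mean())
        psi0[nll.n_beta :] = np.log(0.5)
        f = fit(glm_obs, spec, seed=0)
        assert -f.loglik <= nll.value(psi0) + 1e-6


class TestSmoothTerms:
    def test_smooth_recovers_nonlinear_effect(self, rng):
        n = 1200
        x = rng.uniform(-2, 2, n)
        mu = np.exp(0.5 + np.sin(1.5 * x))
        y = tweedie_rvs(mu, 1.5, 0.2, rng)
        obs = pd.DataFrame(
            {"x_km": rng.uniform(0, 50, n), "y_km": rng.uniform(0, 50, n),
             "year": 2018, "nasc": y, "sst": x}
        )
        f = fit(obs, ModelSpec(smooth_terms=(("sst", 6),)))
        fv = np.log(fitted_values(f, obs))
        r = np.corrcoef(fv, 0.5 + np.sin(1.5 * x))[0, 1]
        assert r > 0.95

    def test_missing_covariate_named_in_error(self, glm_obs):
        f = fit(glm_obs.assign(sst=np.random.default_rng(0).normal(size=len(glm_obs))),
                ModelSpec(smooth_terms=(("sst", 4),)))
        grid = GridSpec(0, 0, 10.0, 5, 5)
        with pytest.raises(KeyError, match="sst"):
            predict(f, GridStack(grid, [2018], {}), years=[2018])


class TestR2:
    def test_conditional_at_least_marginal(self, spatial_fit_and_obs):
        f, obs, _, _ = spatial_fit_and_obs
        rep = r2_decompose(f, obs)
        assert 0 <= rep.marginal_r2 <= rep.conditional_r2 <= 1
        assert rep.spatiotemporal_r2 == pytest.approx(
            rep.conditional_r2 - rep.marginal_r2, abs=1e-12
        )

    def test_near_deterministic_data_r2_one(self, rng):
        n = 600
        x = rng.uniform(-2, 2, n)
        mu = np.exp(1.0 + 0.8 * x)
        y = tweedie_rvs(mu, 1.5, 0.01, rng)  # tiny dispersion
        obs = pd.DataFrame(
            {"x_km": rng.uniform(0, 10, n), "y_km": rng.uniform(0, 10, n),
             "year": 2018, "nasc": y, "cov": x}
        )
        f = fit(obs, ModelSpec(linear_terms=("cov",)))
        assert r2_decompose(f, obs).conditional_r2 > 0.99

    def test_covariate_only_truth_marginal_close_to_conditional(self, rng):
        n = 900
        x = rng.uniform(-1, 1, n)
        mu = np.exp(0.5 + 0.9 * x)
        y = tweedie_rvs(mu, 1.5, 0.3, rng)
        obs = pd.DataFrame(
            {"x_km": rng.uniform(0, 80, n), "y_km": rng.uniform(0, 80, n),
             "year": 2018, "nasc": y, "cov": x}
        )
        f = fit(obs, ModelSpec(linear_terms=("cov",), include_spatial_field=True, n_knots=20))
        rep = r2_decompose(f, obs)
        assert rep.conditional_r2 - rep.marginal_r2 < 0.05

    def test_zero_variance_observations_rejected(self, spatial_fit_and_obs):
        f, obs, _, _ = spatial_fit_and_obs
        bad = obs.copy()
        bad["nasc"] = 1.0
        with pytest.raises(ValueError):
            r2_decompose(f, bad)
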