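"""Mixed models: standardisation, VIF, MELR/LMM fits, posterior simulation."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from wheatrack import models
from wheatrack.models import ModelSpec


# --- z-transform ----------------------------------------------------------


def test_z_transform_simple_column():
    t = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
    out, sc = models.z_transform(t, ["a"])
    np.testing.assert_allclose(out["a"], [-np.sqrt(1.5), 0, np.sqrt(1.5)])
    assert sc["a"][0] == 2.0


def test_z_transform_idempotent_and_exact():
    rng = np.random.default_rng(0)
    t = pd.DataFrame({"a": rng.normal(3, 7, 500)})
    z1, _ = models.z_transform(t, ["a"])
    assert abs(z1["a"].mean()) < 1e-12
    assert abs(z1["a"].std(ddof=0) - 1) < 1e-12
    z2, _ = models.z_transform(z1, ["a"])
    np.testing.assert_allclose(z1["a"], z2["a"], atol=1e-12)


def test_z_transform_zero_variance_named():
    t = pd.DataFrame({"ok": [1.0, 2.0], "flat": [5.0, 5.0]})
    with pytest.raises(ValueError, match="flat"):
        models.z_transform(t, ["ok", "flat"])


# --- VIF ------------------------------------------------------------------


def test_vif_orthogonal_predictors_all_one():
    rng = np.random.default_rng(1)
    n = 2000
    t = pd.DataFrame({"a": rng.standard_normal(n), "b": rng.standard_normal(n),
                      "c": rng.standard_normal(n)})
    v = models.vif(t, ["a", "b", "c"])
    assert (v < 1.01).all()


def test_vif_matches_closed_form_for_two_predictors():
    rng = np.random.default_rng(2)
    n = 100000
    a = rng.standard_normal(n)
    b = 0.9 * a + np.sqrt(1 - 0.81) * rng.standard_normal(n)
    t = pd.DataFrame({"a": a, "b": b})
    v = models.vif(t, ["a", "b"])
    r2 = np.corrcoef(a, b)[0, 1] ** 2
    assert v["a"] == pytest.approx(1 / (1 - r2), rel=1e-6)
    assert v["a"] == pytest.approx(1 / (1 - 0.81), rel=0.05)


def test_vif_screen_drops_collinear_member():
    rng = np.random.default_rng(3)
    n = 3000
    dist = rng.standard_normal(n)
    temp = -0.95 * dist + np.sqrt(1 - 0.95**2) * rng.standard_normal(n)
    other = rng.standard_normal(n)
    t = pd.DataFrame({"temperature": temp, "other": other, "remaining_distance": dist})
    kept, report = models.vif_screen(t, ["temperature", "other", "remaining_distance"], 2.0)
    assert len(report) == 1
    assert report.dropped.iloc[0] in ("temperature", "remaining_distance")
    assert "other" in kept


def test_vif_screen_perfect_tie_drops_later_listed():
    rng = np.random.default_rng(4)
    a = rng.standard_normal(500)
    t = pd.DataFrame({"a": a, "b": a.copy()})
    kept, report = models.vif_screen(t, ["a", "b"], 2.0)
    assert kept == ["a"]
    assert report.dropped.iloc[0] == "b"


def test_vif_needs_two_predictors():
    with pytest.raises(ValueError):
        models.vif(pd.DataFrame({"a": [1.0, 2.0]}), ["a"])


# --- design / spec --------------------------------------------------------


def test_interaction_without_main_effect_rejected():
    with pytest.raises(ValueError, match="main effect"):
        ModelSpec(response="y", fixed=["a:b"], family="binomial")


def test_listwise_dropping_counted():
    t = pd.DataFrame({"y": [0, 1, 1, np.nan], "a": [1.0, np.nan, 0.5, 0.2],
                      "g": [0, 0, 1, 1]})
    X, y, codes, w, terms, nd = models.build_design(
        t, ModelSpec(response="y", fixed=["a"], group="g"))
    assert nd == 2 and len(y) == 2


# --- MELR -----------------------------------------------------------------


def _sim_binomial(seed, n=800, G=6, beta=(0.2, 0.5, -0.4), sigma_u=0.3):
    rng = np.random.default_rng(seed)
    t = pd.DataFrame({"x1": rng.standard_normal(n), "x2": rng.standard_normal(n),
                      "g": rng.integers(0, G, n)})
    u = rng.normal(0, sigma_u, G)
    eta = beta[0] + beta[1] * t.x1 + beta[2] * t.x2 + u[t.g]
    t["y"] = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    return t


def test_melr_loglik_matches_brute_force_quadrature():
    """Adaptive Gauss-Hermite marginal likelihood vs direct numerical
    integration of the random-intercept integral on a 50-row toy set."""
    t = _sim_binomial(7, n=50, G=2)
    spec = ModelSpec(response="y", fixed=["x1", "x2"], group="g", family="binomial")
    X, y, codes, w, terms, _ = models.build_design(t, spec)
    gh = np.polynomial.hermite.hermgauss(15)
    beta = np.array([0.1, 0.4, -0.2])
    ls = np.log(0.35)
    ll, _ = models._melr_loglik(beta, ls, X, y, codes, 2, (gh[0], np.log(gh[1])), None)
    sigma = np.exp(ls)
    brute = 0.0
    for g in range(2):
        m = codes == g
        e0 = X[m] @ beta
        f = lambda u: np.exp(
            np.sum(np.where(y[m] == 1, -np.logaddexp(0, -(e0 + u)), -np.logaddexp(0, e0 + u)))
        ) * stats.norm.pdf(u, 0, sigma)
        v, _ = integrate.quad(f, -8 * sigma, 8 * sigma, limit=200)
        brute += np.log(v)
    assert ll == pytest.approx(brute, abs=1e-6)


def test_melr_equals_plain_logistic_when_variance_zero():
    """With no group structure the mixed fit collapses onto ordinary
    logistic ML (the statsmodels oracle)."""
    import statsmodels.api as sm

    t = _sim_binomial(8, n=1500, G=6, sigma_u=0.0)
    spec = ModelSpec(response="y", fixed=["x1", "x2"], group="g", family="binomial")
    fit = models.fit_melr(t, spec)
    lf = sm.Logit(t.y, sm.add_constant(t[["x1", "x2"]])).fit(disp=0)
    np.testing.assert_allclose(fit.coef, lf.params.values, atol=0.02)
    assert fit.random_sd < 0.1


def test_melr_recovers_coefficients():
    t = _sim_binomial(9, n=4000, G=8)
    spec = ModelSpec(response="y", fixed=["x1", "x2"], group="g", family="binomial")
    fit = models.fit_melr(t, spec)
    se = np.sqrt(np.diag(fit.cov))
    z = (fit.coef - np.array([0.2, 0.5, -0.4])) / se
    assert np.all(np.abs(z) < 3)
    assert 0.5 < fit.scale < 1.6


def test_melr_boundary_variance_flagged():
    t = _sim_binomial(0, n=2000, G=6, sigma_u=0.0)
    spec = ModelSpec(response="y", fixed=["x1"], group="g", family="binomial")
    fit = models.fit_melr(t, spec)
    assert fit.random_sd < 0.01
    assert fit.singular_random


def test_melr_single_group_falls_back_with_warning():
    t = _sim_binomial(11, n=300, G=1)
    spec = ModelSpec(response="y", fixed=["x1"], group="g", family="binomial")
    with pytest.warns(UserWarning, match="fewer than 2 groups"):
        fit = models.fit_melr(t, spec)
    assert fit.random_sd == 0.0


def test_melr_complete_separation_raises():
    t = pd.DataFrame({"x1": np.r_[np.ones(30), -np.ones(30)],
                      "y": np.r_[np.ones(30), np.zeros(30)],
                      "g": np.tile([0, 1], 30)})
    spec = ModelSpec(response="y", fixed=["x1"], group="g", family="binomial")
    with pytest.raises(RuntimeError, match="separation"):
        models.fit_melr(t, spec)


def test_scale_equivariance_of_fitted_probabilities():
    """Fitting on raw vs z-scored covariates gives identical fitted
    probabilities: the model is equivariant under affine predictor maps."""
    t = _sim_binomial(12, n=800, G=4)
    t["x1_raw"] = 10.0 + 5.0 * t.x1
    spec_z = ModelSpec(response="y", fixed=["x1"], group="g", family="binomial")
    spec_r = ModelSpec(response="y", fixed=["x1_raw"], group="g", family="binomial")
    fz = models.fit_melr(t, spec_z)
    fr = models.fit_melr(t, spec_r)
    eta_z = fz.coef[0] + fz.coef[1] * t.x1
    eta_r = fr.coef[0] + fr.coef[1] * t.x1_raw
    np.testing.assert_allclose(eta_z, eta_r, atol=1e-4)


# --- LMM ------------------------------------------------------------------


def _sim_gaussian(seed, n=500, G=8, beta=(1.0, 0.6), sigma_u=0.5, sigma=0.8,
                  heteroskedastic=False):
    rng = np.random.default_rng(seed)
    t = pd.DataFrame({"x1": rng.standard_normal(n), "g": rng.integers(0, G, n)})
    u = rng.normal(0, sigma_u, G)
    sd = sigma * (1.0 + heteroskedastic * rng.uniform(0, 1.5, n))
    t["w"] = 1.0 / sd**2
    t["y"] = beta[0] + beta[1] * t.x1 + u[t.g] + rng.normal(0, sd, n)
    return t


def test_lmm_matches_statsmodels_unweighted():
    import statsmodels.formula.api as smf

    t = _sim_gaussian(13)
    fit = models.fit_lmm(t, ModelSpec(response="y", fixed=["x1"], group="g",
                                      family="gaussian"))
    sm_fit = smf.mixedlm("y ~ x1", t, groups=t["g"]).fit(reml=True)
    np.testing.assert_allclose(fit.coef, sm_fit.fe_params.values, atol=1e-5)
    assert fit.random_sd == pytest.approx(np.sqrt(sm_fit.cov_re.iloc[0, 0]), abs=1e-4)
    assert fit.resid_sd == pytest.approx(np.sqrt(sm_fit.scale), abs=1e-4)
    np.testing.assert_allclose(np.sqrt(np.diag(fit.cov)), sm_fit.bse_fe.values, atol=1e-5)


def test_lmm_all_weights_equal_is_unweighted():
    t = _sim_gaussian(14)
    t["w"] = 2.5
    f1 = models.fit_lmm(t, ModelSpec(response="y", fixed=["x1"], group="g",
                                     family="gaussian"))
    f2 = models.fit_lmm(t, ModelSpec(response="y", fixed=["x1"], group="g",
                                     family="gaussian", weights="w"))
    np.testing.assert_allclose(f1.coef, f2.coef, atol=1e-8)
    assert f1.random_sd == pytest.approx(f2.random_sd, abs=1e-6)


def test_lmm_weighted_recovery():
    t = _sim_gaussian(15, n=2000, heteroskedastic=True)
    fit = models.fit_lmm(t, ModelSpec(response="y", fixed=["x1"], group="g",
                                      family="gaussian", weights="w"))
    se = np.sqrt(np.diag(fit.cov))
    assert abs(fit.coef[1] - 0.6) < 3 * se[1]


def test_lmm_log10_transform():
    t = _sim_gaussian(16)
    t["resp"] = 10.0 ** t.y
    fit = models.fit_lmm(t, ModelSpec(response="resp", fixed=["x1"], group="g",
                                      family="gaussian", transform="log10"))
    assert abs(fit.coef[1] - 0.6) < 3 * np.sqrt(fit.cov[1, 1])


def test_lmm_singular_random_effect_flagged():
    t = _sim_gaussian(17, sigma_u=0.0, G=4)
    fit = models.fit_lmm(t, ModelSpec(response="y", fixed=["x1"], group="g",
                                      family="gaussian"))
    assert fit.random_sd < 0.05
    assert fit.singular_random


def test_lmm_closed_form_regression_on_constructed_data():
    """Noise-free constructed relationship: total speed = c / duration, so
    log10(speed) on log10(duration) has slope exactly -1."""
    duration = np.array([20.0, 30.0, 45.0, 60.0, 80.0, 100.0, 25.0, 55.0])
    speed = 5000.0 / duration
    t = pd.DataFrame({"speed": speed, "logdur": np.log10(duration),
                      "g": [0, 0, 0, 0, 1, 1, 1, 1]})
    fit = models.fit_lmm(t, ModelSpec(response="speed", fixed=["logdur"], group="g",
                                      family="gaussian", transform="log10"))
    assert fit.coef[1] == pytest.approx(-1.0, abs=1e-8)
    assert fit.resid_sd == pytest.approx(0.0, abs=1e-7)


# --- posterior simulation, predictions, R^2 -------------------------------


def test_posterior_median_consistent_with_point_estimate():
    t = _sim_gaussian(18)
    fit = models.fit_lmm(t, ModelSpec(response="y", fixed=["x1"], group="g",
                                      family="gaussian"))
    s = models.posterior_sim(fit, 4000, seed=0)
    mc_se = np.sqrt(np.diag(fit.cov)) / np.sqrt(4000)
    assert np.all(np.abs(s.estimate.values - fit.coef) < 4 * np.sqrt(np.diag(fit.cov)) / 10)


def test_posterior_cri_converges_to_normal_interval():
    t = _sim_gaussian(19, n=3000)
    fit = models.fit_lmm(t, ModelSpec(response="y", fixed=["x1"], group="g",
                                      family="gaussian"))
    s = models.posterior_sim(fit, 100000, seed=1)
    se = np.sqrt(np.diag(fit.cov))
    np.testing.assert_allclose(s.cri_lo.values, fit.coef - 1.96 * se, atol=0.012)
    np.testing.assert_allclose(s.cri_hi.values, fit.coef + 1.96 * se, atol=0.012)


def test_posterior_sim_needs_enough_draws():
    t = _sim_gaussian(20)
    fit = models.fit_lmm(t, ModelSpec(response="y", fixed=["x1"], group="g",
                                      family="gaussian"))
    with pytest.raises(ValueError):
        models.posterior_sim(fit, 100)


def test_strong_effects_declared_significant():
    t = _sim_gaussian(21, n=2000, beta=(1.0, 1.5))
    fit = models.fit_lmm(t, ModelSpec(response="y", fixed=["x1"], group="g",
                                      family="gaussian"))
    s = models.posterior_sim(fit, 2000, seed=2)
    assert bool(s.set_index("term").loc["x1", "significant"])


def test_effect_predictions_no_interaction_parallel():
    rng = np.random.default_rng(22)
    n = 3000
    t = pd.DataFrame({"a": rng.standard_normal(n), "b": rng.standard_normal(n),
                      "g": rng.integers(0, 4, n)})
    eta = 0.8 * t.a + 0.0 * t.a * t.b
    t["y"] = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    spec = ModelSpec(response="y", fixed=["a", "b", "a:b"], group="g", family="binomial")
    fit = models.fit_melr(t, spec)
    models.posterior_sim(fit, 2000, seed=3)
    grid = models.effect_predictions(fit, t, "a:b")
    assert len(grid) == 25
    # slopes across the b categories agree within the interval noise
    piv = grid.pivot_table(index="category_a", columns="category_b", values="predicted")
    slopes = piv.iloc[-1] - piv.iloc[0]
    assert slopes.max() - slopes.min() < 0.35


def test_effect_predictions_sign_flip_reproduced():
    rng = np.random.default_rng(23)
    n = 4000
    t = pd.DataFrame({"a": rng.standard_normal(n), "b": rng.standard_normal(n),
                      "g": rng.integers(0, 4, n)})
    eta = 0.0 + 0.0 * t.a + 1.0 * t.a * t.b  # slope +/- by sign of b
    t["y"] = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    spec = ModelSpec(response="y", fixed=["a", "b", "a:b"], group="g", family="binomial")
    fit = models.fit_melr(t, spec)
    models.posterior_sim(fit, 2000, seed=4)
    grid = models.effect_predictions(fit, t, "a:b")
    piv = grid.pivot_table(index="category_a", columns="category_b", values="predicted")
    slope_low_b = piv[0].iloc[-1] - piv[0].iloc[0]
    slope_high_b = piv[4].iloc[-1] - piv[4].iloc[0]
    assert slope_low_b < 0 < slope_high_b


def test_prediction_at_means_is_inverse_link_of_intercept():
    t = _sim_binomial(24, n=1000, G=4)
    spec = ModelSpec(response="y", fixed=["x1", "x2", "x1:x2"], group="g",
                     family="binomial")
    fit = models.fit_melr(t, spec)
    models.posterior_sim(fit, 5000, seed=5)
    grid = models.effect_predictions(fit, t.assign(x1=t.x1 * 1e-9, x2=t.x2 * 1e-9), "x1:x2")
    expect = 1 / (1 + np.exp(-fit.coef[0]))
    assert np.nanmax(np.abs(grid.predicted - expect)) < 0.02


def test_r2_equal_when_no_random_variance():
    t = _sim_gaussian(25, sigma_u=0.0, G=4)
    fit = models.fit_lmm(t, ModelSpec(response="y", fixed=["x1"], group="g",
                                      family="gaussian"))
    r = models.r_squared(fit)
    assert r["marginal"] == pytest.approx(r["conditional"], abs=1e-4)


def test_r2_near_zero_for_pure_noise():
    rng = np.random.default_rng(26)
    n = 5000
    t = pd.DataFrame({"x1": rng.standard_normal(n), "g": rng.integers(0, 6, n),
                      "y": (rng.random(n) < 0.5).astype(float)})
    fit = models.fit_melr(t, ModelSpec(response="y", fixed=["x1"], group="g",
                                       family="binomial"))
    r = models.r_squared(fit)
    assert r["conditional"] < 0.05


def test_r2_approaches_one_when_noise_vanishes():
    rng = np.random.default_rng(27)
    n = 400
    t = pd.DataFrame({"x1": rng.standard_normal(n), "g": rng.integers(0, 4, n)})
    t["y"] = 2.0 * t.x1 + rng.normal(0, 1e-4, n)
    fit = models.fit_lmm(t, ModelSpec(response="y", fixed=["x1"], group="g",
                                      family="gaussian"))
    r = models.r_squared(fit)
    assert r["marginal"] > 0.999
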