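"""Three-stage estimator: suite selection, prior structure, smoothing and GP
oracles, draw summaries, composition of stages."""

import numpy as np
import pandas as pd
import pytest

from fpstgpr.constants import AGE_GROUPS
from fpstgpr.hierarchy import LocationHierarchy
from fpstgpr.stgpr import STGPR, StGprConfig, expit, logit, summarize_draws
from fpstgpr.synthetic import GeneratorParams, generate_covariates, generate_world

from fpstgpr.indicators import extract_estimates


def _estimates_from_surface(world, quantity="cpr", marital="partnered", se=0.01,
                            years=None):
    """Noise-free estimates taken directly off the truth surface."""
    wide = world.surface.wide.xs(marital, level="marital")
    df = wide.reset_index()[["location_id", "year", "age_group", quantity]]
    if years is not None:
        df = df[df["year"].isin(years)]
    df = df.rename(columns={quantity: "mean"})
    df["survey_id"] = "T_" + df["location_id"].astype(str) + "_" + df["year"].astype(str)
    df["marital"] = marital
    df["quantity"] = quantity
    df["se"] = se
    df["n_eff"] = 1000.0
    df["missing_components"] = ""
    df["adjusted"] = False
    return df


@pytest.fixture(scope="module")
def flat_world():
    """No random effects, no temporal wiggle: truth is exactly logit-linear
    in SDI (suite b)."""
    params = GeneratorParams(
        re_sd={"location": 0.0, "region": 0.0, "super_region": 0.0},
        wiggle_amplitude=0.0,
    )
    return generate_world(
        n_super_regions=2, n_regions_per_super=2, n_locations_per_region=2,
        years=range(2000, 2015), cadence=5, n_per_cell=200, params=params, seed=21,
    )


@pytest.fixture(scope="module")
def config_small():
    return StGprConfig(n_draws=100)


def test_suite_selection_prefers_generating_suite(flat_world, config_small):
    est = _estimates_from_surface(flat_world, years=[2000, 2005, 2010])
    model = STGPR(est, flat_world.covariates, flat_world.hierarchy, config_small)
    fit, _ = model.fit_stage1()
    assert fit.suite == "b"
    assert fit.rmse_by_suite["b"] < fit.rmse_by_suite["a"]


def test_identical_suites_tie_break_to_a(flat_world):
    cfg = StGprConfig(n_draws=100, suite_a=("sdi",), suite_b=("sdi",))
    est = _estimates_from_surface(flat_world, years=[2000, 2010])
    model = STGPR(est, flat_world.covariates, flat_world.hierarchy, cfg)
    fit, _ = model.fit_stage1()
    assert fit.rmse_by_suite["a"] == fit.rmse_by_suite["b"]
    assert fit.suite == "a"


def test_rmse_matches_independent_recomputation(flat_world, config_small):
    est = _estimates_from_surface(flat_world, years=[2000, 2005, 2010])
    model = STGPR(est, flat_world.covariates, flat_world.hierarchy, config_small)
    fit, prior = model.fit_stage1()
    # recompute in-sample RMSE on the logit scale from the prior itself
    prior_map = pd.Series(prior, index=pd.MultiIndex.from_frame(model.cells))
    key = pd.MultiIndex.from_frame(est[["location_id", "year", "age_group"]])
    pred = prior_map.reindex(key).to_numpy()
    y = logit(np.clip(est["mean"].to_numpy(), 0.001, 0.999))
    assert fit.rmse == pytest.approx(float(np.sqrt(np.mean((y - pred) ** 2))), rel=1e-10)


def test_coefficient_recovery_without_random_effects(flat_world, config_small):
    est = _estimates_from_surface(flat_world, se=0.005)
    model = STGPR(est, flat_world.covariates, flat_world.hierarchy, config_small)
    fit, _ = model.fit_stage1(suite="b")
    truth = flat_world.params.coef["cpr"]
    # the intercept absorbs the marital offset and the baseline age band
    expected_intercept = (
        truth["intercept"]
        + flat_world.params.marital_offsets["cpr"]["partnered"]
        + flat_world.params.age_intercepts["cpr"][0]
    )
    assert fit.params["sdi"] == pytest.approx(truth["sdi"], abs=3 * fit.bse["sdi"] + 1e-6)
    assert fit.params["intercept"] == pytest.approx(
        expected_intercept, abs=3 * fit.bse["intercept"] + 1e-3
    )
    # age intercept contrasts are recovered too
    ai = flat_world.params.age_intercepts["cpr"]
    assert fit.params["age[30-34]"] == pytest.approx(ai[3] - ai[0], abs=0.01)


def test_data_free_location_inherits_region_effects(small_world, config_small):
    est = extract_estimates(small_world.microdata(), quantities=["cpr"])
    est = est[est["marital"] == "partnered"]
    held_out = "L000"
    model = STGPR(
        est[est["location_id"] != held_out],
        small_world.covariates,
        small_world.hierarchy,
        config_small,
    )
    fit, prior = model.fit_stage1()
    assert held_out not in fit.re_location
    # structural check: prior at the held-out location equals the pure
    # fixed-effect prediction plus its region and super-region intercepts
    # (location effect exactly zero)
    from fpstgpr.stgpr import _design_matrix

    cells = model.cells
    mask = (cells["location_id"] == held_out).to_numpy()
    attached = model._attach(cells[mask].reset_index(drop=True))
    suite_cols = config_small.suite_a if fit.suite == "a" else config_small.suite_b
    X = _design_matrix(attached, suite_cols, ())[fit.columns]
    fe = X.to_numpy() @ fit.params.to_numpy()
    region = small_world.hierarchy.region_of(held_out)
    sr = small_world.hierarchy.super_region_of(held_out)
    expected = fe + fit.re_region.get(region, 0.0) + fit.re_super_region.get(sr, 0.0)
    assert np.allclose(prior[mask], expected, atol=1e-10)


def test_intercept_only_constant_data(flat_world):
    cfg = StGprConfig(n_draws=100, suite_a=(), suite_b=(), stage2=False, stage3=False)
    est = _estimates_from_surface(flat_world, years=[2000, 2005, 2010])
    est["mean"] = 0.3
    model = STGPR(est, flat_world.covariates, flat_world.hierarchy, cfg)
    res = model.fit(seed=1)
    assert np.allclose(res.prior, 0.3, atol=1e-9)
    assert np.allclose(res.posterior_mean, 0.3, atol=1e-9)


def test_disabling_stages_returns_stage1_prior(flat_world):
    cfg = StGprConfig(n_draws=100, stage2=False, stage3=False)
    est = _estimates_from_surface(flat_world, years=[2000, 2005, 2010])
    model = STGPR(est, flat_world.covariates, flat_world.hierarchy, cfg)
    res = model.fit(seed=1)
    assert np.array_equal(res.trend_t, res.prior_t)
    assert np.array_equal(res.posterior_mean_t, res.prior_t)
    assert np.allclose(res.draws, expit(res.prior_t)[:, None])


def test_constant_residual_shifts_trend_by_constant(flat_world, config_small):
    est = _estimates_from_surface(flat_world, years=[2000, 2005, 2010])
    model = STGPR(est, flat_world.covariates, flat_world.hierarchy, config_small)
    fit, prior = model.fit_stage1()
    from fpstgpr.stgpr import _transform_estimates

    data = _transform_estimates(model._attach(model.estimates), config_small.clip_bounds)
    prior_map = pd.Series(prior, index=pd.MultiIndex.from_frame(model.cells))
    key = pd.MultiIndex.from_frame(data[["location_id", "year", "age_group"]])
    c = 0.37
    data["y"] = prior_map.reindex(key).to_numpy() + c
    smoothed = model.smooth_residuals(prior, data)
    assert np.allclose(smoothed, c, atol=1e-9)


def test_tiny_time_window_passes_through_observed_residual(flat_world):
    """As the time kernel collapses, the trend at an observed year equals
    the prior plus that year's own residual."""
    cfg = StGprConfig(n_draws=100, lambda_t=1e-6, zeta=0.999, omega=50.0)
    est = _estimates_from_surface(flat_world, years=[2005])
    model = STGPR(est, flat_world.covariates, flat_world.hierarchy, cfg)
    fit, prior = model.fit_stage1(suite="b")
    from fpstgpr.stgpr import _transform_estimates

    # smooth single-location data only
    data = _transform_estimates(model._attach(model.estimates), cfg.clip_bounds)
    data = data[data["location_id"] == "L000"].reset_index(drop=True)
    prior_map = pd.Series(prior, index=pd.MultiIndex.from_frame(model.cells))
    key = pd.MultiIndex.from_frame(data[["location_id", "year", "age_group"]])
    resid = data["y"].to_numpy() - prior_map.reindex(key).to_numpy()
    smoothed = model.smooth_residuals(prior, data)
    cells = model.cells
    for i, (_, obs) in enumerate(data.iterrows()):
        mask = (
            (cells["location_id"] == obs["location_id"])
            & (cells["year"] == obs["year"])
            & (cells["age_group"] == obs["age_group"])
        ).to_numpy()
        assert smoothed[mask][0] == pytest.approx(resid[i], abs=1e-9)


def test_three_point_smoother_matches_hand_normal_equations(flat_world):
    """Single location, three observed years, one age: the locally weighted
    linear fit at a target year must match explicit normal equations."""
    cfg = StGprConfig(n_draws=100, lambda_t=0.8, zeta=0.9, omega=1.0)
    est = _estimates_from_surface(flat_world, years=[2002, 2007, 2012])
    model = STGPR(est, flat_world.covariates, flat_world.hierarchy, cfg)
    fit, prior = model.fit_stage1(suite="b")
    from fpstgpr.stgpr import _transform_estimates

    data = _transform_estimates(model._attach(model.estimates), cfg.clip_bounds)
    data = data[
        (data["location_id"] == "L000") & (data["age_group"] == "25-29")
    ].reset_index(drop=True)
    prior_map = pd.Series(prior, index=pd.MultiIndex.from_frame(model.cells))
    key = pd.MultiIndex.from_frame(data[["location_id", "year", "age_group"]])
    resid = data["y"].to_numpy() - prior_map.reindex(key).to_numpy()
    smoothed = model.smooth_residuals(prior, data)

    # hand computation at (L000, 2006, 25-29)
    years_obs = data["year"].to_numpy(dtype=float)
    t0 = 2006.0
    span = 14.0
    h = cfg.lambda_t * span
    wt = np.maximum(1 - (np.abs(years_obs - t0) / h) ** 3, 0.0) ** 3
    ws = cfg.zeta  # same location for all three
    wa = 1.0  # same age
    w = wt * ws * wa
    X = np.column_stack([np.ones(3), years_obs - t0])
    beta = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * resid))
    cells = model.cells
    mask = (
        (cells["location_id"] == "L000")
        & (cells["year"] == 2006)
        & (cells["age_group"] == "25-29")
    ).to_numpy()
    assert smoothed[mask][0] == pytest.approx(beta[0], abs=1e-10)


def _matern52(d, amp, rho):
    a = np.sqrt(5) * d / rho
    return amp**2 * (1 + a + a**2 / 3) * np.exp(-a)


def test_gp_posterior_matches_closed_form(flat_world):
    """Two observations, hand-set kernel: posterior mean must equal the
    closed-form k*^T (K + Sigma)^-1 y to 1e-8."""
    cfg = StGprConfig(
        n_draws=100, stage2=False, amplitude_floor=0.5, length_scale=10.0
    )
    est_full = _estimates_from_surface(flat_world, years=[2003, 2011])
    model = STGPR(est_full, flat_world.covariates, flat_world.hierarchy, cfg)
    res = model.fit(seed=5)

    data = est_full[
        (est_full["location_id"] == "L000") & (est_full["age_group"] == "25-29")
    ].copy()
    p = np.clip(data["mean"].to_numpy(), 0.001, 0.999)
    y = logit(p)
    se_t = np.maximum(data["se"].to_numpy(), 1e-6) / (p * (1 - p))
    cells = model.cells
    mask = (
        (cells["location_id"] == "L000") & (cells["age_group"] == "25-29")
    ).to_numpy()
    trend = res.trend_t[mask]
    years = np.sort(flat_world.covariates["year"].unique()).astype(float)
    ty = data["year"].to_numpy(dtype=float)
    # residuals vs the (stage-1) trend, amplitude floored at 0.5 by config
    resid_amp = y - pd.Series(trend, index=years).reindex(ty).to_numpy()
    amp = max(1.4826 * np.median(np.abs(resid_amp - np.median(resid_amp))), 0.5)
    K = _matern52(np.abs(ty[:, None] - ty[None, :]), amp, 10.0) + np.diag(se_t**2)
    k_star = _matern52(np.abs(years[:, None] - ty[None, :]), amp, 10.0)
    m_obs = pd.Series(trend, index=years).reindex(ty).to_numpy()
    expected = trend + k_star @ np.linalg.solve(K, y - m_obs)
    assert np.allclose(res.posterior_mean_t[mask], expected, atol=1e-8)


def test_gp_noise_limits(flat_world):
    base = _estimates_from_surface(flat_world, years=[2004])

    # enormous noise: posterior mean equals the trend everywhere
    noisy = base.copy()
    noisy["se"] = 0.45
    cfg = StGprConfig(n_draws=100, stage2=False)
    model = STGPR(noisy, flat_world.covariates, flat_world.hierarchy, cfg)
    res = model.fit(seed=2)
    assert np.allclose(res.posterior_mean_t, res.trend_t, atol=0.05)

    # vanishing noise: posterior passes through the observation
    sharp = base.copy()
    sharp["se"] = 1e-6
    model2 = STGPR(sharp, flat_world.covariates, flat_world.hierarchy, cfg)
    res2 = model2.fit(seed=2)
    cells = model2.cells
    at_obs = (
        (cells["location_id"] == "L000")
        & (cells["age_group"] == "25-29")
        & (cells["year"] == 2004)
    ).to_numpy()
    row = sharp[
        (sharp["location_id"] == "L000") & (sharp["age_group"] == "25-29")
    ].iloc[0]
    y_obs = logit(np.clip(row["mean"], 0.001, 0.999))
    assert res2.posterior_mean_t[at_obs][0] == pytest.approx(y_obs, abs=1e-6)


def test_data_following_improves_with_smaller_se(flat_world):
    """|posterior mean - observation| shrinks monotonically with the
    observation's standard error."""
    base = _estimates_from_surface(flat_world, years=[2004])
    # shift one observation off the prior so there is something to follow
    base = base.copy()
    target = (base["location_id"] == "L000") & (base["age_group"] == "25-29")
    base.loc[target, "mean"] = np.clip(base.loc[target, "mean"] + 0.15, 0.01, 0.99)
    cfg = StGprConfig(n_draws=100, stage2=False)
    gaps = []
    for se in (0.2, 0.05, 0.01):
        est = base.copy()
        est.loc[target, "se"] = se
        model = STGPR(est, flat_world.covariates, flat_world.hierarchy, cfg)
        res = model.fit(seed=2)
        cells = model.cells
        at_obs = (
            (cells["location_id"] == "L000")
            & (cells["age_group"] == "25-29")
            & (cells["year"] == 2004)
        ).to_numpy()
        y_obs = logit(np.clip(est.loc[target, "mean"].iloc[0], 0.001, 0.999))
        gaps.append(abs(res.posterior_mean_t[at_obs][0] - y_obs))
    assert gaps[0] > gaps[1] > gaps[2]


def test_draw_order_invariance(flat_world, config_small):
    est = _estimates_from_surface(flat_world, years=[2000, 2005, 2010])
    model1 = STGPR(est, flat_world.covariates, flat_world.hierarchy, config_small)
    shuffled = est.sample(frac=1.0, random_state=0).reset_index(drop=True)
    model2 = STGPR(shuffled, flat_world.covariates, flat_world.hierarchy, config_small)
    r1 = model1.fit(seed=9)
    r2 = model2.fit(seed=9)
    assert np.allclose(r1.draws, r2.draws)


def test_draws_bounded_and_summary_ordered(flat_world, config_small):
    est = _estimates_from_surface(flat_world, years=[2000, 2005, 2010])
    model = STGPR(est, flat_world.covariates, flat_world.hierarchy, config_small)
    res = model.fit(seed=9)
    assert ((res.draws >= 0) & (res.draws <= 1)).all()
    s = res.summarize()
    assert (s["lower"] <= s["mean"] + 1e-12).all()
    assert (s["mean"] <= s["upper"] + 1e-12).all()
    assert "covariate suite" in res.summary()


def test_summarize_draws_rules():
    const = np.full((1, 100), 0.42)
    s = summarize_draws(const).iloc[0]
    for k in ("mean", "lower", "upper"):
        assert s[k] == pytest.approx(0.42, abs=1e-12)

    draws = (np.arange(1, 1001) / 1000.0)[None, :]
    s2 = summarize_draws(draws).iloc[0]
    # linear-interpolation quantile: position (n-1)q of the sorted draws
    n = 1000
    for q, key in ((0.025, "lower"), (0.975, "upper")):
        pos = (n - 1) * q
        lo, hi = int(np.floor(pos)), int(np.ceil(pos))
        frac = pos - lo
        expected = draws[0, lo] * (1 - frac) + draws[0, hi] * frac
        assert s2[key] == pytest.approx(expected, abs=1e-12)
    assert s2["mean"] == pytest.approx(draws.mean(), abs=1e-12)


def test_singular_design_names_columns(flat_world, config_small):
    cov = flat_world.covariates.copy()
    cov["dup"] = cov["sdi"]
    cfg = StGprConfig(n_draws=100, suite_b=("sdi", "dup"))
    est = _estimates_from_surface(flat_world, years=[2000, 2010])
    model = STGPR(est, cov, flat_world.hierarchy, cfg)
    with pytest.raises(ValueError, match="collinear"):
        model.fit_stage1(suite="b")


def test_too_few_estimates_fail(flat_world, config_small):
    est = _estimates_from_surface(flat_world, years=[2000]).head(4)
    model = STGPR(est, flat_world.covariates, flat_world.hierarchy, config_small)
    with pytest.raises(ValueError, match="too few"):
        model.fit_stage1(suite="b")


def test_config_validation():
    with pytest.raises(ValueError):
        StGprConfig(n_draws=50)
    with pytest.raises(ValueError):
        StGprConfig(zeta=1.5)
    with pytest.raises(ValueError):
        StGprConfig(lambda_t=0.0)
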