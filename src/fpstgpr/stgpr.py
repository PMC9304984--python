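"""Three-stage spatiotemporal Gaussian process regression.

Stage 1 is a weighted linear model of the logit-transformed survey
estimates on a development-covariate suite with age-group intercepts and
nested empirical-Bayes random intercepts on geography (location within
region within super-region); the suite (female education + log
lag-distributed income, or SDI) is chosen by minimum in-sample RMSE.
Stage 2 smooths the stage-1 residuals with a locally weighted polynomial
across time, age, and the location hierarchy, giving a non-linear trend
that follows the data in each location. Stage 3 uses that trend as the
mean function of an exact Gaussian process over years per
location-age series, with observation-specific noise variances, and draws
from the posterior; draws are inverse-logit transformed back to the
proportion scale.

The model is exposed statsmodels-style: build an :class:`STGPR` from the
estimates table, call :meth:`STGPR.fit`, and read draws and summaries off
the returned :class:`STGPRResults`.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .constants import AGE_GROUPS, AGE_INDEX
from .hierarchy import LocationHierarchy
from .synthetic import SUITE_A_COVARIATES, SUITE_B_COVARIATES

__all__ = [
    "StGprConfig",
    "Stage1Fit",
    "STGPR",
    "STGPRResults",
    "logit",
    "expit",
    "summarize_draws",
]


def logit(p):
    return np.log(p / (1.0 - p))


def expit(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class StGprConfig:
    """Hyperparameters of the three stages.

    lambda_t is the tricube time half-window as a fraction of the year
    span (smaller = more local); omega the exponential decay per age-band
    step; zeta the weight retained by the location's own data relative to
    its region and super-region. The Matern-5/2 kernel amplitude is set
    per series from the median absolute deviation of the residuals against
    the stage-1 prior (``amplitude_from``), floored at ``amplitude_floor``
    on the logit scale; both were chosen by interval-coverage calibration
    on synthetic data (see docs/methods.md).
    """

    n_draws: int = 1000
    transform: str = "logit"
    suite_a: tuple = SUITE_A_COVARIATES
    suite_b: tuple = SUITE_B_COVARIATES
    extra_covariates: tuple = ()
    lambda_t: float = 0.5
    zeta: float = 0.9
    omega: float = 1.0
    loess_degree: int = 1
    kernel: str = "matern52"
    length_scale: float = 10.0
    amplitude_floor: float = 0.3
    amplitude_from: str = "stage1"  # residuals vs the stage-1 prior or stage-2 trend
    clip_bounds: tuple = (0.001, 0.999)
    stage2: bool = True
    stage3: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_draws < 100:
            raise ValueError("n_draws must be >= 100")
        if not self.lambda_t > 0:
            raise ValueError("lambda_t must be positive")
        if not 0.0 < self.zeta < 1.0:
            raise ValueError("zeta must lie in (0,1)")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if self.loess_degree not in (0, 1):
            raise ValueError("loess_degree must be 0 or 1")


@dataclass
class Stage1Fit:
    """Fixed effects, age intercepts and nested random intercepts."""

    suite: str
    columns: list
    params: pd.Series
    bse: pd.Series
    re_location: dict
    re_region: dict
    re_super_region: dict
    sigma2_e: float
    rmse_by_suite: dict

    @property
    def rmse(self) -> float:
        return self.rmse_by_suite[self.suite]


def _transform_estimates(est: pd.DataFrame, clip_bounds) -> pd.DataFrame:
    lo, hi = clip_bounds
    out = est.copy()
    p = np.clip(out["mean"].to_numpy(dtype=float), lo, hi)
    se = np.maximum(out["se"].to_numpy(dtype=float), 1e-6)
    out["y"] = logit(p)
    out["se_t"] = se / (p * (1.0 - p))  # delta method
    out["w"] = 1.0 / out["se_t"] ** 2
    return out


def _design_matrix(df: pd.DataFrame, suite_covs, extra_covs) -> pd.DataFrame:
    X = pd.DataFrame(index=df.index)
    X["intercept"] = 1.0
    for age in AGE_GROUPS[1:]:
        X[f"age[{age}]"] = (df["age_group"] == age).astype(float)
    for c in list(suite_covs) + list(extra_covs):
        X[c] = df[c].to_numpy(dtype=float)
    return X


def _check_rank(X: pd.DataFrame):
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify offending columns by greedy removal
        bad = []
        cols = list(X.columns)
        M = X.to_numpy()
        base_rank = rank
        for j, c in enumerate(cols):
            sub = np.delete(M, j, axis=1)
            if np.linalg.matrix_rank(sub) == base_rank:
                bad.append(c)
        raise ValueError(f"singular design matrix; collinear columns: {bad}")


def _eb_random_effects(resid: np.ndarray, groups: np.ndarray, sigma2_e: float) -> dict:
    """Moment-based empirical-Bayes shrunken group intercepts."""
    df = pd.DataFrame({"r": resid, "g": groups})
    stats = df.groupby("g")["r"].agg(["mean", "count"])
    if len(stats) < 2:
        return {g: 0.0 for g in stats.index}
    between = float(np.var(stats["mean"].to_numpy(), ddof=1))
    noise = float(np.mean(sigma2_e / stats["count"].to_numpy()))
    sigma2_u = max(between - noise, 0.0)
    if sigma2_u == 0.0:
        return {g: 0.0 for g in stats.index}
    shrink = sigma2_u / (sigma2_u + sigma2_e / stats["count"].to_numpy())
    return dict(zip(stats.index, stats["mean"].to_numpy() * shrink))


class STGPR:
    """Three-stage model for one quantity in one marital stratum.

    Parameters
    ----------
    estimates : DataFrame
        Survey estimates (one quantity, one marital stratum) with columns
        ``location_id, year, age_group, mean, se``.
    covariates : DataFrame
        Location-year covariate table covering every prediction cell.
    hierarchy : LocationHierarchy
    config : StGprConfig
    extra_covariates : DataFrame, optional
        Location-year-age values of previously modelled indicators (e.g.
        the CPR posterior mean entering the unmet-need model), entered on
        the logit scale. Columns: the cell key plus one column per name in
        ``config.extra_covariates``.
    """

    def __init__(
        self,
        estimates: pd.DataFrame,
        covariates: pd.DataFrame,
        hierarchy: LocationHierarchy,
        config: StGprConfig | None = None,
        extra_covariates: pd.DataFrame | None = None,
    ):
        self.config = config or StGprConfig()
        self.hierarchy = hierarchy
        self.covariates = covariates
        self.extra = extra_covariates
        if self.config.extra_covariates and extra_covariates is None:
            raise ValueError("config names extra covariates but none were supplied")
        self.estimates = estimates.reset_index(drop=True)
        self.years = np.sort(covariates["year"].unique())
        self.locations = hierarchy.locations
        self.cells = pd.DataFrame(
            [
                (l, int(y), a)
                for l in self.locations
                for y in self.years
                for a in AGE_GROUPS
            ],
            columns=["location_id", "year", "age_group"],
        )
        self._attach = self._make_attach()

    # ------------------------------------------------------------------ #
    def _make_attach(self):
        """Return a function merging covariates (and extras) onto a cell frame."""
        cov = self.covariates
        extra = self.extra

        def attach(df: pd.DataFrame) -> pd.DataFrame:
            out = df.merge(cov, on=["location_id", "year"], how="left", validate="m:1")
            for c in ("sdi", "edu_female", "log_ldi"):
                if c in out and out[c].isna().any():
                    bad = out.loc[out[c].isna(), ["location_id", "year"]].iloc[0]
                    raise ValueError(
                        f"covariates missing for location-year "
                        f"({bad['location_id']}, {bad['year']})"
                    )
            if extra is not None:
                out = out.merge(
                    extra, on=["location_id", "year", "age_group"], how="left", validate="m:1"
                )
            return out

        return attach

    def _suite_columns(self, suite: str):
        return self.config.suite_a if suite == "a" else self.config.suite_b

    def _fit_wls(self, data: pd.DataFrame, suite: str):
        X = _design_matrix(data, self._suite_columns(suite), self.config.extra_covariates)
        if len(data) <= X.shape[1]:
            raise ValueError(
                f"too few estimates ({len(data)}) for {X.shape[1]} fixed effects"
            )
        _check_rank(X)
        res = sm.WLS(data["y"].to_numpy(), X, weights=data["w"].to_numpy()).fit()
        return res, X

    def fit_stage1(self, suite: str | None = None) -> tuple[Stage1Fit, np.ndarray]:
        """Fit the mixed-effects prior; returns the fit and the prior over
        all cells (transformed scale). With ``suite=None`` both covariate
        suites are fitted and the minimum-RMSE one kept (tie -> suite a)."""
        data = self._attach(self.estimates)
        data = _transform_estimates(data, self.config.clip_bounds)
        hier = self.hierarchy.table.set_index("location_id")
        reg = data["location_id"].map(hier["region_id"]).to_numpy()
        sreg = data["location_id"].map(hier["super_region_id"]).to_numpy()

        candidates = ("a", "b") if suite is None else (suite,)
        fits = {}
        rmses = {}
        for s in candidates:
            res, X = self._fit_wls(data, s)
            resid = data["y"].to_numpy() - res.fittedvalues
            sigma2_e = float(np.average(resid**2))
            u_sr = _eb_random_effects(resid, sreg, sigma2_e)
            r1 = resid - np.array([u_sr[g] for g in sreg])
            u_r = _eb_random_effects(r1, reg, sigma2_e)
            r2 = r1 - np.array([u_r[g] for g in reg])
            u_l = _eb_random_effects(r2, data["location_id"].to_numpy(), sigma2_e)
            pred = (
                res.fittedvalues
                + np.array([u_sr[g] for g in sreg])
                + np.array([u_r[g] for g in reg])
                + np.array([u_l.get(g, 0.0) for g in data["location_id"]])
            )
            rmses[s] = float(np.sqrt(np.mean((data["y"].to_numpy() - pred) ** 2)))
            fits[s] = (res, X, u_l, u_r, u_sr, sigma2_e)
        chosen = min(candidates, key=lambda s: (rmses[s], s))  # tie -> "a"
        res, X, u_l, u_r, u_sr, sigma2_e = fits[chosen]
        fit = Stage1Fit(
            suite=chosen,
            columns=list(X.columns),
            params=pd.Series(res.params, index=X.columns),
            bse=pd.Series(res.bse, index=X.columns),
            re_location=u_l,
            re_region=u_r,
            re_super_region=u_sr,
            sigma2_e=sigma2_e,
            rmse_by_suite=rmses,
        )
        return fit, self._predict_prior(fit)

    def _predict_prior(self, fit: Stage1Fit) -> np.ndarray:
        """Stage-1 prediction for every cell; unobserved locations take a
        zero location effect and inherit their region/super-region effects."""
        cells = self._attach(self.cells)
        X = _design_matrix(cells, self._suite_columns(fit.suite), self.config.extra_covariates)
        X = X[fit.columns]
        lp = X.to_numpy() @ fit.params.to_numpy()
        hier = self.hierarchy.table.set_index("location_id")
        locs = cells["location_id"]
        lp = lp + locs.map(lambda l: fit.re_location.get(l, 0.0)).to_numpy()
        lp = lp + locs.map(hier["region_id"]).map(
            lambda g: fit.re_region.get(g, 0.0)
        ).to_numpy()
        lp = lp + locs.map(hier["super_region_id"]).map(
            lambda g: fit.re_super_region.get(g, 0.0)
        ).to_numpy()
        return lp

    # ------------------------------------------------------------------ #
    def smooth_residuals(self, prior: np.ndarray, data_t: pd.DataFrame) -> np.ndarray:
        """Stage 2: locally weighted polynomial smoothing of residuals.

        Weights are the product of a tricube kernel in years (half-window
        ``lambda_t`` x year span), exponential decay in age-band distance
        (rate ``omega``), and a hierarchy kernel: observations from the
        same location carry weight proportional to zeta, same region
        (1-zeta)*zeta, same super-region (1-zeta)^2*zeta, otherwise
        (1-zeta)^3. Returns the smoothed residual per cell (transformed
        scale); the stage-2 trend is ``prior + smoothed``.
        """
        cfg = self.config
        prior_at = self._prior_lookup(prior)
        obs = data_t.copy()
        obs["resid"] = obs["y"].to_numpy() - prior_at(obs)
        if obs.empty:
            return np.zeros(len(self.cells))

        hier = self.hierarchy.table.set_index("location_id")
        o_year = obs["year"].to_numpy(dtype=float)
        o_age = obs["age_group"].map(AGE_INDEX).to_numpy(dtype=float)
        o_loc = obs["location_id"].to_numpy()
        o_reg = obs["location_id"].map(hier["region_id"]).to_numpy()
        o_sr = obs["location_id"].map(hier["super_region_id"]).to_numpy()
        r = obs["resid"].to_numpy()

        span = max(float(self.years.max() - self.years.min()), 1.0)
        h = cfg.lambda_t * span
        tgrid = self.years.astype(float)
        u = np.abs(tgrid[:, None] - o_year[None, :]) / h
        Wt = np.where(u < 1.0, (1.0 - u**3) ** 3, 0.0)  # (n_year, n_obs)

        z = cfg.zeta
        smoothed = np.zeros((len(self.locations), len(self.years), len(AGE_GROUPS)))
        for li, loc in enumerate(self.locations):
            same_loc = o_loc == loc
            same_reg = (o_reg == hier.loc[loc, "region_id"]) & ~same_loc
            same_sr = (
                (o_sr == hier.loc[loc, "super_region_id"]) & ~same_loc & ~same_reg
            )
            ws = np.where(
                same_loc, z,
                np.where(same_reg, (1 - z) * z,
                         np.where(same_sr, (1 - z) ** 2 * z, (1 - z) ** 3)),
            )
            for ai in range(len(AGE_GROUPS)):
                wa = np.exp(-cfg.omega * np.abs(ai - o_age))
                base = ws * wa
                M = Wt * base[None, :]  # (n_year, n_obs)
                S0 = M.sum(axis=1)
                T0 = M @ r
                if cfg.loess_degree == 0:
                    est = np.where(S0 > 0, T0 / np.maximum(S0, 1e-300), 0.0)
                else:
                    My = M @ o_year
                    My2 = M @ (o_year**2)
                    Tr = M @ (o_year * r)
                    S1 = My - tgrid * S0
                    S2 = My2 - 2 * tgrid * My + tgrid**2 * S0
                    T1 = Tr - tgrid * T0
                    den = S0 * S2 - S1**2
                    with np.errstate(divide="ignore", invalid="ignore"):
                        beta0 = (S2 * T0 - S1 * T1) / den
                        fallback = np.where(S0 > 0, T0 / np.maximum(S0, 1e-300), 0.0)
                    # den/(S0*S2) in [0,1] measures spread of observed years;
                    # fall back to the weighted mean when effectively single-year
                    well_posed = den > 1e-8 * np.maximum(S0 * S2, 1e-300)
                    est = np.where(well_posed & np.isfinite(beta0), beta0, fallback)
                smoothed[li, :, ai] = est
        # flatten in the cells order (location, year, age)
        return smoothed.reshape(-1)

    def _prior_lookup(self, prior: np.ndarray):
        idx = pd.MultiIndex.from_frame(self.cells)
        series = pd.Series(prior, index=idx)

        def lookup(df: pd.DataFrame) -> np.ndarray:
            key = pd.MultiIndex.from_frame(df[["location_id", "year", "age_group"]])
            return series.reindex(key).to_numpy()

        return lookup

    # ------------------------------------------------------------------ #
    def _kernel(self, d: np.ndarray, amplitude: float) -> np.ndarray:
        rho = self.config.length_scale
        a = np.sqrt(5.0) * d / rho
        return amplitude**2 * (1.0 + a + a**2 / 3.0) * np.exp(-a)

    def _series_seed(self, location_id: str, age_group: str, seed: int) -> np.random.Generator:
        name = f"{location_id}|{age_group}"
        digest = int(hashlib.sha256(name.encode()).hexdigest()[:15], 16)
        return np.random.default_rng(np.random.SeedSequence([seed, digest]))

    def fit_gpr(
        self, trend: np.ndarray, data_t: pd.DataFrame, seed: int, prior: np.ndarray | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Stage 3: exact GP posterior per location-age series over years.

        Returns (posterior mean, draws) on the transformed scale, draws of
        shape (n_cells, n_draws). Each series gets a named substream of
        ``seed`` so results do not depend on evaluation order. The kernel
        amplitude is set per series from the median absolute deviation of
        the residuals against the stage-1 prior (default) or the stage-2
        trend; the prior-based rule keeps the model-uncertainty scale of
        the data around the linear prior rather than the already
        data-following trend.
        """
        cfg = self.config
        n_y = len(self.years)
        tgrid = self.years.astype(float)
        trend3 = trend.reshape(len(self.locations), n_y, len(AGE_GROUPS))
        mean3 = np.empty_like(trend3)
        draws = np.empty((len(self.locations), n_y, len(AGE_GROUPS), cfg.n_draws))
        obs_by = {
            k: g for k, g in data_t.groupby(["location_id", "age_group"], sort=False, observed=True)
        }
        amp_ref = prior if (cfg.amplitude_from == "stage1" and prior is not None) else trend
        amp_lookup = self._prior_lookup(amp_ref)
        trend_lookup = self._prior_lookup(trend)
        D = np.abs(tgrid[:, None] - tgrid[None, :])
        for li, loc in enumerate(self.locations):
            for ai, age in enumerate(AGE_GROUPS):
                m = trend3[li, :, ai]
                g = obs_by.get((loc, age))
                rng = self._series_seed(loc, age, seed)
                if g is None or len(g) == 0:
                    amp = cfg.amplitude_floor
                    K = self._kernel(D, amp)
                    mu, C = m, K
                else:
                    z = g["y"].to_numpy()
                    v = g["se_t"].to_numpy() ** 2
                    ty = g["year"].to_numpy(dtype=float)
                    resid_amp = z - amp_lookup(g)
                    m_obs = trend_lookup(g)
                    resid = z - m_obs
                    if len(resid_amp) >= 2:
                        mad = np.median(np.abs(resid_amp - np.median(resid_amp)))
                        amp = max(1.4826 * mad, cfg.amplitude_floor)
                    else:
                        amp = cfg.amplitude_floor
                    K_oo = self._kernel(np.abs(ty[:, None] - ty[None, :]), amp) + np.diag(v)
                    K_go = self._kernel(np.abs(tgrid[:, None] - ty[None, :]), amp)
                    K_gg = self._kernel(D, amp)
                    sol = np.linalg.solve(K_oo, np.column_stack([resid[:, None], K_go.T]))
                    mu = m + K_go @ sol[:, 0]
                    C = K_gg - K_go @ sol[:, 1:]
                L = _chol_with_jitter(C, cell=f"{loc}/{age}")
                mean3[li, :, ai] = mu
                eps = rng.standard_normal((n_y, cfg.n_draws))
                draws[li, :, ai, :] = mu[:, None] + L @ eps
        return mean3.reshape(-1), draws.reshape(-1, cfg.n_draws)

    # ------------------------------------------------------------------ #
    def fit(self, seed: int | None = None, suite: str | None = None) -> "STGPRResults":
        if seed is None:
            seed = self.config.seed
        stage1, prior = self.fit_stage1(suite=suite)
        data_t = self._attach(self.estimates)
        data_t = _transform_estimates(data_t, self.config.clip_bounds)
        if self.config.stage2:
            trend = prior + self.smooth_residuals(prior, data_t)
        else:
            trend = prior.copy()
        if self.config.stage3:
            post_mean_t, draws_t = self.fit_gpr(trend, data_t, seed, prior=prior)
        else:
            post_mean_t = trend.copy()
            draws_t = np.repeat(trend[:, None], self.config.n_draws, axis=1)
        return STGPRResults(
            model=self,
            stage1=stage1,
            prior_t=prior,
            trend_t=trend,
            posterior_mean_t=post_mean_t,
            draws=expit(draws_t),
            seed=seed,
        )


def _chol_with_jitter(C: np.ndarray, cell: str) -> np.ndarray:
    base = max(np.trace(C) / len(C), 1e-12)
    for jitter in (0.0, 1e-10, 1e-8, 1e-6, 1e-4):
        try:
            return np.linalg.cholesky(C + jitter * base * np.eye(len(C)))
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError(
        f"posterior covariance not positive definite after jitter escalation at cell {cell}"
    )


def summarize_draws(draws: np.ndarray) -> pd.DataFrame:
    """Point estimate and 95% uncertainty interval per cell.

    The point estimate is the mean across draws; the interval spans the
    0.025 and 0.975 quantiles (linear-interpolation quantile rule, i.e.
    the (n-1)*q+1-th order statistic interpolated).
    """
    draws = np.atleast_2d(draws)
    return pd.DataFrame(
        {
            "mean": draws.mean(axis=1),
            "lower": np.quantile(draws, 0.025, axis=1),
            "upper": np.quantile(draws, 0.975, axis=1),
        }
    )


@dataclass
class STGPRResults:
    """Posterior draws and stage diagnostics for one fitted model."""

    model: STGPR
    stage1: Stage1Fit
    prior_t: np.ndarray
    trend_t: np.ndarray
    posterior_mean_t: np.ndarray
    draws: np.ndarray  # (n_cells, n_draws), proportion scale
    seed: int

    @property
    def cells(self) -> pd.DataFrame:
        return self.model.cells

    @property
    def prior(self) -> np.ndarray:
        return expit(self.prior_t)

    @property
    def trend(self) -> np.ndarray:
        return expit(self.trend_t)

    @property
    def posterior_mean(self) -> np.ndarray:
        return self.draws.mean(axis=1)

    def summarize(self) -> pd.DataFrame:
        out = self.cells.copy()
        s = summarize_draws(self.draws)
        out[["mean", "lower", "upper"]] = s[["mean", "lower", "upper"]].to_numpy()
        return out

    def draws_frame(self) -> pd.DataFrame:
        out = self.cells.copy()
        cols = pd.DataFrame(
            self.draws, columns=[f"draw_{i}" for i in range(self.draws.shape[1])]
        )
        return pd.concat([out, cols], axis=1)

    def summary(self) -> str:
        lines = [
            "Three-stage spatiotemporal GP regression",
            f"  covariate suite: {self.stage1.suite} "
            f"(RMSE {', '.join(f'{k}={v:.4f}' for k, v in self.stage1.rmse_by_suite.items())})",
            f"  cells: {len(self.cells)}  draws: {self.draws.shape[1]}  seed: {self.seed}",
            "  fixed effects (logit scale):",
        ]
        for name, val in self.stage1.params.items():
            lines.append(f"    {name:24s} {val:+.4f} (se {self.stage1.bse[name]:.4f})")
        lines.append(
            f"  random-effect groups: {len(self.stage1.re_super_region)} super-regions, "
            f"{len(self.stage1.re_region)} regions, {len(self.stage1.re_location)} locations"
        )
        cfg = self.model.config
        lines.append(
            f"  smoothing: lambda_t={cfg.lambda_t}, omega={cfg.omega}, zeta={cfg.zeta}, "
            f"degree={cfg.loess_degree}; kernel: {cfg.kernel}, length-scale {cfg.length_scale}"
        )
        return "\n".join(lines)
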