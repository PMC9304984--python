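"""Trimmed penalized-spline meta-regression of an indicator on SDI.

Expected-value curves of mCPR or demand satisfied as a function of the
Socio-demographic Index, per age group: a weighted (1/se^2) cubic B-spline
regression with a second-difference roughness penalty, made robust by
least-trimmed squares — the gamma fraction of observations with the
largest weighted absolute residuals is excluded and the fit iterated to a
fixed inlier set. Interior knots default to the SDI development-category
boundaries. With gamma = 0 the method reduces exactly to ordinary weighted
penalized-spline regression.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

logger = logging.getLogger(__name__)

DEFAULT_KNOTS = (45.5, 60.8, 69.0, 80.5)


def _basis(x: np.ndarray, knots, degree: int) -> np.ndarray:
    t = np.r_[[0.0] * (degree + 1), list(knots), [100.0] * (degree + 1)]
    x = np.clip(np.asarray(x, dtype=float), 0.0, 100.0 - 1e-9)
    return BSpline.design_matrix(x, t, degree).toarray()


def _second_diff_penalty(n_coef: int) -> np.ndarray:
    D = np.diff(np.eye(n_coef), n=2, axis=0)
    return D.T @ D


def _isotonic(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators projection onto non-decreasing sequences."""
    y = y.astype(float).copy()
    w = np.ones_like(y)
    i = 0
    vals, wts, idx = [], [], []
    for v, ww in zip(y, w):
        vals.append(v)
        wts.append(ww)
        idx.append(1)
        while len(vals) > 1 and vals[-2] > vals[-1]:
            v2, w2, n2 = vals.pop(), wts.pop(), idx.pop()
            v1, w1, n1 = vals.pop(), wts.pop(), idx.pop()
            vals.append((v1 * w1 + v2 * w2) / (w1 + w2))
            wts.append(w1 + w2)
            idx.append(n1 + n2)
    return np.repeat(vals, idx)


@dataclass
class TrimmedSplineMetaRegression:
    """Least-trimmed weighted penalized-spline model of value ~ spline(SDI).

    Parameters
    ----------
    points : DataFrame
        Observations with columns ``sdi`` (0-100), ``value`` (proportion)
        and ``se`` (> 0); weights are 1/se^2.
    gamma : float
        Trimming fraction in [0, 0.5): the ceil(gamma*n) observations with
        the largest weighted absolute residuals are excluded.
    knots : tuple
        Interior knots of the cubic B-spline over [0, 100].
    penalty : float
        Second-difference roughness penalty on the spline coefficients.
    monotone : bool
        Project the fitted curve onto non-decreasing curves.
    """

    points: pd.DataFrame
    gamma: float = 0.1
    knots: tuple = DEFAULT_KNOTS
    degree: int = 3
    penalty: float = 1.0
    monotone: bool = False
    max_iter: int = 100

    def __post_init__(self):
        if not 0.0 <= self.gamma < 0.5:
            raise ValueError("gamma must lie in [0, 0.5)")
        missing = {"sdi", "value", "se"} - set(self.points.columns)
        if missing:
            raise ValueError(f"points missing columns: {sorted(missing)}")
        self.n_basis = len(self.knots) + self.degree + 1
        if len(self.points) <= self.n_basis:
            raise ValueError(
                f"need more than {self.n_basis} points to fit a {self.n_basis}-column basis"
            )
        if len(self.points) < 10 * self.n_basis:
            logger.warning(
                "only %d points for a basis of %d; the curve may be unstable",
                len(self.points), self.n_basis,
            )

    def _solve(self, B, w, y) -> np.ndarray:
        P = _second_diff_penalty(B.shape[1])
        A = B.T @ (w[:, None] * B) + self.penalty * P
        return np.linalg.solve(A, B.T @ (w * y))

    def fit(self) -> "MetaRegressionResults":
        x = self.points["sdi"].to_numpy(dtype=float)
        y = self.points["value"].to_numpy(dtype=float)
        se = self.points["se"].to_numpy(dtype=float)
        if np.any(se <= 0):
            raise ValueError("all standard errors must be positive")
        w = 1.0 / se**2
        B = _basis(x, self.knots, self.degree)
        n = len(y)
        n_trim = math.ceil(self.gamma * n)
        inlier = np.ones(n, dtype=bool)
        converged = True
        if n_trim == 0:
            coef = self._solve(B, w, y)
        else:
            converged = False
            for _ in range(self.max_iter):
                coef = self._solve(B[inlier], w[inlier], y[inlier])
                wresid = np.sqrt(w) * np.abs(y - B @ coef)
                new_inlier = np.ones(n, dtype=bool)
                new_inlier[np.argsort(wresid)[-n_trim:]] = False
                if np.array_equal(new_inlier, inlier):
                    converged = True
                    break
                inlier = new_inlier
            coef = self._solve(B[inlier], w[inlier], y[inlier])
            if not converged:
                logger.warning("trimming did not reach a fixed inlier set; last fit returned")
        return MetaRegressionResults(
            model=self, coefficients=coef, inlier=inlier, converged=converged
        )


@dataclass
class MetaRegressionResults:
    model: TrimmedSplineMetaRegression
    coefficients: np.ndarray
    inlier: np.ndarray
    converged: bool

    def predict(self, sdi_grid) -> np.ndarray:
        """Expected indicator on an SDI grid, clipped to [0,1]."""
        grid = np.asarray(sdi_grid, dtype=float)
        if np.any((grid < 0) | (grid > 100)):
            raise ValueError("SDI grid must lie within [0,100]")
        B = _basis(grid, self.model.knots, self.model.degree)
        curve = B @ self.coefficients
        if self.model.monotone:
            order = np.argsort(grid)
            iso = np.empty_like(curve)
            iso[order] = _isotonic(curve[order])
            curve = iso
        return np.clip(curve, 0.0, 1.0)

    @property
    def n_trimmed(self) -> int:
        return int((~self.inlier).sum())

    def summary(self) -> str:
        m = self.model
        return "\n".join(
            [
                "Trimmed penalized-spline meta-regression",
                f"  points: {len(m.points)}  trimmed: {self.n_trimmed} (gamma={m.gamma})",
                f"  knots: {m.knots}  degree: {m.degree}  penalty: {m.penalty}",
                f"  converged: {self.converged}",
            ]
        )


def fit_trimmed_spline(points: pd.DataFrame, gamma: float = 0.1, **kw) -> MetaRegressionResults:
    """Functional wrapper around :class:`TrimmedSplineMetaRegression`."""
    return TrimmedSplineMetaRegression(points, gamma=gamma, **kw).fit()


def predict_expected(fit: MetaRegressionResults, sdi_grid) -> np.ndarray:
    return fit.predict(sdi_grid)


def expected_curves(
    points_by_age: pd.DataFrame, sdi_grid, gamma: float = 0.1, **kw
) -> pd.DataFrame:
    """Fit one curve per age group; returns long (age_group, sdi, expected)."""
    rows = []
    for age, grp in points_by_age.groupby("age_group", observed=True):
        res = fit_trimmed_spline(grp, gamma=gamma, **kw)
        curve = res.predict(sdi_grid)
        rows.append(
            pd.DataFrame({"age_group": age, "sdi": sdi_grid, "expected": curve})
        )
    return pd.concat(rows, ignore_index=True)
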