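"""Aggregation across marital strata, ages and locations, plus reporting.

Everything operates on aligned draws: aggregates are convex combinations
per draw (population- or proportion-weighted means), changes over time are
within-draw differences, and user counts are prevalence x population
summed per draw. Derived indicators (mCPR, unmet need, demand satisfied)
must be recomputed from aggregated component draws, never aggregated
directly. Includes age standardization to the global 2019 age structure,
SDI development categories, and the FP2020 120-million-additional-users
accounting.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

FP2020_GOAL = 120_000_000.0
FP2020_RATE_TOLERANCE_PP = 0.2

SDI_CATEGORIES = (
    ("low", 0.0, 45.5),
    ("low-middle", 45.5, 60.8),
    ("middle", 60.8, 69.0),
    ("high-middle", 69.0, 80.5),
    ("high", 80.5, 100.0),
)


def weighted_mean_draws(values: np.ndarray, weights: np.ndarray, axis: int = 0) -> np.ndarray:
    """Convex combination of draw arrays along ``axis``; weights broadcast."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    total = weights.sum(axis=axis, keepdims=True)
    if np.any(total <= 0):
        raise ValueError("weights sum to zero")
    shape = [1] * values.ndim
    shape[axis] = values.shape[axis]
    if weights.ndim != values.ndim:
        weights = weights.reshape(shape)
        total = weights.sum(axis=axis, keepdims=True)
    return (values * weights / total).sum(axis=axis)


def aggregate_marital(
    partnered: np.ndarray, unpartnered: np.ndarray, partnered_proportion
) -> np.ndarray:
    """All-women draws: pi x partnered + (1 - pi) x unpartnered, per draw."""
    p = np.asarray(partnered, dtype=float)
    u = np.asarray(unpartnered, dtype=float)
    pi = np.asarray(partnered_proportion, dtype=float)
    if p.shape != u.shape:
        raise ValueError("misaligned partnered/unpartnered draw arrays")
    if np.any((pi < 0) | (pi > 1)):
        raise ValueError("partnered_proportion outside [0,1]")
    if pi.ndim == p.ndim - 1:
        pi = pi[..., None]
    return pi * p + (1.0 - pi) * u


def aggregate_age(draws_by_age: np.ndarray, population: np.ndarray) -> np.ndarray:
    """Population-weighted 15-49 aggregate; age groups on axis 0."""
    draws_by_age = np.asarray(draws_by_age, dtype=float)
    population = np.asarray(population, dtype=float)
    if draws_by_age.shape[0] != population.shape[0]:
        raise ValueError("missing age group: draws and population lengths differ")
    return weighted_mean_draws(draws_by_age, population, axis=0)


def age_standardize(draws_by_age: np.ndarray, age_weights: np.ndarray) -> np.ndarray:
    """Fixed-weight mean over age groups (global 2019 age structure)."""
    age_weights = np.asarray(age_weights, dtype=float)
    if not np.isclose(age_weights.sum(), 1.0):
        raise ValueError("age-standardization weights must sum to 1")
    return aggregate_age(draws_by_age, age_weights)


def aggregate_locations(draws_by_location: np.ndarray, population: np.ndarray) -> np.ndarray:
    """Population-weighted aggregate over locations (axis 0)."""
    return weighted_mean_draws(
        np.asarray(draws_by_location, dtype=float), np.asarray(population, dtype=float), axis=0
    )


def absolute_change(draws_end: np.ndarray, draws_start: np.ndarray) -> np.ndarray:
    """Within-draw difference in percentage points (end minus start).

    Sharing draw indices at both endpoints preserves the positive
    correlation of a location's draws over time, which is what keeps
    change intervals narrower than the endpoint intervals.
    """
    end = np.asarray(draws_end, dtype=float)
    start = np.asarray(draws_start, dtype=float)
    if end.shape != start.shape:
        raise ValueError("misaligned endpoint draws")
    return (end - start) * 100.0


def count_users(prevalence_draws: np.ndarray, population: np.ndarray) -> np.ndarray:
    """User-count draws: sum over cells of prevalence x population.

    ``prevalence_draws``: (n_cells, n_draws); ``population``: (n_cells,).
    """
    prev = np.asarray(prevalence_draws, dtype=float)
    pop = np.asarray(population, dtype=float)
    if prev.shape[0] != pop.shape[0]:
        raise ValueError("population missing for some cells")
    return (prev * pop[:, None]).sum(axis=0)


@dataclass
class Fp2020Account:
    """Modern-user accounting against the 120-million goal."""

    countries: list
    baseline_year: int
    end_year: int
    users: dict  # year -> draws of total modern users
    additional_users: np.ndarray
    goal: float
    shortfall: np.ndarray
    rate_check: pd.DataFrame


def fp2020_account(
    mcpr_draws: np.ndarray,
    population: np.ndarray,
    years,
    countries,
    goal: float = FP2020_GOAL,
    goal_schedule: pd.DataFrame | None = None,
    baseline_year: int = 2012,
    end_year: int = 2019,
    tolerance_pp: float = FP2020_RATE_TOLERANCE_PP,
) -> Fp2020Account:
    """FP2020 accounting over a country set.

    ``mcpr_draws``: (n_countries, n_years, n_draws) all-women modern
    prevalence; ``population``: (n_countries, n_years) women 15-49. Users
    per year are summed across countries per draw; additional users are
    the within-draw difference end minus baseline; the shortfall is
    goal minus additional users per draw. ``goal_schedule`` (optional)
    holds per-country target annual mCPR growth in percentage points
    (columns ``country``, ``target_pp_per_year``); observed annualized
    growth is compared against it within ``tolerance_pp``.
    """
    mcpr = np.asarray(mcpr_draws, dtype=float)
    pop = np.asarray(population, dtype=float)
    years = list(years)
    countries = list(countries)
    if mcpr.shape[:2] != pop.shape:
        raise ValueError("country missing population rows")
    for y in (baseline_year, end_year):
        if y not in years:
            raise ValueError(f"year {y} not covered")
    users = {
        y: count_users(mcpr[:, i, :], pop[:, i]) for i, y in enumerate(years)
    }
    additional = users[end_year] - users[baseline_year]
    shortfall = goal - additional
    i0, i1 = years.index(baseline_year), years.index(end_year)
    annual_pp = (
        (mcpr[:, i1, :].mean(axis=1) - mcpr[:, i0, :].mean(axis=1))
        / (end_year - baseline_year)
        * 100.0
    )
    rate = pd.DataFrame({"country": countries, "annual_mcpr_change_pp": annual_pp})
    if goal_schedule is not None:
        rate = rate.merge(goal_schedule, on="country", how="left")
        rate["within_tolerance"] = (
            (rate["annual_mcpr_change_pp"] - rate["target_pp_per_year"]).abs()
            <= tolerance_pp
        )
    return Fp2020Account(
        countries=countries,
        baseline_year=baseline_year,
        end_year=end_year,
        users=users,
        additional_users=additional,
        goal=goal,
        shortfall=shortfall,
        rate_check=rate,
    )


def categorize_sdi(sdi: float) -> str:
    """Development category of an SDI value on the 0-100 scale.

    Intervals are half-open at the top except the last, which includes
    100.0 exactly.
    """
    if not 0.0 <= sdi <= 100.0:
        raise ValueError(f"SDI out of range [0,100]: {sdi}")
    for name, lo, hi in SDI_CATEGORIES:
        if lo <= sdi < hi:
            return name
    return SDI_CATEGORIES[-1][0]  # sdi == 100.0


def share_report(counts: dict) -> pd.DataFrame:
    """Shares of a total across groups (e.g. unmet need across regions).

    ``counts`` maps group name to a count (scalar or draw array). Shares
    are computed per draw against the summed total and summarized; they
    sum to 1 by construction.
    """
    names = list(counts)
    arrs = [np.atleast_1d(np.asarray(counts[k], dtype=float)) for k in names]
    total = np.sum(arrs, axis=0)
    rows = []
    for name, a in zip(names, arrs):
        share = a / total
        rows.append(
            {
                "group": name,
                "count": float(a.mean()),
                "share": float(share.mean()),
                "share_pct": float(share.mean() * 100.0),
            }
        )
    return pd.DataFrame(rows)


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal round-half-up (reports print 26.45 -> 26.5, not 26.4)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def format_percent(x: float, decimals: int = 1) -> str:
    return f"{round_half_up(x * 100.0, decimals):.{decimals}f}"


def render_indicator_report(rows: list[dict]) -> pd.DataFrame:
    """Country-level report: 2019 levels and 1970-2019 changes with UIs.

    Each input row carries ``location_id``, ``quantity`` and draw arrays
    ``draws_2019``/``draws_1970``; output holds percentages at one decimal
    (half-up) with 95% uncertainty intervals.
    """
    out = []
    for r in rows:
        d19 = np.asarray(r["draws_2019"], dtype=float)
        d70 = np.asarray(r["draws_1970"], dtype=float)
        change = absolute_change(d19, d70)
        out.append(
            {
                "location_id": r["location_id"],
                "quantity": r["quantity"],
                "value_2019": format_percent(d19.mean()),
                "lower_2019": format_percent(np.quantile(d19, 0.025)),
                "upper_2019": format_percent(np.quantile(d19, 0.975)),
                "change_pp": round_half_up(change.mean()),
                "change_lower": round_half_up(np.quantile(change, 0.025)),
                "change_upper": round_half_up(np.quantile(change, 0.975)),
            }
        )
    return pd.DataFrame(out)
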