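"""Crosswalk adjustment for surveys missing need-classification items.

Some questionnaires lack one or more of the items needed to classify need
among non-users (fecundity, fertility desire, post-partum amenorrhoea
status, pregnancy wantedness). Estimates from such surveys are computed
under permissive defaults and are therefore biased relative to complete
surveys. The crosswalk measures that bias on complete surveys — each
quantity recomputed with and without the item, paired within survey and
age group — and applies the mean difference (with-item minus without-item)
additively to incomplete-survey estimates, inflating their standard errors
by the bias uncertainty.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .constants import NEED_COMPONENTS, QUANTITY_NEED_SHARE
from .indicators import ESTIMATE_COLUMNS, SurveyEstimate, extract_estimates
from .methods import DEFAULT_PRIORITY

logger = logging.getLogger(__name__)

BIAS_COLUMNS = [
    "component",
    "age_group",
    "quantity",
    "delta",
    "delta_se",
    "n_pairs",
    "usable",
]

POOLED_AGE = "all"


class UnusableBiasError(ValueError):
    """No usable bias exists for a missing component."""


def _to_scale(p: np.ndarray, scale: str) -> np.ndarray:
    if scale == "natural":
        return p
    q = np.clip(p, 1e-3, 1 - 1e-3)
    return np.log(q / (1 - q))


def estimate_component_bias(
    microdata: pd.DataFrame,
    components=NEED_COMPONENTS,
    quantity: str = QUANTITY_NEED_SHARE,
    priority=DEFAULT_PRIORITY,
    scale: str = "natural",
) -> pd.DataFrame:
    """Mean with/without-item difference per component and age group.

    ``microdata`` must come from complete surveys (every need item asked).
    For each component the quantity is recomputed twice per
    survey-age-marital cell — once with the full classification rule, once
    with the item forced to its permissive default — and the paired
    differences are averaged by age group. A pooled all-age row (age group
    ``"all"``) is appended as the fallback for sparse age groups. A bias
    with fewer than 2 pairs is flagged unusable.
    """
    rows = []
    keys = ["survey_id", "age_group", "marital"]
    with_item = extract_estimates(microdata, quantities=[quantity], priority=priority)
    for comp in components:
        # withhold the item exactly as a missing-item survey would lack it
        masked = microdata.copy()
        if comp == "ppa_status":
            masked["pregnant_or_ppa"] = np.nan
            masked["pregnancy_wanted"] = np.nan
        elif comp == "pregnancy_wanted":
            masked["pregnancy_wanted"] = np.nan
        else:
            masked[comp] = np.nan
        missing_map = {sid: frozenset([comp]) for sid in microdata["survey_id"].unique()}
        without = extract_estimates(
            masked, quantities=[quantity], missing_by_survey=missing_map, priority=priority
        )
        merged = with_item.merge(
            without[keys + ["mean"]], on=keys, suffixes=("", "_without")
        )
        merged["diff"] = _to_scale(merged["mean"].to_numpy(), scale) - _to_scale(
            merged["mean_without"].to_numpy(), scale
        )
        for age, grp in merged.groupby("age_group", observed=True):
            rows.append(_bias_row(comp, age, quantity, grp["diff"].to_numpy()))
        rows.append(_bias_row(comp, POOLED_AGE, quantity, merged["diff"].to_numpy()))
    out = pd.DataFrame(rows, columns=BIAS_COLUMNS)
    out["scale"] = scale
    return out


def _bias_row(component, age_group, quantity, diffs) -> dict:
    n = len(diffs)
    delta = float(np.mean(diffs)) if n else np.nan
    delta_se = float(np.std(diffs, ddof=1) / np.sqrt(n)) if n >= 2 else np.nan
    return {
        "component": component,
        "age_group": age_group,
        "quantity": quantity,
        "delta": delta,
        "delta_se": delta_se,
        "n_pairs": n,
        "usable": bool(n >= 2 and np.isfinite(delta)),
    }


def _lookup_bias(biases: pd.DataFrame, component: str, age_group: str, quantity: str):
    """Usable bias for (component, age), falling back to the pooled row."""
    for age in (age_group, POOLED_AGE):
        m = biases[
            (biases["component"] == component)
            & (biases["age_group"] == age)
            & (biases["quantity"] == quantity)
            & biases["usable"]
        ]
        if not m.empty:
            return float(m.iloc[0]["delta"]), float(m.iloc[0]["delta_se"])
    raise UnusableBiasError(
        f"no usable bias for component {component!r}, age {age_group!r}, quantity {quantity!r}"
    )


def _apply_shift(mean: float, se: float, shift: float, var: float, scale: str):
    """Shifted (mean', se', clipped?) on the requested adjustment scale.

    On the natural scale the delta adds directly and SEs combine in
    quadrature. On the logit scale the delta adds to logit(mean) and SEs
    combine in quadrature on that scale (delta method both ways); the
    adjusted SE is floored at the input SE so adjustment never appears to
    reduce uncertainty.
    """
    if scale == "natural":
        raw = mean + shift
        return float(np.clip(raw, 0.0, 1.0)), float(np.sqrt(se**2 + var)), not 0.0 <= raw <= 1.0
    p = float(np.clip(mean, 1e-3, 1 - 1e-3))
    se_t = se / (p * (1 - p))
    y = np.log(p / (1 - p)) + shift
    p_new = float(1.0 / (1.0 + np.exp(-y)))
    se_new = np.sqrt(se_t**2 + var) * p_new * (1 - p_new)
    return p_new, float(max(se_new, se)), False


def apply_crosswalk(e: SurveyEstimate, biases: pd.DataFrame) -> SurveyEstimate:
    """Shift one incomplete-survey estimate to the complete-survey scale.

    On the (default) natural scale: mean' = clip(mean + sum of deltas, 0,
    1); se' = sqrt(se^2 + sum of delta_se^2). Estimates with no missing
    components are returned unchanged. Raises :class:`UnusableBiasError`
    when a needed bias is unusable (the caller drops the estimate).
    """
    if not e.missing_components:
        return e
    scale = biases["scale"].iloc[0] if "scale" in biases else "natural"
    deltas, variances = [], []
    for comp in sorted(e.missing_components):
        d, dse = _lookup_bias(biases, comp, e.age_group, e.quantity)
        deltas.append(d)
        variances.append(dse**2)
    new_mean, new_se, clipped = _apply_shift(
        e.mean, e.se, sum(deltas), sum(variances), scale
    )
    if clipped:
        logger.warning(
            "crosswalk clipped estimate %s/%s/%s to [0,1]", e.survey_id, e.age_group, e.quantity
        )
    return e.with_values(mean=new_mean, se=new_se, adjusted=True)


def apply_crosswalk_frame(
    estimates: pd.DataFrame,
    biases: pd.DataFrame,
    quantity: str = QUANTITY_NEED_SHARE,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Adjust every flagged estimate of ``quantity`` in an estimates table.

    Returns (adjusted estimates, drop log). Rows whose required bias is
    unusable are dropped and logged; rows of other quantities or with no
    missing components pass through unchanged. Adjusted SEs are never
    smaller than the inputs.
    """
    est = estimates.copy()
    dropped = []
    keep = np.ones(len(est), dtype=bool)
    n_clipped = 0
    miss = est["missing_components"].fillna("")
    target = (est["quantity"] == quantity) & (miss != "")
    for i in np.nonzero(target.to_numpy())[0]:
        row = est.iloc[i]
        comps = sorted(set(row["missing_components"].split(";")) - {""})
        try:
            pairs = [
                _lookup_bias(biases, c, row["age_group"], quantity) for c in comps
            ]
        except UnusableBiasError as err:
            keep[i] = False
            dropped.append(
                {
                    "survey_id": row["survey_id"],
                    "age_group": row["age_group"],
                    "marital": row["marital"],
                    "quantity": quantity,
                    "reason": str(err),
                }
            )
            continue
        shift = sum(d for d, _ in pairs)
        var = sum(dse**2 for _, dse in pairs)
        scale = biases["scale"].iloc[0] if "scale" in biases else "natural"
        new_mean, new_se, clipped = _apply_shift(row["mean"], row["se"], shift, var, scale)
        if clipped:
            n_clipped += 1
        est.iat[i, est.columns.get_loc("mean")] = new_mean
        est.iat[i, est.columns.get_loc("se")] = new_se
        est.iat[i, est.columns.get_loc("adjusted")] = True
    if dropped:
        logger.info("crosswalk dropped %d estimates with unusable biases", len(dropped))
    if n_clipped:
        logger.warning("crosswalk clipped %d adjusted means to [0,1]", n_clipped)
    out = est[keep].reset_index(drop=True)
    return out[ESTIMATE_COLUMNS], pd.DataFrame(
        dropped, columns=["survey_id", "age_group", "marital", "quantity", "reason"]
    )
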