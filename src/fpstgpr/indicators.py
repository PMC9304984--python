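"""Woman-level records -> survey estimates.

Classifies each respondent's contraceptive status and need for family
planning, then produces survey-weighted proportions with standard errors
per (survey, location, year, age group, marital status) cell for: CPR,
each of the 14 method shares (among all women), and the share of non-users
with need. Effective sample sizes follow the Kish formula
``n_eff = (sum w)^2 / sum w^2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .constants import QUANTITY_CPR, QUANTITY_NEED_SHARE
from .methods import ALL_METHODS, DEFAULT_PRIORITY, MethodPriority, prioritize_method

NO_NEED = "no_need"
MET_MODERN = "met_modern"
MET_TRADITIONAL = "met_traditional"
UNMET = "unmet"

ESTIMATE_COLUMNS = [
    "survey_id",
    "location_id",
    "year",
    "age_group",
    "marital",
    "quantity",
    "mean",
    "se",
    "n_eff",
    "missing_components",
    "adjusted",
]


class MissingComponentError(ValueError):
    """A need component required for classification is absent."""


@dataclass(frozen=True)
class SurveyEstimate:
    survey_id: str
    location_id: str
    year: int
    age_group: str
    marital: str
    quantity: str
    mean: float
    se: float
    n_eff: float
    missing_components: frozenset = field(default_factory=frozenset)
    adjusted: bool = False

    def with_values(self, **kw) -> "SurveyEstimate":
        return replace(self, **kw)


def _require(record, name: str, defaults_for) -> float | None:
    """Fetch a flag; None signals 'use the permissive default'."""
    if name == "ppa_status":
        val = record.get("pregnant_or_ppa")
    else:
        val = record.get(name)
    if val is None or (isinstance(val, float) and np.isnan(val)):
        if name in defaults_for or (name == "pregnancy_wanted" and "ppa_status" in defaults_for):
            return None
        raise MissingComponentError(f"need component absent: {name}")
    return float(val)


def classify_need(record, priority: MethodPriority = DEFAULT_PRIORITY, defaults_for=frozenset()):
    """Classify one woman as no_need / met_modern / met_traditional / unmet.

    A current user is met (modern or traditional by her prioritized
    method) regardless of other flags. A non-user has need either through
    the pregnancy branch — currently pregnant or post-partum amenorrhoeic
    and wished to have delayed or prevented that pregnancy — or through
    the exposure branch: partnered (or, if unpartnered, sexually active in
    the past 4 weeks), fecund, and not wanting a child within 2 years.
    Women in the pregnancy branch are classified by it alone.

    Components named in ``defaults_for`` may be absent and then take
    permissive defaults: missing fecundity counts as fecund, missing
    fertility desire as not wanting a child, missing pregnancy status or
    pregnancy wantedness skips the pregnancy branch. Any other absent
    component raises :class:`MissingComponentError`.
    """
    methods = record.get("methods", "")
    if isinstance(methods, (set, frozenset, list, tuple)):
        method_set = set(methods)
    else:
        method_set = set(str(methods).split(";")) - {""} if methods else set()
    if method_set:
        code = prioritize_method(method_set, priority)
        return MET_MODERN if priority.is_modern(code) else MET_TRADITIONAL

    pregnant = _require(record, "ppa_status", defaults_for)
    if pregnant is not None and pregnant > 0:
        wanted = _require(record, "pregnancy_wanted", defaults_for)
        if wanted is None:
            return NO_NEED
        return UNMET if wanted == 0 else NO_NEED

    if record.get("marital") == "unpartnered":
        active = record.get("sexually_active_4wk")
        if active is None or (isinstance(active, float) and np.isnan(active)):
            raise MissingComponentError("need component absent: sexually_active_4wk")
        if not active:
            return NO_NEED
    fecund = _require(record, "fecund", defaults_for)
    if fecund is not None and fecund == 0:
        return NO_NEED
    wants = _require(record, "wants_child_2yr", defaults_for)
    if wants is not None and wants > 0:
        return NO_NEED
    return UNMET


def _prioritized_codes(methods: pd.Series, priority: MethodPriority) -> pd.Series:
    """Vectorized method-of-choice; '' for non-users."""
    rank = {m: i for i, m in enumerate(priority.order)}
    uniq = methods.unique()
    mapping = {}
    for s in uniq:
        if not s:
            mapping[s] = ""
            continue
        codes = s.split(";")
        unknown = [c for c in codes if c not in rank]
        if unknown:
            raise KeyError(f"unknown method code(s): {unknown}")
        mapping[s] = min(codes, key=rank.__getitem__)
    return methods.map(mapping)


def classify_need_frame(
    df: pd.DataFrame,
    priority: MethodPriority = DEFAULT_PRIORITY,
    defaults_for=frozenset(),
) -> pd.Series:
    """Vectorized :func:`classify_need` over a microdata frame."""
    defaults_for = frozenset(defaults_for)
    code = _prioritized_codes(df["methods"].fillna(""), priority)
    modern = code.isin(priority.modern)
    user = (code != "").to_numpy()

    def col(name, default, required_mask):
        if name in defaults_for or (
            name == "pregnancy_wanted" and "ppa_status" in defaults_for
        ):
            return df[_colname(name)].fillna(default).to_numpy(dtype=float)
        vals = df[_colname(name)].to_numpy(dtype=float)
        if np.isnan(vals[required_mask]).any():
            raise MissingComponentError(f"need component absent: {name}")
        return vals

    nonuser = ~user
    pregnant = col("ppa_status", 0.0, nonuser)
    preg_branch = nonuser & (pregnant > 0)
    preg_wanted = col("pregnancy_wanted", 1.0, preg_branch)
    fecund = col("fecund", 1.0, nonuser & ~preg_branch)
    wants = col("wants_child_2yr", 0.0, nonuser & ~preg_branch)
    active = df["sexually_active_4wk"].to_numpy(dtype=float)
    unpartnered = (df["marital"] == "unpartnered").to_numpy()
    if np.isnan(active[unpartnered & nonuser & ~preg_branch]).any():
        raise MissingComponentError("need component absent: sexually_active_4wk")

    need_preg = preg_branch & (np.nan_to_num(preg_wanted, nan=1.0) == 0)
    exposed = np.where(unpartnered, np.nan_to_num(active, nan=0.0) > 0, True)
    need_exposure = ~preg_branch & exposed & (np.nan_to_num(fecund, nan=0.0) > 0) & (
        np.nan_to_num(wants, nan=1.0) == 0
    )
    need = need_preg | need_exposure

    out = np.where(
        user,
        np.where(modern, MET_MODERN, MET_TRADITIONAL),
        np.where(need, UNMET, NO_NEED),
    )
    return pd.Series(out, index=df.index)


def _colname(component: str) -> str:
    return "pregnant_or_ppa" if component == "ppa_status" else component


def _group_codes(df: pd.DataFrame, keys: list) -> tuple[np.ndarray, pd.DataFrame]:
    """Dense group indices plus the unique key rows, in group order."""
    codes, sizes = [], []
    for k in keys:
        col = df[k]
        if isinstance(col.dtype, pd.CategoricalDtype):
            c = col.cat.codes.to_numpy()
            n = len(col.cat.categories)
        else:
            c, uniq = pd.factorize(col, sort=False)
            n = len(uniq)
        codes.append(c.astype(np.int64))
        sizes.append(max(n, 1))
    combined = np.ravel_multi_index(codes, sizes)
    _, first_idx, inv = np.unique(combined, return_index=True, return_inverse=True)
    key_frame = df.iloc[first_idx][keys].reset_index(drop=True)
    return inv, key_frame


def _weighted_mean_se(y: np.ndarray, w: np.ndarray) -> tuple[float, float, float]:
    sw = w.sum()
    if len(w) == 0:
        raise ValueError("empty cell: no records to estimate from")
    if sw <= 0:
        raise ValueError("all-zero survey weights in cell")
    mean = float((w * y).sum() / sw)
    n_eff = float(sw**2 / (w**2).sum())
    if 0.0 < mean < 1.0:
        se = float(np.sqrt(mean * (1.0 - mean) / n_eff))
    else:
        # continuity (Wilson-style) variance floor at the boundary
        x = mean * n_eff
        p_t = (x + 0.5) / (n_eff + 1.0)
        se = float(np.sqrt(p_t * (1.0 - p_t) / n_eff))
    return mean, se, n_eff


def _indicator(records: pd.DataFrame, quantity: str, priority, defaults_for):
    """(denominator mask, 0/1 outcome) for one quantity."""
    code = _prioritized_codes(records["methods"].fillna(""), priority)
    user = (code != "").to_numpy()
    if quantity == QUANTITY_CPR:
        return np.ones(len(records), dtype=bool), user.astype(float)
    if quantity in ALL_METHODS:
        return np.ones(len(records), dtype=bool), (code == quantity).to_numpy(dtype=float)
    if quantity == QUANTITY_NEED_SHARE:
        status = classify_need_frame(records, priority, defaults_for)
        return ~user, (status == UNMET).to_numpy(dtype=float)
    raise ValueError(f"unknown quantity: {quantity}")


def weighted_prevalence(
    records: pd.DataFrame,
    quantity: str,
    cell: dict | None = None,
    priority: MethodPriority = DEFAULT_PRIORITY,
    missing_components=frozenset(),
) -> SurveyEstimate:
    """Survey-weighted proportion with SE for one quantity in one cell.

    ``records`` are the microdata rows of the cell (or a larger frame plus
    a ``cell`` filter dict). ``missing_components`` are the survey's absent
    need items; they are routed to permissive defaults and recorded on the
    estimate so the crosswalk can adjust it.
    """
    df = records
    if cell:
        mask = np.ones(len(df), dtype=bool)
        for k, v in cell.items():
            mask &= (df[k] == v).to_numpy()
        df = df[mask]
    if df.empty:
        raise ValueError(f"empty cell: {cell}")
    missing = frozenset(missing_components)
    denom, y = _indicator(df, quantity, priority, missing)
    mean, se, n_eff = _weighted_mean_se(y[denom], df["weight"].to_numpy()[denom])
    first = df.iloc[0]
    return SurveyEstimate(
        survey_id=str(first["survey_id"]),
        location_id=str(first["location_id"]),
        year=int(first["year"]),
        age_group=str(first["age_group"]),
        marital=str(first["marital"]),
        quantity=quantity,
        mean=mean,
        se=se,
        n_eff=n_eff,
        missing_components=missing,
    )


def tabulate_method_mix(
    records: pd.DataFrame,
    cell: dict | None = None,
    priority: MethodPriority = DEFAULT_PRIORITY,
) -> list[SurveyEstimate]:
    """Per-method shares among all women for one cell.

    Each woman counts once, under her prioritized method, so the 14 shares
    sum exactly to the cell's CPR estimate.
    """
    return [weighted_prevalence(records, m, cell, priority) for m in ALL_METHODS]


def extract_estimates(
    microdata: pd.DataFrame,
    quantities=None,
    missing_by_survey: dict | None = None,
    priority: MethodPriority = DEFAULT_PRIORITY,
) -> pd.DataFrame:
    """Vectorized extraction of all cell estimates from pooled microdata.

    Returns one row per (survey, location, year, age, marital, quantity)
    with columns ``mean``, ``se``, ``n_eff``, ``missing_components``
    (semicolon-joined), ``adjusted`` (False). ``missing_by_survey`` maps
    survey_id to its absent need components; need-share estimates from
    those surveys are computed under permissive defaults and flagged.
    """
    if quantities is None:
        quantities = [QUANTITY_CPR, QUANTITY_NEED_SHARE, *ALL_METHODS]
    missing_by_survey = missing_by_survey or {}
    keys = ["survey_id", "location_id", "year", "age_group", "marital"]
    w = microdata["weight"].to_numpy(dtype=float)
    methods_col = microdata["methods"].fillna("")
    if any(q in ALL_METHODS for q in quantities):
        code = _prioritized_codes(methods_col, priority)
        user = (code != "").to_numpy()
    else:
        code = None
        user = (methods_col != "").to_numpy()

    need_unmet = np.zeros(len(microdata), dtype=float)
    if QUANTITY_NEED_SHARE in quantities:
        key_by_survey = {
            s: ";".join(sorted(missing_by_survey.get(s, ())))
            for s in microdata["survey_id"].unique()
        }
        groups_missing = microdata["survey_id"].map(key_by_survey)
        for miss_key, idx in microdata.groupby(groups_missing, sort=False, observed=True).indices.items():
            defaults = frozenset(miss_key.split(";")) - {""}
            chunk = microdata.iloc[idx]
            status = classify_need_frame(chunk, priority, defaults)
            need_unmet[idx] = (status == UNMET).to_numpy(dtype=float)

    group_idx, key_frame = _group_codes(microdata, keys)
    n_groups = len(key_frame)

    rows = []
    for quantity in quantities:
        if quantity == QUANTITY_NEED_SHARE:
            mask = ~user
            y = need_unmet
        elif quantity == QUANTITY_CPR:
            mask = None
            y = user.astype(float)
        elif quantity in ALL_METHODS:
            mask = None
            y = (code == quantity).to_numpy(dtype=float)
        else:
            raise ValueError(f"unknown quantity: {quantity}")
        if mask is None:
            idx, ws, ys = group_idx, w, y
        else:
            idx, ws, ys = group_idx[mask], w[mask], y[mask]
        sw = np.bincount(idx, weights=ws, minlength=n_groups)
        sw2 = np.bincount(idx, weights=ws**2, minlength=n_groups)
        swy = np.bincount(idx, weights=ws * ys, minlength=n_groups)
        keep = sw > 0
        mean = swy[keep] / sw[keep]
        n_eff = sw[keep] ** 2 / sw2[keep]
        with np.errstate(invalid="ignore"):
            se = np.sqrt(mean * (1 - mean) / n_eff)
        at_bound = (mean <= 0) | (mean >= 1)
        if at_bound.any():
            x = mean[at_bound] * n_eff[at_bound]
            p_t = (x + 0.5) / (n_eff[at_bound] + 1.0)
            se[at_bound] = np.sqrt(p_t * (1 - p_t) / n_eff[at_bound])
        out = key_frame[keep].reset_index(drop=True).copy()
        out["quantity"] = quantity
        out["mean"] = mean
        out["se"] = se
        out["n_eff"] = n_eff
        rows.append(out)
    est = pd.concat(rows, ignore_index=True)
    est["missing_components"] = np.array(
        [";".join(sorted(missing_by_survey.get(s, ()))) for s in est["survey_id"]],
        dtype=object,
    )
    est["adjusted"] = False
    return est[ESTIMATE_COLUMNS]
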