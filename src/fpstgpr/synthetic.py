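"""Synthetic ground truth and survey microdata for the full pipeline.

The generator builds the world the estimator assumes: smooth logit-linear
prevalence trends driven by development covariates, nested random
intercepts at location/region/super-region, a per-location method mix that
drifts log-linearly from traditional toward modern methods, and
survey-weighted woman-level microdata sampled from that truth. Every
downstream stage (indicator extraction, crosswalk, three-stage regression,
raking, aggregation) can therefore be tested against a known surface.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import (
    AGE_GROUPS,
    DEFAULT_YEARS,
    MARITAL_STATUSES,
    NEED_COMPONENTS,
    QUANTITY_CPR,
    QUANTITY_NEED_SHARE,
    QUANTITY_PARTNERED,
)
from .hierarchy import LocationHierarchy, generate_population
from .methods import ALL_METHODS, N_METHODS

SUITE_A_COVARIATES = ("edu_female", "log_ldi")
SUITE_B_COVARIATES = ("sdi",)

_CELL_KEY = ["location_id", "year", "age_group", "marital"]


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class GeneratorParams:
    """Settings of the synthetic data-generating process.

    Fixed effects are on the logit scale. ``truth_suite`` selects which
    covariate suite drives the truth: ``"a"`` (female education and log
    lag-distributed income) or ``"b"`` (SDI). Random-intercept standard
    deviations apply at each nesting level. ``wiggle_amplitude`` adds a
    smooth low-frequency sinusoid per location so the truth is not exactly
    linear in time. ``misspecify`` injects a year-driven sinusoid that no
    covariate explains, for robustness tests.
    """

    truth_suite: str = "b"
    coef: dict = field(
        default_factory=lambda: {
            QUANTITY_CPR: {"intercept": -2.2, "sdi": 0.035, "edu_female": 0.18, "log_ldi": 0.25},
            QUANTITY_NEED_SHARE: {"intercept": 0.5, "sdi": -0.015, "edu_female": -0.08, "log_ldi": -0.10},
            QUANTITY_PARTNERED: {"intercept": 0.8, "sdi": -0.008, "edu_female": -0.04, "log_ldi": -0.05},
        }
    )
    age_intercepts: dict = field(
        default_factory=lambda: {
            QUANTITY_CPR: (-0.8, -0.2, 0.0, 0.1, 0.1, -0.1, -0.5),
            QUANTITY_NEED_SHARE: (0.2, 0.1, 0.0, 0.0, -0.1, -0.2, -0.4),
            QUANTITY_PARTNERED: (-2.5, -0.8, 0.2, 0.7, 0.9, 1.0, 1.0),
        }
    )
    marital_offsets: dict = field(
        default_factory=lambda: {
            QUANTITY_CPR: {"partnered": 0.3, "unpartnered": -0.7},
            QUANTITY_NEED_SHARE: {"partnered": 0.1, "unpartnered": -0.3},
        }
    )
    re_sd: dict = field(
        default_factory=lambda: {"location": 0.25, "region": 0.15, "super_region": 0.15}
    )
    wiggle_amplitude: float = 0.12
    misspecify: bool = False
    # Dirichlet concentrations for the per-location method-mix weights; a
    # zero entry deactivates that method entirely.
    method_alpha: tuple = (3.0, 0.5, 2.5, 2.5, 1.5, 3.0, 2.0, 0.3, 0.2, 0.5, 1.0, 1.5, 1.5, 0.5)
    # Log-linear drift of the mix weights per year (modern up, traditional down).
    method_drift: tuple = (
        0.010, 0.005, 0.015, 0.020, 0.025, 0.010, 0.015, 0.0, 0.010, 0.005,
        -0.020, -0.030, -0.030, -0.020,
    )
    p_multi_method: float = 0.05
    weight_sigma: float = 0.25
    # Marginals used for flags whose value does not alter the cell's truth.
    p_pregnant_need: float = 0.15
    p_pregnant_noneed: float = 0.08

    def suite_covariates(self) -> tuple[str, ...]:
        return SUITE_A_COVARIATES if self.truth_suite == "a" else SUITE_B_COVARIATES

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["method_alpha"] = list(self.method_alpha)
        d["method_drift"] = list(self.method_drift)
        return d


def generate_covariates(hierarchy: LocationHierarchy, years=None, seed: int = 0) -> pd.DataFrame:
    """Location-year development covariates: SDI, female education, log LDI.

    SDI follows a per-location upward linear trend with a small smooth
    perturbation; education and income are generated as noisy monotone
    functions of SDI so the two covariate suites carry similar signal.
    """
    rng = np.random.default_rng(seed)
    if years is None:
        years = range(DEFAULT_YEARS[0], DEFAULT_YEARS[1] + 1)
    years = np.asarray(list(years))
    locs = hierarchy.locations
    n = len(locs)
    base = rng.uniform(15.0, 75.0, size=n)
    slope = rng.uniform(0.15, 0.55, size=n)
    phase = rng.uniform(0, 2 * np.pi, size=n)
    t = years - years[0]
    sdi = base[:, None] + slope[:, None] * t[None, :] + 1.5 * np.sin(
        2 * np.pi * t[None, :] / 35.0 + phase[:, None]
    )
    sdi = np.clip(sdi, 0.0, 100.0)
    edu = 1.0 + 0.12 * sdi + rng.normal(0, 0.3, size=(n, 1))
    ldi = 5.5 + 0.045 * sdi + rng.normal(0, 0.15, size=(n, 1))
    idx = pd.MultiIndex.from_product([locs, years], names=["location_id", "year"])
    return pd.DataFrame(
        {
            "sdi": sdi.reshape(-1),
            "edu_female": edu.reshape(-1),
            "log_ldi": ldi.reshape(-1),
        },
        index=idx,
    ).reset_index()


@dataclass
class TrueSurface:
    """Ground-truth proportions for every (location, year, age, marital) cell.

    ``wide`` is indexed by the cell key and carries one column per
    quantity: ``cpr``, the 14 method shares (among all women), and
    ``nonuser_need_share``. ``partnered`` holds the partnered proportion by
    (location, year, age). Method shares sum to CPR in every cell.
    """

    wide: pd.DataFrame
    partnered: pd.DataFrame

    def value(self, location_id, year, age_group, marital, quantity) -> float:
        if quantity == QUANTITY_PARTNERED:
            return float(
                self.partnered.set_index(["location_id", "year", "age_group"]).loc[
                    (location_id, year, age_group), QUANTITY_PARTNERED
                ]
            )
        return float(self.wide.loc[(location_id, year, age_group, marital), quantity])

    def long(self) -> pd.DataFrame:
        out = self.wide.reset_index().melt(
            id_vars=_CELL_KEY, var_name="quantity", value_name="value"
        )
        p = self.partnered.copy()
        p["marital"] = "all"
        p = p.rename(columns={QUANTITY_PARTNERED: "value"})
        p["quantity"] = QUANTITY_PARTNERED
        return pd.concat([out, p[_CELL_KEY + ["quantity", "value"]]], ignore_index=True)

    def to_csv(self, path) -> None:
        self.long().to_csv(path, index=False)

    @classmethod
    def from_long(cls, long: pd.DataFrame) -> "TrueSurface":
        p = long[long["quantity"] == QUANTITY_PARTNERED]
        rest = long[long["quantity"] != QUANTITY_PARTNERED]
        wide = rest.pivot_table(
            index=_CELL_KEY, columns="quantity", values="value", aggfunc="first"
        )
        wide.columns.name = None
        partnered = p.rename(columns={"value": QUANTITY_PARTNERED})[
            ["location_id", "year", "age_group", QUANTITY_PARTNERED]
        ].reset_index(drop=True)
        return cls(wide=wide, partnered=partnered)

    @classmethod
    def from_csv(cls, path) -> "TrueSurface":
        return cls.from_long(pd.read_csv(path))


def _linear_predictor(params, quantity, cov, ages, marital, re_by_loc, wiggle):
    """Logit-scale predictor over (loc x year) for one quantity/age/marital."""
    coefs = params.coef[quantity]
    lp = np.full(cov["sdi"].shape, coefs["intercept"], dtype=float)
    for name in params.suite_covariates():
        lp = lp + coefs[name] * cov[name]
    lp = lp + re_by_loc[:, None]
    lp = lp + wiggle
    if marital is not None:
        lp = lp + params.marital_offsets[quantity][marital]
    return lp


def generate_true_surface(
    hierarchy: LocationHierarchy,
    covariates: pd.DataFrame,
    params: GeneratorParams | None = None,
    seed: int = 0,
) -> TrueSurface:
    """Build the complete ground-truth surface.

    CPR is generated first on the logit scale; method shares are a
    Dirichlet-weighted split of CPR with log-linear temporal drift of the
    weights; the need share among non-users and the partnered proportion
    get their own logit surfaces. Deterministic given ``seed``.
    """
    if params is None:
        params = GeneratorParams()
    rng = np.random.default_rng(seed)
    locs = hierarchy.locations
    years = np.sort(covariates["year"].unique())
    n_loc, n_year = len(locs), len(years)

    cov_idx = covariates.set_index(["location_id", "year"])
    for loc in locs:
        for year in years:
            if (loc, int(year)) not in cov_idx.index:
                raise ValueError(f"covariates missing for location-year ({loc}, {year})")
    cov = {}
    for name in ("sdi", "edu_female", "log_ldi"):
        cov[name] = (
            cov_idx[name].unstack("year").reindex(index=locs, columns=years).to_numpy()
        )

    quantities = [QUANTITY_CPR, QUANTITY_NEED_SHARE, QUANTITY_PARTNERED]
    # Nested random intercepts per quantity, drawn at each level then summed.
    re_total = {}
    regions = hierarchy.table.set_index("location_id")
    for q in quantities:
        u_sr = {sr: rng.normal(0, params.re_sd["super_region"]) for sr in hierarchy.super_regions}
        u_r = {r: rng.normal(0, params.re_sd["region"]) for r in hierarchy.regions}
        u_l = {l: rng.normal(0, params.re_sd["location"]) for l in locs}
        re_total[q] = np.array(
            [
                u_l[l] + u_r[regions.loc[l, "region_id"]] + u_sr[regions.loc[l, "super_region_id"]]
                for l in locs
            ]
        )

    t = years - years[0]
    wiggles = {}
    for q in quantities:
        period = rng.uniform(15, 30, size=n_loc)
        phase = rng.uniform(0, 2 * np.pi, size=n_loc)
        wiggles[q] = params.wiggle_amplitude * np.sin(
            2 * np.pi * t[None, :] / period[:, None] + phase[:, None]
        )
        if params.misspecify and q == QUANTITY_CPR:
            wiggles[q] = wiggles[q] + 0.5 * np.sin(2 * np.pi * t[None, :] / 18.0)

    # Method-mix Dirichlet weights per location, drifting log-linearly in time.
    alpha = np.asarray(params.method_alpha, dtype=float)
    active = alpha > 0
    base_w = np.zeros((n_loc, N_METHODS))
    base_w[:, active] = rng.dirichlet(alpha[active], size=n_loc)
    drift = np.asarray(params.method_drift, dtype=float)
    logw = np.where(base_w > 0, np.log(np.maximum(base_w, 1e-300)), -np.inf)
    # shape (loc, year, method)
    logw_t = logw[:, None, :] + drift[None, None, :] * t[None, :, None]
    logw_t[:, :, ~active] = -np.inf
    w = np.exp(logw_t - logw_t.max(axis=2, keepdims=True))
    w[:, :, ~active] = 0.0
    w = w / w.sum(axis=2, keepdims=True)

    rows = []
    for ai, age in enumerate(AGE_GROUPS):
        for marital in MARITAL_STATUSES:
            cpr = _expit(
                _linear_predictor(params, QUANTITY_CPR, cov, ages=ai, marital=marital,
                                  re_by_loc=re_total[QUANTITY_CPR], wiggle=wiggles[QUANTITY_CPR])
                + params.age_intercepts[QUANTITY_CPR][ai]
            )
            need = _expit(
                _linear_predictor(params, QUANTITY_NEED_SHARE, cov, ages=ai, marital=marital,
                                  re_by_loc=re_total[QUANTITY_NEED_SHARE],
                                  wiggle=wiggles[QUANTITY_NEED_SHARE])
                + params.age_intercepts[QUANTITY_NEED_SHARE][ai]
            )
            shares = cpr[:, :, None] * w  # (loc, year, method)
            block = pd.DataFrame(
                {
                    "location_id": np.repeat(locs, n_year),
                    "year": np.tile(years, n_loc),
                    "age_group": age,
                    "marital": marital,
                    QUANTITY_CPR: cpr.reshape(-1),
                    QUANTITY_NEED_SHARE: need.reshape(-1),
                }
            )
            for mi, m in enumerate(ALL_METHODS):
                block[m] = shares[:, :, mi].reshape(-1)
            rows.append(block)
    wide = pd.concat(rows, ignore_index=True).set_index(_CELL_KEY).sort_index()

    prows = []
    for ai, age in enumerate(AGE_GROUPS):
        pp = _expit(
            _linear_predictor(params, QUANTITY_PARTNERED, cov, ages=ai, marital=None,
                              re_by_loc=re_total[QUANTITY_PARTNERED],
                              wiggle=wiggles[QUANTITY_PARTNERED])
            + params.age_intercepts[QUANTITY_PARTNERED][ai]
        )
        prows.append(
            pd.DataFrame(
                {
                    "location_id": np.repeat(locs, n_year),
                    "year": np.tile(years, n_loc),
                    "age_group": age,
                    QUANTITY_PARTNERED: pp.reshape(-1),
                }
            )
        )
    partnered = pd.concat(prows, ignore_index=True)
    return TrueSurface(wide=wide, partnered=partnered)


@dataclass(frozen=True)
class SurveyDesign:
    """One survey: where/when it sampled, cell sizes, and which need items
    its questionnaire lacked (withheld from every respondent)."""

    survey_id: str
    location_id: str
    year: int
    n_women: int = 500
    missing_components: frozenset = frozenset()
    partnered_only: bool = False
    p_multi_method: float = 0.05

    def __post_init__(self):
        if self.n_women < 1:
            raise ValueError("n_women must be >= 1")
        bad = set(self.missing_components) - set(NEED_COMPONENTS)
        if bad:
            raise ValueError(f"unknown need components: {sorted(bad)}")


def make_survey_designs(
    hierarchy: LocationHierarchy,
    years,
    cadence: int = 5,
    n_per_cell: int = 500,
    missing_rate: float = 0.0,
    partnered_only_rate: float = 0.0,
    seed: int = 0,
) -> list[SurveyDesign]:
    """One survey per location every ``cadence`` years; a ``missing_rate``
    fraction of surveys lack one randomly chosen need item."""
    rng = np.random.default_rng(seed)
    years = list(years)
    designs = []
    for loc in hierarchy.locations:
        for year in years:
            if (year - years[0]) % cadence != 0:
                continue
            missing = frozenset()
            if rng.random() < missing_rate:
                missing = frozenset([str(rng.choice(NEED_COMPONENTS))])
            designs.append(
                SurveyDesign(
                    survey_id=f"SVY_{loc}_{year}",
                    location_id=loc,
                    year=int(year),
                    n_women=n_per_cell,
                    missing_components=missing,
                    partnered_only=rng.random() < partnered_only_rate,
                )
            )
    return designs


MICRODATA_COLUMNS = [
    "survey_id",
    "location_id",
    "year",
    "age_group",
    "marital",
    "methods",
    "sexually_active_4wk",
    "fecund",
    "wants_child_2yr",
    "pregnant_or_ppa",
    "pregnancy_wanted",
    "weight",
]


def simulate_survey(
    surface: TrueSurface, design: SurveyDesign, seed: int, wants_bias: float = 0.0
) -> pd.DataFrame:
    """Draw woman-level records from the truth for one survey.

    Per age-marital cell, method use is multinomial over the 14 methods
    plus non-use with the cell's true probabilities; need components of
    non-users are drawn so the cell's true need share among non-users is
    matched in expectation, by first drawing the need indicator and then
    filling flags consistent with it. Components listed in
    ``design.missing_components`` are withheld (NaN) on every record.
    Flag columns are 0.0/1.0 floats; ``pregnancy_wanted`` is defined only
    for pregnant or post-partum-amenorrhoeic women.

    ``wants_bias`` installs a known component effect for crosswalk
    recovery tests: exactly that probability mass of non-users is made
    "no need, failing only the fertility-desire criterion", so that
    recomputing the need share without the wants-child item (permissive
    default: not wanting) shifts it by +wants_bias in expectation, i.e.
    the with-minus-without bias is -wants_bias.
    """
    rng = np.random.default_rng(seed)
    maritals = ("partnered",) if design.partnered_only else MARITAL_STATUSES
    method_cols = list(ALL_METHODS)
    chunks: dict[str, list] = {c: [] for c in ("methods", "sexually_active_4wk", "fecund",
                                               "wants_child_2yr", "pregnant_or_ppa",
                                               "pregnancy_wanted")}
    cell_age, cell_marital, cell_n = [], [], []
    try:
        block = surface.wide.loc[(design.location_id, design.year)]
    except KeyError:
        raise KeyError(
            f"design cell absent from surface: ({design.location_id}, {design.year})"
        ) from None
    cols = [QUANTITY_CPR, QUANTITY_NEED_SHARE] + method_cols
    block_np = block[cols].to_numpy(dtype=float)
    block_pos = {k: i for i, k in enumerate(block.index)}
    for age in AGE_GROUPS:
        for marital in maritals:
            key = (design.location_id, design.year, age, marital)
            if (age, marital) not in block_pos:
                raise KeyError(f"design cell absent from surface: {key}")
            row = block_np[block_pos[(age, marital)]]
            cpr = row[0]
            need_share = row[1]
            shares = row[2:]
            n = design.n_women
            probs = np.concatenate([shares, [max(0.0, 1.0 - cpr)]])
            probs = np.maximum(probs, 0.0)
            probs = probs / probs.sum()
            assign = rng.choice(N_METHODS + 1, size=n, p=probs)
            user = assign < N_METHODS

            methods = np.empty(n, dtype=object)
            methods[~user] = ""
            user_idx = np.nonzero(user)[0]
            if user_idx.size:
                codes = np.array(ALL_METHODS, dtype=object)[assign[user_idx]]
                # occasionally a second, lower-priority method is also
                # reported; prioritization must still pick the drawn one.
                multi = (rng.random(user_idx.size) < design.p_multi_method) & (
                    assign[user_idx] < N_METHODS - 1
                )
                methods[user_idx] = codes
                if multi.any():
                    mi = user_idx[multi]
                    extra_rank = rng.integers(assign[mi] + 1, N_METHODS)
                    extras = np.array(ALL_METHODS, dtype=object)[extra_rank]
                    methods[mi] = np.char.add(
                        np.char.add(codes[multi].astype(str), ";"), extras.astype(str)
                    ).astype(object)

            active = np.ones(n)
            fecund = np.ones(n)
            wants = np.zeros(n)
            pregnant = np.zeros(n)
            preg_wanted = np.full(n, np.nan)

            nonuser_idx = np.nonzero(~user)[0]
            if nonuser_idx.size:
                m = nonuser_idx.size
                u01 = rng.random(m)
                need = u01 < need_share
                # need via the pregnancy branch: pregnant/PPA with an
                # unwanted (mistimed) pregnancy
                preg_need = need & (rng.random(m) < 0.15)
                pregnant[nonuser_idx[preg_need]] = 1.0
                preg_wanted[nonuser_idx[preg_need]] = 0.0
                # installed wants-only no-need mass (crosswalk recovery)
                wants_only = ~need & (u01 < need_share + wants_bias)
                wants[nonuser_idx[wants_only]] = 1.0
                # no-need via a wanted pregnancy
                preg_ok = ~need & ~wants_only & (rng.random(m) < 0.08)
                pregnant[nonuser_idx[preg_ok]] = 1.0
                preg_wanted[nonuser_idx[preg_ok]] = 1.0
                wants[nonuser_idx[preg_ok]] = 1.0
                # remaining no-need women fail exactly one criterion
                rest = ~need & ~wants_only & ~preg_ok
                reasons = ["infecund", "inactive"] if marital == "unpartnered" else ["infecund"]
                if wants_bias == 0.0:
                    reasons.append("wants_child")
                reason = rng.integers(0, len(reasons), size=m)
                fecund[nonuser_idx[rest & (reason == 0)]] = 0.0
                if "inactive" in reasons:
                    active[nonuser_idx[rest & (reason == 1)]] = 0.0
                if "wants_child" in reasons:
                    wi = reasons.index("wants_child")
                    wants[nonuser_idx[rest & (reason == wi)]] = 1.0
            if user_idx.size:
                # components of users never enter need classification (the
                # user branch wins) but are populated realistically.
                k = user_idx.size
                fecund[user_idx] = (rng.random(k) < 0.9).astype(float)
                wants[user_idx] = (rng.random(k) < 0.3).astype(float)
                preg_u = rng.random(k) < 0.05
                pregnant[user_idx] = preg_u.astype(float)
                pw = np.where(rng.random(k) < 0.5, 1.0, 0.0)
                preg_wanted[user_idx] = np.where(preg_u, pw, np.nan)

            cell_age.append(age)
            cell_marital.append(marital)
            cell_n.append(n)
            chunks["methods"].append(methods)
            chunks["sexually_active_4wk"].append(active)
            chunks["fecund"].append(fecund)
            chunks["wants_child_2yr"].append(wants)
            chunks["pregnant_or_ppa"].append(pregnant)
            chunks["pregnancy_wanted"].append(preg_wanted)
    cols = {c: np.concatenate(v) for c, v in chunks.items()}
    counts = np.asarray(cell_n)
    total = int(counts.sum())
    out = pd.DataFrame(
        {
            "survey_id": pd.Categorical([design.survey_id]).repeat(total),
            "location_id": pd.Categorical([design.location_id]).repeat(total),
            "year": np.full(total, design.year, dtype=np.int64),
            "age_group": pd.Categorical(
                np.repeat(np.asarray(cell_age, dtype=object), counts), categories=AGE_GROUPS
            ),
            "marital": pd.Categorical(
                np.repeat(np.asarray(cell_marital, dtype=object), counts),
                categories=MARITAL_STATUSES,
            ),
            **cols,
        }
    )
    w = rng.lognormal(0.0, 0.25, size=len(out))
    out["weight"] = w / w.mean()

    for comp in design.missing_components:
        if comp == "fecund":
            out["fecund"] = np.nan
        elif comp == "wants_child_2yr":
            out["wants_child_2yr"] = np.nan
        elif comp == "ppa_status":
            out["pregnant_or_ppa"] = np.nan
            out["pregnancy_wanted"] = np.nan
        elif comp == "pregnancy_wanted":
            out["pregnancy_wanted"] = np.nan
    return out[MICRODATA_COLUMNS]


def simulate_all_surveys(surface: TrueSurface, designs, seed: int) -> pd.DataFrame:
    """Simulate every survey; each gets an independent substream of ``seed``
    keyed by its position, so results do not depend on evaluation order."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(designs))
    frames = [
        simulate_survey(surface, d, seed=int(c.generate_state(1)[0] % (2**31)))
        for d, c in zip(designs, children)
    ]
    return pd.concat(frames, ignore_index=True)


@dataclass
class SyntheticWorld:
    """Bundle of every synthetic input the pipeline consumes."""

    hierarchy: LocationHierarchy
    covariates: pd.DataFrame
    surface: TrueSurface
    population: pd.DataFrame
    designs: list
    params: GeneratorParams
    seed: int

    def microdata(self) -> pd.DataFrame:
        return simulate_all_surveys(self.surface, self.designs, seed=self.seed + 1)


def generate_world(
    n_super_regions: int = 2,
    n_regions_per_super: int = 2,
    n_locations_per_region: int = 5,
    years=None,
    cadence: int = 5,
    n_per_cell: int = 500,
    missing_rate: float = 0.0,
    partnered_only_rate: float = 0.0,
    params: GeneratorParams | None = None,
    seed: int = 0,
) -> SyntheticWorld:
    if years is None:
        years = range(DEFAULT_YEARS[0], DEFAULT_YEARS[1] + 1)
    years = list(years)
    if params is None:
        params = GeneratorParams()
    hierarchy = LocationHierarchy.balanced(
        n_super_regions, n_regions_per_super, n_locations_per_region
    )
    covariates = generate_covariates(hierarchy, years, seed=seed)
    surface = generate_true_surface(hierarchy, covariates, params, seed=seed + 10)
    population = generate_population(hierarchy, years, seed=seed + 20)
    designs = make_survey_designs(
        hierarchy,
        years,
        cadence=cadence,
        n_per_cell=n_per_cell,
        missing_rate=missing_rate,
        partnered_only_rate=partnered_only_rate,
        seed=seed + 30,
    )
    return SyntheticWorld(hierarchy, covariates, surface, population, designs, params, seed)
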