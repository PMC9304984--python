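"""Synthetic world generator: determinism, degenerate limits, convergence."""

import numpy as np
import pandas as pd
import pytest

from fpstgpr.constants import AGE_GROUPS, MARITAL_STATUSES
from fpstgpr.hierarchy import LocationHierarchy, generate_population, global_age_weights
from fpstgpr.indicators import classify_need_frame, weighted_prevalence
from fpstgpr.methods import ALL_METHODS
from fpstgpr.synthetic import (
    GeneratorParams,
    SurveyDesign,
    TrueSurface,
    generate_covariates,
    generate_true_surface,
    simulate_survey,
)


@pytest.fixture(scope="module")
def tiny_hierarchy():
    return LocationHierarchy.balanced(1, 2, 2)


@pytest.fixture(scope="module")
def tiny_covariates(tiny_hierarchy):
    return generate_covariates(tiny_hierarchy, range(2000, 2006), seed=1)


def test_surface_determinism_and_roundtrip(tiny_hierarchy, tiny_covariates, tmp_path):
    s1 = generate_true_surface(tiny_hierarchy, tiny_covariates, seed=5)
    s2 = generate_true_surface(tiny_hierarchy, tiny_covariates, seed=5)
    pd.testing.assert_frame_equal(s1.wide, s2.wide)
    path = tmp_path / "surface.csv"
    s1.to_csv(path)
    s3 = TrueSurface.from_csv(path)
    assert np.allclose(
        s1.wide.sort_index().to_numpy(), s3.wide.sort_index()[s1.wide.columns].to_numpy()
    )


def test_surface_invariants(tiny_hierarchy, tiny_covariates):
    s = generate_true_surface(tiny_hierarchy, tiny_covariates, seed=5)
    vals = s.wide.to_numpy()
    assert ((vals >= 0) & (vals <= 1)).all()
    share_sum = s.wide[list(ALL_METHODS)].sum(axis=1)
    assert np.all(share_sum <= s.wide["cpr"] + 1e-9)
    assert np.allclose(share_sum, s.wide["cpr"])  # composition is exact
    pv = s.partnered["partnered_proportion"].to_numpy()
    assert ((pv >= 0) & (pv <= 1)).all()


def test_degenerate_generator_is_exact_inverse_logit(tiny_hierarchy, tiny_covariates):
    params = GeneratorParams(
        re_sd={"location": 0.0, "region": 0.0, "super_region": 0.0},
        wiggle_amplitude=0.0,
    )
    s = generate_true_surface(tiny_hierarchy, tiny_covariates, params, seed=9)
    cov = tiny_covariates.set_index(["location_id", "year"])
    for (loc, year, age, marital), row in s.wide.iloc[:40].iterrows():
        ai = list(AGE_GROUPS).index(age)
        lp = (
            params.coef["cpr"]["intercept"]
            + params.coef["cpr"]["sdi"] * cov.loc[(loc, year), "sdi"]
            + params.age_intercepts["cpr"][ai]
            + params.marital_offsets["cpr"][marital]
        )
        assert row["cpr"] == pytest.approx(1 / (1 + np.exp(-lp)), abs=1e-12)


def test_missing_covariate_row_fails_with_location(tiny_hierarchy, tiny_covariates):
    cov = tiny_covariates[
        ~((tiny_covariates["location_id"] == "L001") & (tiny_covariates["year"] == 2003))
    ]
    with pytest.raises(ValueError, match="L001.*2003"):
        generate_true_surface(tiny_hierarchy, cov, seed=1)


def test_dirichlet_mix_monte_carlo(tiny_hierarchy):
    """Two active methods with Dirichlet(0.5, 0.5) weights and no drift:
    each method's expected share is cpr/2; the Monte-Carlo mean over many
    surfaces must sit within 3 standard errors."""
    cov = generate_covariates(tiny_hierarchy, [2000], seed=1)
    alpha = [0.5, 0.5] + [0.0] * 12
    params = GeneratorParams(method_alpha=tuple(alpha), method_drift=(0.0,) * 14)
    cell = ("L000", 2000, "25-29", "partnered")
    vals = np.empty((1000, 2))
    for i in range(1000):
        s = generate_true_surface(tiny_hierarchy, cov, params, seed=20_000 + i)
        row = s.wide.loc[cell]
        vals[i, 0] = row[ALL_METHODS[0]] / row["cpr"]
        vals[i, 1] = row[ALL_METHODS[1]] / row["cpr"]
    # weights ~ Dirichlet(0.5,0.5): mean 1/2, var = 1/8 -> se of MC mean
    se = np.sqrt(0.125 / 1000)
    for j in range(2):
        assert abs(vals[:, j].mean() - 0.5) < 3 * se


def _manual_surface(cpr, need_share, methods=None):
    rows = []
    shares = methods or {m: 0.0 for m in ALL_METHODS}
    for age in AGE_GROUPS:
        for marital in MARITAL_STATUSES:
            rows.append(
                {
                    "location_id": "L0",
                    "year": 2010,
                    "age_group": age,
                    "marital": marital,
                    "cpr": cpr,
                    "nonuser_need_share": need_share,
                    **shares,
                }
            )
    wide = pd.DataFrame(rows).set_index(["location_id", "year", "age_group", "marital"])
    return TrueSurface(wide=wide, partnered=pd.DataFrame(
        {"location_id": [], "year": [], "age_group": [], "partnered_proportion": []}
    ))


def test_cpr_one_means_every_woman_uses(tiny_hierarchy):
    shares = {m: 0.0 for m in ALL_METHODS}
    shares["pill"] = 0.6
    shares["condom"] = 0.4
    surf = _manual_surface(1.0, 0.0, shares)
    d = SurveyDesign("S", "L0", 2010, n_women=50)
    md = simulate_survey(surf, d, seed=3)
    assert (md["methods"] != "").all()


def test_unmet_need_matches_binomial_oracle(tiny_hierarchy):
    surf = _manual_surface(0.0, 0.3)
    d = SurveyDesign("S", "L0", 2010, n_women=10_000)
    md = simulate_survey(surf, d, seed=3)
    cell = md[(md["age_group"] == "25-29") & (md["marital"] == "partnered")]
    e = weighted_prevalence(cell, "nonuser_need_share")
    se = np.sqrt(0.3 * 0.7 / len(cell))
    assert abs(e.mean - 0.3) < 3 * se


def test_missing_components_masked_on_every_record(tiny_hierarchy):
    surf = _manual_surface(0.3, 0.4, {m: 0.3 / 14 for m in ALL_METHODS})
    d = SurveyDesign("S", "L0", 2010, n_women=40, missing_components=frozenset(["fecund"]))
    md = simulate_survey(surf, d, seed=3)
    assert md["fecund"].isna().all()
    d2 = SurveyDesign("S", "L0", 2010, n_women=40, missing_components=frozenset(["ppa_status"]))
    md2 = simulate_survey(surf, d2, seed=3)
    assert md2["pregnant_or_ppa"].isna().all()
    assert md2["pregnancy_wanted"].isna().all()


def test_partnered_only_survey_has_no_unpartnered_records(tiny_hierarchy):
    surf = _manual_surface(0.3, 0.4)
    d = SurveyDesign("S", "L0", 2010, n_women=30, partnered_only=True)
    md = simulate_survey(surf, d, seed=3)
    assert set(md["marital"].unique()) == {"partnered"}


def test_microdata_determinism(tiny_hierarchy):
    surf = _manual_surface(0.4, 0.3, {m: 0.4 / 14 for m in ALL_METHODS})
    d = SurveyDesign("S", "L0", 2010, n_women=60)
    a = simulate_survey(surf, d, seed=11)
    b = simulate_survey(surf, d, seed=11)
    pd.testing.assert_frame_equal(a, b)


def test_survey_estimates_converge_to_surface(tiny_hierarchy):
    """Weighted estimates at n=50 000 sit within 4 SE of the truth."""
    surf = _manual_surface(0.35, 0.25, {"pill": 0.2, "rhythm": 0.15,
                                        **{m: 0.0 for m in ALL_METHODS if m not in ("pill", "rhythm")}})
    d = SurveyDesign("S", "L0", 2010, n_women=50_000)
    md = simulate_survey(surf, d, seed=17)
    cell = md[(md["age_group"] == "30-34") & (md["marital"] == "partnered")]
    for quantity, truth in [("cpr", 0.35), ("pill", 0.2), ("rhythm", 0.15)]:
        e = weighted_prevalence(cell, quantity)
        assert abs(e.mean - truth) < 4 * e.se, quantity


def test_population_age_shares_and_options(tiny_hierarchy):
    pop = generate_population(tiny_hierarchy, range(2015, 2021), seed=2)
    w = global_age_weights(pop, 2019)
    assert w.sum() == pytest.approx(1.0)
    pop2 = generate_population(tiny_hierarchy, range(2015, 2021), seed=2)
    pd.testing.assert_frame_equal(pop, pop2)
    eq = generate_population(tiny_hierarchy, range(2015, 2021), seed=2, equal=True)
    weq = global_age_weights(eq, 2019)
    assert np.allclose(weq.to_numpy(), 1 / 7)
    assert (pop["population"] > 0).all()
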