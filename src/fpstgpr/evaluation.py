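"""Validation experiments on synthetic data.

Reusable harnesses that measure how well the estimator recovers a known
truth: full-pipeline CPR recovery (error and interval coverage), crosswalk
bias recovery, and outlier-trimming success of the SDI meta-regression.
Both the test suite and the reproduction script run these.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .constants import AGE_GROUPS, MARITAL_STATUSES
from .crosswalk import POOLED_AGE, estimate_component_bias
from .indicators import extract_estimates
from .metareg import fit_trimmed_spline
from .methods import ALL_METHODS
from .stgpr import STGPR, StGprConfig
from .synthetic import SurveyDesign, TrueSurface, generate_world, simulate_survey


def cpr_recovery_experiment(
    n_seeds: int = 50,
    base_seed: int = 0,
    n_super_regions: int = 2,
    n_regions_per_super: int = 2,
    n_locations_per_region: int = 5,
    years=range(1970, 2020),
    cadence: int = 5,
    n_per_cell: int = 2000,
    n_draws: int = 1000,
) -> dict:
    """Estimate CPR with the full pipeline on well-specified synthetic
    worlds and score it against the generating truth.

    Per seed: a fresh world (default 20 locations x 50 years x 7 age bands
    x 2 marital strata, one survey per location every ``cadence`` years
    with ``n_per_cell`` women per cell), indicator extraction, and one
    three-stage fit per marital stratum. Returns the pooled median
    absolute error of the posterior mean in percentage points, the 95%
    uncertainty-interval coverage of the truth, and the cell count.
    """
    errors, covered = [], []
    for k in range(n_seeds):
        seed = int((base_seed + 1000 * k) % (2**31))
        world = generate_world(
            n_super_regions=n_super_regions,
            n_regions_per_super=n_regions_per_super,
            n_locations_per_region=n_locations_per_region,
            years=years,
            cadence=cadence,
            n_per_cell=n_per_cell,
            seed=seed,
        )
        est = extract_estimates(world.microdata(), quantities=["cpr"])
        for marital in MARITAL_STATUSES:
            sub = est[est["marital"] == marital]
            model = STGPR(
                sub, world.covariates, world.hierarchy, StGprConfig(n_draws=n_draws)
            )
            res = model.fit(seed=seed + 7)
            key = pd.MultiIndex.from_frame(model.cells)
            truth = (
                world.surface.wide.xs(marital, level="marital")["cpr"]
                .reindex(key)
                .to_numpy()
            )
            errors.append(np.abs(res.posterior_mean - truth))
            s = res.summarize()
            covered.append(
                ((s["lower"].to_numpy() <= truth) & (truth <= s["upper"].to_numpy()))
            )
    errors = np.concatenate(errors)
    covered = np.concatenate(covered)
    return {
        "median_abs_error_pp": float(np.median(errors) * 100.0),
        "coverage_95ui_pct": float(covered.mean() * 100.0),
        "n_cells": int(errors.size),
        "n_seeds": n_seeds,
    }


def crosswalk_recovery_experiment(
    installed_bias: float = 0.05,
    n_surveys: int = 20,
    n_per_cell: int = 1500,
    base_seed: int = 0,
) -> dict:
    """Install a known wants-child component effect and recover it.

    The generator reserves exactly ``installed_bias`` probability mass of
    non-users as "no need only because a child is wanted", so the
    with-minus-without mean difference for the need share is
    -installed_bias. Returns the pooled estimate, its SE, and the error in
    SE units.
    """
    rows = []
    for age in AGE_GROUPS:
        for marital in MARITAL_STATUSES:
            rows.append(
                {
                    "location_id": "L0",
                    "year": 2010,
                    "age_group": age,
                    "marital": marital,
                    "cpr": 0.2,
                    "nonuser_need_share": 0.3,
                    **{m: 0.2 / 14 for m in ALL_METHODS},
                }
            )
    wide = pd.DataFrame(rows).set_index(["location_id", "year", "age_group", "marital"])
    surface = TrueSurface(wide=wide, partnered=pd.DataFrame(
        {"location_id": [], "year": [], "age_group": [], "partnered_proportion": []}
    ))
    frames = [
        simulate_survey(
            surface,
            SurveyDesign(f"S{i}", "L0", 2010, n_women=n_per_cell),
            seed=int((base_seed + i) % (2**31)),
            wants_bias=installed_bias,
        )
        for i in range(n_surveys)
    ]
    md = pd.concat(frames, ignore_index=True)
    biases = estimate_component_bias(md, components=("wants_child_2yr",))
    pooled = biases[biases["age_group"] == POOLED_AGE].iloc[0]
    delta, delta_se = float(pooled["delta"]), float(pooled["delta_se"])
    return {
        "installed": -installed_bias,
        "recovered_delta": delta,
        "delta_se": delta_se,
        "abs_error_in_se_units": abs(delta - (-installed_bias)) / max(delta_se, 1e-12),
    }


def trimming_experiment(
    n_replicates: int = 100,
    gamma: float = 0.1,
    n_points: int = 120,
    outlier_fraction: float = 0.1,
    base_seed: int = 0,
) -> dict:
    """Rate at which the trimmed spline isolates installed gross outliers.

    Each replicate draws points from a smooth quadratic truth, corrupts a
    ``outlier_fraction`` subset by +-0.4-0.8, fits with trimming fraction
    ``gamma``, and counts success when the trimmed set equals the
    corrupted set exactly.
    """
    hits = 0
    n_out = int(round(outlier_fraction * n_points))
    for rep in range(n_replicates):
        rng = np.random.default_rng(int((base_seed + rep) % (2**31)))
        sdi = rng.uniform(5, 95, size=n_points)
        truth = 0.1 + 0.8 * (sdi / 100.0) ** 2
        value = truth + rng.normal(0, 0.01, n_points)
        idx = rng.choice(n_points, size=n_out, replace=False)
        value[idx] += rng.choice([-1.0, 1.0], n_out) * rng.uniform(0.4, 0.8, n_out)
        points = pd.DataFrame({"sdi": sdi, "value": value, "se": 0.02})
        res = fit_trimmed_spline(points, gamma=gamma)
        if set(np.nonzero(~res.inlier)[0]) == set(idx):
            hits += 1
    return {
        "success_rate_pct": 100.0 * hits / n_replicates,
        "n_replicates": n_replicates,
    }
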