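"""Nested-proportion raking and derived indicators at the draw level."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fpstgpr.consistency import (
    compute_demand_satisfied,
    compute_mcpr,
    compute_unmet,
    make_consistent,
    rake_methods_to_cpr,
)
from fpstgpr.methods import ALL_METHODS, MODERN_METHODS


def vec(**shares):
    out = np.zeros(14)
    for m, v in shares.items():
        out[ALL_METHODS.index(m)] = v
    return out


def test_raking_proportional_scaling():
    methods = vec(pill=0.2, condom=0.2)
    raked = rake_methods_to_cpr(methods, 0.5)
    assert raked[ALL_METHODS.index("pill")] == pytest.approx(0.25)
    assert raked[ALL_METHODS.index("condom")] == pytest.approx(0.25)
    assert raked.sum() == pytest.approx(0.5)


def test_raking_identity_when_consistent():
    methods = vec(pill=0.1, iud=0.2)
    raked = rake_methods_to_cpr(methods, 0.3)
    assert np.allclose(raked, methods)


def test_raking_hand_arithmetic():
    methods = vec(female_sterilisation=0.1, pill=0.3, condom=0.2)
    raked = rake_methods_to_cpr(methods, 0.3)
    assert raked[ALL_METHODS.index("female_sterilisation")] == pytest.approx(0.05)
    assert raked[ALL_METHODS.index("pill")] == pytest.approx(0.15)
    assert raked[ALL_METHODS.index("condom")] == pytest.approx(0.10)
    assert raked.sum() == pytest.approx(0.3, abs=1e-12)


def test_raking_zero_mass_spreads_uniformly():
    raked = rake_methods_to_cpr(np.zeros(14), 0.28)
    assert np.allclose(raked, 0.02)


def test_raking_rejects_bad_cpr():
    with pytest.raises(ValueError):
        rake_methods_to_cpr(vec(pill=0.1), 1.2)


def test_mcpr_sums_modern_only():
    assert compute_mcpr(vec(lam=0.1, rhythm=0.2)) == 0.0
    assert compute_mcpr(vec(pill=0.4)) == pytest.approx(0.4)
    raked = rake_methods_to_cpr(vec(female_sterilisation=0.1, pill=0.3, condom=0.2), 0.3)
    # all three raked methods are modern here; swap one to traditional
    raked2 = rake_methods_to_cpr(vec(female_sterilisation=0.1, pill=0.3, rhythm=0.2), 0.3)
    assert compute_mcpr(raked2) == pytest.approx(0.20)


@pytest.mark.parametrize(
    "share, cpr, expected",
    [(0.5, 0.6, 0.2), (0.0, 1.0, 0.0), (0.3, 0.25, 0.225)],
)
def test_unmet_need_identity(share, cpr, expected):
    assert compute_unmet(share, cpr) == pytest.approx(expected)


def test_demand_satisfied_printed_rows():
    # national worked examples at one decimal
    assert round(float(compute_demand_satisfied(0.879, 0.894, 0.012)) * 100, 1) == 97.0
    assert round(float(compute_demand_satisfied(0.820, 0.875, 0.035)) * 100, 1) == 90.1
    assert compute_demand_satisfied(0.0, 0.3, 0.1) == 0.0
    assert compute_demand_satisfied(0.0, 0.0, 0.0) == 0.0


def test_make_consistent_constant_draws_reduce_to_scalar_formulas():
    n_cells, n_draws = 2, 5
    cpr = np.full((n_cells, n_draws), 0.5)
    methods = np.zeros((14, n_cells, n_draws))
    methods[ALL_METHODS.index("pill")] = 0.2
    methods[ALL_METHODS.index("rhythm")] = 0.2
    need = np.full((n_cells, n_draws), 0.4)
    cons = make_consistent(cpr, methods, need)
    assert np.allclose(cons.methods.sum(axis=0), 0.5)
    assert np.allclose(cons.mcpr, 0.25)
    assert np.allclose(cons.unmet, 0.2)
    assert np.allclose(cons.demand_satisfied, 0.25 / 0.7)


def test_make_consistent_rejects_misaligned_draws():
    with pytest.raises(ValueError, match="misaligned"):
        make_consistent(np.zeros((2, 5)), np.zeros((14, 2, 4)), np.zeros((2, 5)))


def test_draw_permutation_leaves_summaries_unchanged():
    rng = np.random.default_rng(0)
    cpr = rng.uniform(0.2, 0.8, size=(3, 50))
    methods = rng.dirichlet(np.ones(14), size=(3, 50)).transpose(2, 0, 1) * cpr
    need = rng.uniform(0, 1, size=(3, 50))
    cons = make_consistent(cpr, methods, need)
    perm = rng.permutation(50)
    cons_p = make_consistent(cpr[:, perm], methods[:, :, perm], need[:, perm])
    for a, b in [(cons.mcpr, cons_p.mcpr), (cons.demand_satisfied, cons_p.demand_satisfied)]:
        assert np.allclose(np.sort(a, axis=1), np.sort(b, axis=1))
        assert np.allclose(a.mean(axis=1), b.mean(axis=1))


def test_derived_interval_differs_from_plugging_in_endpoints():
    """On skewed draws the demand-satisfied interval computed from derived
    draws is not the interval obtained by transforming the CPR bounds."""
    rng = np.random.default_rng(1)
    n = 2000
    cpr = np.clip(0.3 + 0.25 * rng.gamma(1.0, 1.0, size=(1, n)) / 3.0, 0.01, 0.95)
    methods = np.zeros((14, 1, n))
    methods[ALL_METHODS.index("pill")] = cpr * 0.9
    methods[ALL_METHODS.index("rhythm")] = cpr * 0.1
    # an independent, skewed need-share makes ds a genuinely multivariate draw
    need = np.clip(rng.beta(0.8, 4.0, size=(1, n)), 0.0, 1.0)
    cons = make_consistent(cpr, methods, need)
    lo_draw, hi_draw = np.quantile(cons.demand_satisfied, [0.025, 0.975])

    def ds_of(cpr_scalar, need_scalar):
        mcpr = 0.9 * cpr_scalar
        unmet = need_scalar * (1 - cpr_scalar)
        return mcpr / (cpr_scalar + unmet)

    # plugging the component interval endpoints into the formula is wrong
    lo_plug = ds_of(np.quantile(cpr, 0.025), np.quantile(need, 0.975))
    hi_plug = ds_of(np.quantile(cpr, 0.975), np.quantile(need, 0.025))
    assert abs(lo_draw - lo_plug) > 1e-3
    assert abs(hi_draw - hi_plug) > 1e-3


@settings(deadline=None, max_examples=25)
@given(st.integers(min_value=0, max_value=10_000))
def test_per_draw_conservation_and_nesting(seed):
    rng = np.random.default_rng(seed)
    n_cells, n_draws = 4, 40
    cpr = rng.uniform(0, 1, size=(n_cells, n_draws))
    raw = rng.uniform(0, 1, size=(14, n_cells, n_draws))
    need = rng.uniform(0, 1, size=(n_cells, n_draws))
    cons = make_consistent(cpr, raw, need)
    assert np.abs(cons.methods.sum(axis=0) - cons.cpr).max() < 1e-9
    assert (cons.mcpr <= cons.cpr + 1e-12).all()
    assert (cons.unmet >= -1e-12).all()
    assert (cons.cpr + cons.unmet <= 1 + 1e-12).all()
    ds = cons.demand_satisfied
    assert ((ds >= 0) & (ds <= 1 + 1e-12)).all()


def test_demand_satisfied_is_one_iff_no_unmet_and_all_modern():
    methods = np.zeros((14, 1, 1))
    methods[ALL_METHODS.index("iud")] = 0.4
    cons = make_consistent(np.full((1, 1), 0.4), methods, np.zeros((1, 1)))
    assert cons.demand_satisfied[0, 0] == pytest.approx(1.0)
    # traditional use keeps it below 1
    methods2 = np.zeros((14, 1, 1))
    methods2[ALL_METHODS.index("rhythm")] = 0.4
    cons2 = make_consistent(np.full((1, 1), 0.4), methods2, np.zeros((1, 1)))
    assert cons2.demand_satisfied[0, 0] == pytest.approx(0.0)


def test_method_mix_shares_of_use_sum_to_one():
    rng = np.random.default_rng(3)
    cpr = rng.uniform(0.1, 0.9, size=(5, 20))
    raw = rng.uniform(0, 1, size=(14, 5, 20))
    cons = make_consistent(cpr, raw, rng.uniform(0, 1, size=(5, 20)))
    mix = cons.method_mix()
    assert np.allclose(np.nansum(mix, axis=0), 1.0)
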