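"""Cohort engine: conservation, closed-form oracles, waning, cure, and
half-cycle accounting."""

import numpy as np
import pandas as pd
import pytest

from alkcea.inputs import default_inputs
from alkcea.markov import (SUBSTATES, CohortTrace, Lifetable,
                           background_mortality, build_cycle_transitions,
                           cure_fraction, effective_dfs_hazard, run_cohort)
from helpers import const_fit, flat_fits

I = {name: i for i, name in enumerate(SUBSTATES)}


def test_cure_fraction_ramp():
    tr = default_inputs().transitions
    assert cure_fraction(23, tr) == 0.0
    assert cure_fraction(120, tr) == 0.975
    assert cure_fraction(300, tr) == 0.975
    assert cure_fraction(72, tr) == pytest.approx((72 - 24) / 96 * 0.975)


def test_background_mortality_closed_form(lifetable):
    zero = Lifetable(pd.DataFrame({"age": np.arange(18, 101),
                                   "q_annual": np.zeros(83)}))
    assert background_mortality(56, 0, zero, cured=True) == 0.0
    q = pd.DataFrame({"age": np.arange(18, 101), "q_annual": np.full(83, 0.012)})
    lt = Lifetable(q)
    expect = 1 - 0.988 ** (1 / 12)
    assert background_mortality(56, 0, lt) == pytest.approx(expect, rel=1e-12)
    assert background_mortality(56, 0, lt, cured=True) == pytest.approx(
        1.25 * expect, rel=1e-12)
    ratio = (background_mortality(70, 30, lifetable, cured=True)
             / background_mortality(70, 30, lifetable, cured=False))
    assert ratio == pytest.approx(1.25, rel=1e-12)


def test_lifetable_terminal_row_warning(lifetable):
    with pytest.warns(UserWarning, match="terminal row"):
        q = lifetable.monthly_q(130.0)
    assert q == lifetable.monthly_q(100.0)


def test_effective_dfs_hazard_waning():
    tr = default_inputs().transitions
    ale, chemo = const_fit(0.01), const_fit(0.03)
    assert effective_dfs_hazard(12, "alectinib", ale, chemo, tr) == pytest.approx(0.01)
    assert effective_dfs_hazard(12, "chemotherapy", ale, chemo, tr) == pytest.approx(0.03)
    assert effective_dfs_hazard(60, "alectinib", ale, chemo, tr) == pytest.approx(0.03)
    assert effective_dfs_hazard(44, "alectinib", ale, chemo, tr) == pytest.approx(0.02)


def test_transition_matrix_identity_when_inert(zero_lifetable):
    """All hazards and fixed probabilities zero with a zero lifetable give
    the identity matrix."""
    mi = default_inputs()
    mi.transitions.p_nonmet_to_1l_active = 0.0
    mi.transitions.p_nonmet_death_supportive = 0.0
    mi.transitions.p_met_death_supportive = 0.0
    mi.transitions.cure_cap = 0.0
    M = build_cycle_transitions(0, "alectinib", flat_fits(), mi, zero_lifetable)
    np.testing.assert_allclose(M, np.eye(len(SUBSTATES)), atol=1e-15)


def test_supportive_geometric_decay(zero_lifetable):
    """Cohort seeded in supportive nonmetastatic care decays at the fixed
    monthly death probability."""
    mi = default_inputs()
    M = build_cycle_transitions(0, "alectinib", flat_fits(), mi, zero_lifetable)
    x = np.zeros(len(SUBSTATES))
    x[I["nonmet_supportive"]] = 1.0
    occ = [x[I["nonmet_supportive"]]]
    for _ in range(24):
        x = x @ M
        occ.append(x[I["nonmet_supportive"]])
    np.testing.assert_allclose(occ, (1 - 0.0762) ** np.arange(25), rtol=1e-12)


def test_row_sums_and_occupancy_conservation(ctx):
    """Every cycle's matrix rows and every occupancy row sum to one within
    1e-9 over the full 600-cycle horizon, for both arms."""
    for arm in ("alectinib", "chemotherapy"):
        for t in (0, 27, 44, 120, 599):
            M = build_cycle_transitions(t, arm, ctx.fits, ctx.inputs, ctx.lifetable)
            np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-9)
        tr = run_cohort(arm, ctx.fits, ctx.inputs, ctx.lifetable)
        assert tr.horizon == 600
        np.testing.assert_allclose(tr.occupancy.sum(axis=-1), 1.0, atol=1e-9)
        death = tr.occupancy[:, I["death"]]
        assert np.all(np.diff(death) >= -1e-12)
        # all alive states vanish as t -> infinity (<1% left at 50 years)
        assert tr.occupancy[-1, : I["death"]].sum() < 0.01
        assert np.all(tr.occupancy >= -1e-12)


def test_trace_matches_matrix_recursion_oracle(ctx):
    """The vectorized engine equals an independent hand-rolled recursion
    multiplying the per-cycle transition matrices."""
    tr = run_cohort("alectinib", ctx.fits, ctx.inputs, ctx.lifetable,
                    horizon_months=600)
    x = np.zeros(len(SUBSTATES))
    x[I["dfs_at_risk"]] = 1.0
    for t in range(600):
        M = build_cycle_transitions(t, "alectinib", ctx.fits, ctx.inputs,
                                    ctx.lifetable)
        x = x @ M
        np.testing.assert_allclose(tr.occupancy[t + 1], x, atol=1e-9)


def test_reduced_three_state_closed_form(zero_lifetable):
    """DFS -> supportive metastatic -> death with constant probabilities
    matches the closed-form geometric solution to 1e-10."""
    mi = default_inputs()
    mi.transitions.distant_prop = {"alectinib": 1.0, "chemotherapy": 1.0}
    mi.transitions.active_props = (0.0, 0.0, 0.0)
    mi.transitions.cure_cap = 0.0
    h = 0.04
    fits = flat_fits() | {"dfs_alectinib": const_fit(h),
                          "dfs_chemotherapy": const_fit(h)}
    tr = run_cohort("chemotherapy", fits, mi, zero_lifetable, horizon_months=600)
    p = 1 - np.exp(-h)
    q = mi.transitions.p_met_death_supportive
    t = np.arange(601)
    dfs = (1 - p) ** t
    supp = p * ((1 - p) ** t - (1 - q) ** t) / (q - p)
    np.testing.assert_allclose(tr.occupancy[:, I["dfs_at_risk"]], dfs, atol=1e-10)
    np.testing.assert_allclose(tr.occupancy[:, I["met1l_supportive"]], supp,
                               atol=1e-10)
    np.testing.assert_allclose(tr.occupancy[:, I["death"]],
                               1 - dfs - supp, atol=1e-10)


def test_arm_symmetry(ctx):
    """Equal DFS curves and distant proportions give identical traces for
    both strategies."""
    mi = ctx.inputs.copy()
    mi.transitions.distant_prop = {"alectinib": 0.45, "chemotherapy": 0.45}
    fits = dict(ctx.fits)
    fits["dfs_alectinib"] = fits["dfs_chemotherapy"]
    a = run_cohort("alectinib", fits, mi, ctx.lifetable, horizon_months=240)
    c = run_cohort("chemotherapy", fits, mi, ctx.lifetable, horizon_months=240)
    np.testing.assert_allclose(a.occupancy, c.occupancy, atol=1e-12)


def test_cured_share_follows_ramp(zero_lifetable):
    """With no DFS exits and no mortality, the cured share of the DFS
    cohort tracks the cure ramp exactly."""
    mi = default_inputs()
    tr = run_cohort("alectinib", flat_fits(), mi, zero_lifetable,
                    horizon_months=200)
    for t in (12, 24, 72, 120, 199):
        assert tr.occupancy[t, I["dfs_cured"]] == pytest.approx(
            cure_fraction(t, mi.transitions), abs=1e-12)


def test_horizon_one_inert_cohort(zero_lifetable):
    mi = default_inputs()
    mi.transitions.cure_cap = 0.0
    tr = run_cohort("alectinib", flat_fits(), mi, zero_lifetable,
                    horizon_months=1)
    ly = tr.life_years()
    assert ly["dfs"] == pytest.approx(1 / 12)
    assert sum(v for k, v in ly.items() if k != "death") <= 1 / 12 + 1e-12


def test_total_lys_bounded_by_horizon(ctx):
    tr = run_cohort("alectinib", ctx.fits, ctx.inputs, ctx.lifetable,
                    horizon_months=120)
    total = sum(v for k, v in tr.life_years().items() if k != "death")
    assert total <= 10.0 + 1e-9


def test_half_cycle_between_endpoint_accumulations(ctx):
    tr = run_cohort("alectinib", ctx.fits, ctx.inputs, ctx.lifetable,
                    horizon_months=240)
    alive = 1 - tr.collapse()[:, -1]
    start_sum = alive[:-1].sum() / 12
    end_sum = alive[1:].sum() / 12
    corrected = sum(v for k, v in tr.life_years().items() if k != "death")
    assert end_sum < corrected < start_sum


def test_dfs_dominance_of_alectinib(ctx, base_pair):
    """Alectinib's share of life-years spent disease-free substantially
    exceeds chemotherapy's under trial-like inputs."""
    from alkcea.economics import dfs_ly_share
    a, c = base_pair
    assert dfs_ly_share(a) > dfs_ly_share(c) + 10.0


def test_run_cohort_validation(ctx):
    with pytest.raises(ValueError, match="arm"):
        run_cohort("placebo", ctx.fits, ctx.inputs, ctx.lifetable)
    with pytest.raises(ValueError, match="horizon"):
        run_cohort("alectinib", ctx.fits, ctx.inputs, ctx.lifetable,
                   horizon_months=0)
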