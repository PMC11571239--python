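"""Uncertainty machinery: DSA, PSA samplers and reproducibility, CEAC,
and scenario analyses."""

import numpy as np
import pandas as pd
import pytest

from alkcea.economics import icer
from alkcea.inputs import ParamSpec, default_param_specs
from alkcea.sensitivity import (WTP_1X_GDP, WTP_3X_GDP, ceac,
                                default_wtp_grid, fit_psa_distribution,
                                run_dsa, run_psa, run_scenarios)


@pytest.fixture(scope="module")
def specs(ctx):
    return default_param_specs(ctx.inputs)


def test_paramspec_validation_and_apply(ctx):
    with pytest.raises(ValueError, match="bracket"):
        ParamSpec("bad", 1.0, 2.0, 3.0, "GAMMA", "costs.end_of_life")
    with pytest.raises(ValueError, match="distribution"):
        ParamSpec("bad", 1.0, 0.0, 2.0, "NORMAL", "costs.end_of_life")
    mi = ctx.inputs.copy()
    ParamSpec("eol", 1967.49, 764.34, 5254.75, "GAMMA",
              "costs.end_of_life").apply(mi, 1000.0)
    assert mi.costs.end_of_life == 1000.0
    ParamSpec("dp", 0.357, 0.2, 0.5, "BETA",
              "transitions.distant_prop[alectinib]").apply(mi, 0.4)
    assert mi.transitions.distant_prop["alectinib"] == 0.4
    blend = ParamSpec("1l", 1855.02, 1484.01, 2226.02, "GAMMA",
                      "costs.met1l_blend")
    blend.apply(mi, 2 * 1855.02)
    assert mi.costs.met1l_blend == pytest.approx(2 * 1855.02)


def test_psa_distribution_method_of_moments():
    """Gamma parameters follow mean = base, SD = (high-low)/3.92 on the
    published chemotherapy-cost row."""
    spec = ParamSpec("chemo", 412.87, 245.49, 691.93, "GAMMA",
                     "costs.chemo_dfs_per_21d")
    smp = fit_psa_distribution(spec)
    sd = (691.93 - 245.49) / 3.92
    assert smp.a == pytest.approx(412.87**2 / sd**2)
    assert smp.b == pytest.approx(sd**2 / 412.87)
    v = smp.draw(np.random.default_rng(0), 50000)
    assert v.mean() == pytest.approx(412.87, rel=0.02)
    assert v.std() == pytest.approx(sd, rel=0.05)


def test_psa_distribution_beta_support_and_degenerate():
    spec = ParamSpec("u", 0.845, 0.820, 0.870, "BETA",
                     "utilities.dfs_on_treatment")
    v = fit_psa_distribution(spec).draw(np.random.default_rng(1), 20000)
    assert np.all((v > 0) & (v < 1))
    with pytest.warns(UserWarning, match="degenerate"):
        smp = fit_psa_distribution(
            ParamSpec("d", 0.5, 0.5, 0.5, "BETA", "utilities.dfs_on_treatment"))
    assert smp.kind == "constant"
    assert fit_psa_distribution(
        ParamSpec("c", 0.05, 0.0, 0.08, "CONSTANT", "discount.cost_rate")
    ).kind == "constant"


def test_psa_sampled_means_match_base(specs):
    """Empirical mean of every sampled parameter lies within 3 standard
    errors of its published base value at n = 5000."""
    rng = np.random.default_rng(99)
    for spec in specs:
        smp = fit_psa_distribution(spec)
        if smp.kind == "constant":
            continue
        v = smp.draw(rng, 5000)
        se = v.std(ddof=1) / np.sqrt(5000)
        assert abs(v.mean() - spec.base) <= 3 * se, spec.name


def test_psa_seed_reproducibility(ctx, specs):
    a = run_psa(40, seed=7, specs=specs, ctx=ctx)
    b = run_psa(40, seed=7, specs=specs, ctx=ctx)
    pd.testing.assert_frame_equal(a, b)
    c = run_psa(40, seed=8, specs=specs, ctx=ctx)
    assert not np.array_equal(a["delta_cost"], c["delta_cost"])


def test_psa_matches_scalar_rerun(ctx, specs):
    """The vectorized PSA equals re-running the model one draw at a time."""
    draws = run_psa(3, seed=5, specs=specs, ctx=ctx)
    for _, row in draws.iterrows():
        mi = ctx.inputs.copy()
        for s in specs:
            s.apply(mi, float(row[s.name]))
        a, c = ctx.run_pair(mi)
        assert a.total_cost == pytest.approx(row["cost_alectinib"], rel=1e-9)
        assert c.total_qaly == pytest.approx(row["qaly_chemotherapy"], rel=1e-9)


def test_psa_survival_uncertainty_mode(ctx, specs):
    from alkcea.pipeline import fit_from_params

    fits = dict(ctx.fits)
    # attach a tiny coefficient covariance to one curve
    fits["os_subsequent"].vcov = np.diag([1e-4, 1e-4])
    try:
        draws = run_psa(4, seed=3, specs=specs[:2], ctx=ctx,
                        survival_uncertainty=True)
        assert len(draws) == 4
        assert draws["delta_qaly"].std() > 0
    finally:
        fits["os_subsequent"].vcov = None


def test_ceac_limits_and_monotonicity():
    rng = np.random.default_rng(2)
    draws = pd.DataFrame({
        "delta_cost": rng.normal(16000, 4000, 400).clip(min=1.0),
        "delta_qaly": rng.normal(1.8, 0.3, 400).clip(min=0.01),
    })
    curve = ceac(draws, np.arange(0, 60001, 500))
    assert curve["probability"].iloc[0] == 0.0          # lambda=0, all dC>0
    assert curve["probability"].iloc[-1] > 0.99          # lambda -> infinity
    assert (np.diff(curve["probability"]) >= 0).all()    # all dQALY > 0
    with pytest.raises(ValueError):
        ceac(draws.iloc[:0])


def test_ceac_degenerate_is_step_at_base_icer():
    """With every parameter constant, the CEAC is the indicator that the
    threshold exceeds the base-case ICER."""
    draws = pd.DataFrame({"delta_cost": [9000.0] * 10,
                          "delta_qaly": [1.0] * 10})
    grid = np.arange(0, 20001, 250)
    curve = ceac(draws, grid)
    np.testing.assert_allclose(curve["probability"],
                               (grid > 9000).astype(float))


def test_wtp_grid_contains_thresholds():
    grid = default_wtp_grid()
    assert WTP_1X_GDP in grid and WTP_3X_GDP in grid
    assert grid[0] == 0.0 and grid[-1] == 50000.0


def test_dsa_degenerate_bounds_return_base(ctx):
    spec = ParamSpec("fixed", 24.42, 24.42, 24.42, "GAMMA",
                     "costs.followup_0_5y")
    tab = run_dsa([spec], ctx)
    assert tab["width"].iloc[0] == 0.0
    assert tab["icer_low"].iloc[0] == tab["base_icer"].iloc[0]


def test_dsa_chemo_cost_direction(ctx):
    """Raising a chemotherapy-arm-only cost reduces the incremental cost of
    alectinib (sign argument, checked numerically)."""
    base_a, base_c = ctx.run_pair()
    base = icer(base_a, base_c)
    mi = ctx.inputs.copy()
    mi.costs.met_subsequent["chemotherapy"] *= 2
    a, c = ctx.run_pair(mi)
    bumped = icer(a, c)
    assert bumped["delta_cost"] < base["delta_cost"]
    assert bumped["delta_qaly"] == pytest.approx(base["delta_qaly"])


def test_dsa_table_shape_and_ranking(ctx, specs):
    tab = run_dsa(specs[:6], ctx)
    assert set(tab.columns) >= {"parameter", "icer_low", "icer_high", "width"}
    w = tab["width"].to_numpy()
    w = w[np.isfinite(w)]
    assert (np.diff(w) <= 1e-9).all()


def test_scenarios_identities_and_horizon_ordering(ctx):
    tab = run_scenarios(ctx).set_index("scenario")
    base = tab.loc["base_case"]
    # scenario 3 with the base proportions reproduces the base case
    mi = ctx.inputs.copy()
    mi.transitions.active_props = (0.839, 0.909, 0.875)
    a, c = ctx.run_pair(mi)
    r = icer(a, c)
    assert r["delta_qaly"] == pytest.approx(base["delta_qaly"], rel=1e-12)
    # scenario 2 at the lifetime horizon reproduces the base case exactly
    a, c = ctx.run_pair(horizon_months=ctx.inputs.horizon_months)
    r = icer(a, c)
    assert r["delta_cost"] == pytest.approx(base["delta_cost"], rel=1e-12)
    # ICERs fall monotonically as the horizon lengthens
    icers = [tab.loc[f"scenario2_horizon_{y}y", "icer_per_qaly"]
             for y in (10, 20, 30)] + [base["icer_per_qaly"]]
    assert all(x > y for x, y in zip(icers, icers[1:]))
    # scenario 1: dearer single-drug 1L lowers incremental cost, and the
    # cheaper one raises it
    assert tab.loc["scenario1_1l_lorlatinib", "delta_cost"] < base["delta_cost"]
    assert tab.loc["scenario1_1l_alectinib", "delta_cost"] > base["delta_cost"]
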