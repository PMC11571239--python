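"""Economic accumulation: discounted costs, life-years, QALYs, and ICERs.

Costs and outcomes are accrued per monthly cycle on the half-cycle-corrected
occupancy (mean of cycle-start and cycle-end), discounted at mid-cycle.
Adjuvant drug exposure is time-limited: alectinib is costed for its first
24 model months; the four 21-day chemotherapy cycles (84 days) are prorated
by calendar days onto the first three model months, with intravenous
administration fees accruing only on chemotherapy days.  Severe
adverse-event costs and disutilities enter in the first treatment cycle
as expectations (risk x cost / risk x disutility for one month).
End-of-life cost attaches to deaths leaving the recurrence states through
disease pathways, not to background deaths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inputs import (DAYS_PER_MONTH, CostInputs, DiscountSpec, ModelInputs,
                     UtilityInputs)
from .markov import REPORTED_STATES, STATE_OF_SUBSTATE, SUBSTATES, CohortTrace

__all__ = [
    "discount_factor",
    "chemo_days_in_cycle",
    "cycle_cost",
    "cycle_utility",
    "end_of_life_cost",
    "aggregate",
    "icer",
    "dfs_ly_share",
    "CEAResult",
    "units_required",
]

_IDX = {name: i for i, name in enumerate(SUBSTATES)}


def discount_factor(t_months, annual_rate, mid_cycle: bool = True):
    """(1 + r)^(-t/12); with ``mid_cycle`` the factor is evaluated at
    t + 0.5 months for consistency with half-cycle-corrected occupancy."""
    t = np.asarray(t_months, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if mid_cycle:
        t = t + 0.5
    return (1.0 + annual_rate) ** (-t / 12.0)


def chemo_days_in_cycle(t: int, costs: CostInputs) -> float:
    """Calendar days of the 21-day chemotherapy course falling in model
    cycle t (cycles are DAYS_PER_MONTH days long)."""
    total_days = costs.chemo_n_cycles * 21.0
    lo, hi = t * DAYS_PER_MONTH, (t + 1) * DAYS_PER_MONTH
    return max(0.0, min(hi, total_days) - lo)


def cycle_cost(substate: str, t: int, arm: str, costs: CostInputs):
    """Per-person cost of occupying ``substate`` during cycle t (USD).

    DFS (at-risk or cured) carries the follow-up tier plus adjuvant drug
    and administration while on treatment; active recurrence substates
    carry their regimen's treatment cost; supportive substates carry
    follow-up only.  Adverse-event costs are handled separately in
    :func:`aggregate` (first cycle only).
    """
    if substate not in SUBSTATES:
        raise ValueError(f"unknown substate {substate!r}")
    if substate == "death":
        return 0.0
    followup = costs.followup_0_5y if t < 60 else costs.followup_post5y
    if substate in ("dfs_at_risk", "dfs_cured"):
        if arm == "alectinib":
            drug = (costs.alectinib_dfs_monthly
                    if t < costs.alectinib_duration_months else 0.0)
        else:
            days = chemo_days_in_cycle(t, costs)
            drug = days * (costs.chemo_dfs_per_21d
                           + costs.administration_per_21d) / 21.0
        return followup + drug
    if substate == "nonmet_active":
        return costs.nonmet_treatment[arm]
    if substate == "met1l_active_lorlatinib":
        return costs.met1l_lorlatinib
    if substate == "met1l_active_alectinib":
        return costs.met1l_alectinib
    if substate in ("met2l_active_alectinib", "met2l_active_brigatinib",
                    "met2l_active_chemo_bev"):
        return costs.met_subsequent[arm]
    # supportive substates
    return followup


def _on_adjuvant_treatment(t: int, arm: str, costs: CostInputs) -> bool:
    if arm == "alectinib":
        return t < costs.alectinib_duration_months
    return chemo_days_in_cycle(t, costs) > 0


def cycle_utility(substate: str, t: int, arm: str,
                  utilities: UtilityInputs, costs: CostInputs):
    """Annual utility weight for ``substate`` at cycle t.  DFS uses the
    on-treatment utility while adjuvant therapy is given and the
    off-treatment utility afterwards."""
    if substate not in SUBSTATES:
        raise ValueError(f"unknown substate {substate!r}")
    if substate == "death":
        return 0.0
    if substate in ("dfs_at_risk", "dfs_cured"):
        return (utilities.dfs_on_treatment
                if _on_adjuvant_treatment(t, arm, costs)
                else utilities.dfs_off_treatment)
    state = STATE_OF_SUBSTATE[substate]
    return {"nonmetastatic": utilities.nonmetastatic,
            "metastatic_1l": utilities.metastatic_1l,
            "metastatic_subsequent": utilities.metastatic_subsequent}[state]


def end_of_life_cost(new_disease_deaths, costs: CostInputs):
    """Undiscounted end-of-life cost for one cycle's disease-state deaths."""
    return costs.end_of_life * np.asarray(new_disease_deaths, dtype=float)


@dataclass
class CEAResult:
    """Machine-readable base-case table for one strategy."""

    arm: str
    ly: dict = field(default_factory=dict)      # per reported alive state
    qaly: dict = field(default_factory=dict)
    cost: dict = field(default_factory=dict)    # includes 'end_of_life'
    total_ly: float = 0.0
    total_qaly: float = 0.0
    total_cost: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in REPORTED_STATES[:-1]:
            rows.append({"state": s, "ly": self.ly[s], "qaly": self.qaly[s],
                         "cost": self.cost[s]})
        rows.append({"state": "end_of_life", "ly": 0.0, "qaly": 0.0,
                     "cost": self.cost["end_of_life"]})
        rows.append({"state": "total", "ly": self.total_ly,
                     "qaly": self.total_qaly, "cost": self.total_cost})
        return pd.DataFrame(rows)


def aggregate(trace: CohortTrace, costs: CostInputs, utilities: UtilityInputs,
              discount: DiscountSpec, arm: str | None = None) -> CEAResult:
    """Accumulate discounted LYs, QALYs and costs over a cohort trace.

    Cost and utility inputs may hold numpy arrays (probabilistic draws)
    broadcastable against the trace's draw axes.
    """
    arm = trace.arm if arm is None else arm
    horizon = trace.horizon
    mid = trace.mid_cycle()                       # (H, ..., n_sub)
    t = np.arange(horizon)

    draw_shape = np.broadcast_shapes(
        mid.shape[1:-1],
        np.shape(np.asarray(costs.followup_0_5y)),
        np.shape(np.asarray(utilities.dfs_off_treatment)),
        np.shape(np.asarray(discount.cost_rate)),
    )
    state_ly = {s: np.zeros(draw_shape) for s in REPORTED_STATES[:-1]}
    state_qaly = {s: np.zeros(draw_shape) for s in REPORTED_STATES[:-1]}
    state_cost = {s: np.zeros(draw_shape) for s in REPORTED_STATES[:-1]}

    t_col = t.reshape((horizon,) + (1,) * len(draw_shape))
    df_c = discount_factor(t_col, np.asarray(discount.cost_rate, dtype=float))
    df_o = discount_factor(t_col, np.asarray(discount.outcome_rate, dtype=float))
    df_c = np.broadcast_to(df_c, (horizon,) + draw_shape)
    df_o = np.broadcast_to(df_o, (horizon,) + draw_shape)

    for i, sub in enumerate(SUBSTATES):
        if sub == "death":
            continue
        state = STATE_OF_SUBSTATE[sub]
        occ = mid[..., i]                          # (H, ...)
        # costs and utilities vary only through the two follow-up tiers and
        # the adjuvant-treatment window; build per-cycle vectors
        cvec = np.stack([np.broadcast_to(
            np.asarray(cycle_cost(sub, int(tt), arm, costs), dtype=float),
            draw_shape) for tt in t])
        uvec = np.stack([np.broadcast_to(
            np.asarray(cycle_utility(sub, int(tt), arm, utilities, costs),
                       dtype=float), draw_shape) for tt in t])
        state_ly[state] = state_ly[state] + (df_o * occ).sum(axis=0) / 12.0
        state_qaly[state] = state_qaly[state] + (df_o * occ * uvec).sum(axis=0) / 12.0
        state_cost[state] = state_cost[state] + (df_c * occ * cvec).sum(axis=0)

    # adverse events: expectation applied once at the first treatment cycle
    ae_cost = np.asarray(costs.ae_risk[arm], dtype=float) * np.asarray(
        costs.ae_cost[arm], dtype=float)
    ae_dis = (np.asarray(costs.ae_risk[arm], dtype=float)
              * np.asarray(utilities.ae_disutility[arm], dtype=float) / 12.0)
    state_cost["dfs"] = state_cost["dfs"] + ae_cost * df_c[0]
    state_qaly["dfs"] = np.maximum(state_qaly["dfs"] - ae_dis * df_o[0], 0.0)

    eol = (df_c * end_of_life_cost(trace.disease_deaths, costs)).sum(axis=0)

    res = CEAResult(arm=arm)
    res.ly = {s: _maybe_scalar(v) for s, v in state_ly.items()}
    res.qaly = {s: _maybe_scalar(v) for s, v in state_qaly.items()}
    res.cost = {s: _maybe_scalar(v) for s, v in state_cost.items()}
    res.cost["end_of_life"] = _maybe_scalar(eol)
    res.total_ly = _maybe_scalar(sum(state_ly.values()))
    res.total_qaly = _maybe_scalar(sum(state_qaly.values()))
    res.total_cost = _maybe_scalar(sum(state_cost.values()) + eol)
    return res


def _maybe_scalar(x):
    x = np.asarray(x)
    return float(x) if x.shape == () else x


def icer(result_a: CEAResult, result_b: CEAResult) -> dict:
    """Incremental cost-effectiveness of strategy a versus strategy b.

    Returns increments plus per-LY and per-QALY ratios; dominance
    (more effect, less cost) and domination are flagged instead of a ratio.
    """
    d_cost = np.asarray(result_a.total_cost) - np.asarray(result_b.total_cost)
    d_ly = np.asarray(result_a.total_ly) - np.asarray(result_b.total_ly)
    d_qaly = np.asarray(result_a.total_qaly) - np.asarray(result_b.total_qaly)

    def ratio(dc, de):
        dc, de = np.asarray(dc, dtype=float), np.asarray(de, dtype=float)
        out = np.full(np.broadcast_shapes(dc.shape, de.shape), np.nan)
        ok = np.abs(de) > 1e-9
        out[ok] = (dc / np.where(ok, de, 1.0))[ok]
        return _maybe_scalar(out)

    out = {
        "delta_cost": _maybe_scalar(d_cost),
        "delta_ly": _maybe_scalar(d_ly),
        "delta_qaly": _maybe_scalar(d_qaly),
        "icer_per_ly": ratio(d_cost, d_ly),
        "icer_per_qaly": ratio(d_cost, d_qaly),
        "dominant": _maybe_scalar((d_qaly > 0) & (d_cost < 0)),
        "dominated": _maybe_scalar((d_qaly < 0) & (d_cost > 0)),
        "undefined": _maybe_scalar(np.abs(d_qaly) <= 1e-9),
    }
    return out


def dfs_ly_share(result: CEAResult) -> float:
    """Proportion of a strategy's life-years spent disease-free (%)."""
    return 100.0 * np.asarray(result.ly["dfs"]) / np.asarray(result.total_ly)


def units_required(dose_mg: float, unit_mg: float) -> int:
    """Whole drug units needed for one administration (vial/capsule
    rounding: unused remainder is wasted)."""
    if unit_mg <= 0:
        raise ValueError("unit size must be positive")
    return int(np.ceil(dose_mg / unit_mg - 1e-12))
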