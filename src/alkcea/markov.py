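"""Five-state monthly Markov cohort model with expanded substates.

Reported health states: disease-free survival (DFS), nonmetastatic
recurrence, first-line (1L) metastatic recurrence, subsequent-line
metastatic recurrence, and death.  The engine tracks an expanded substate
space: DFS splits into at-risk and cured; recurrence states split into
active-treatment regimens and supportive care.  Cycle length is one month;
the cohort starts 100% in DFS at-risk.

Within-cycle order of operations (fixed convention): age-specific
background mortality is applied to every alive substate first (cured
patients at the excess-mortality multiplier), disease transitions are then
applied to the survivors, and finally the incremental cure flow moves DFS
at-risk survivors into the cured substate so that the cumulative cured
share follows the cure ramp.  Rows of every cycle's transition matrix sum
to one by construction.

Treatment-effect waning: the alectinib arm's DFS exit hazard equals the
fitted alectinib hazard before the waning window, blends linearly into the
chemotherapy hazard across the window, and equals the chemotherapy hazard
after it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inputs import ModelInputs, TransitionInputs
from .survival import SurvivalFit

__all__ = [
    "SUBSTATES",
    "REPORTED_STATES",
    "STATE_OF_SUBSTATE",
    "Lifetable",
    "cure_fraction",
    "effective_dfs_hazard",
    "background_mortality",
    "build_cycle_transitions",
    "run_cohort",
    "CohortTrace",
]

SUBSTATES = (
    "dfs_at_risk",
    "dfs_cured",
    "nonmet_active",
    "nonmet_supportive",
    "met1l_active_lorlatinib",
    "met1l_active_alectinib",
    "met1l_supportive",
    "met2l_active_alectinib",
    "met2l_active_brigatinib",
    "met2l_active_chemo_bev",
    "met2l_supportive",
    "death",
)

REPORTED_STATES = ("dfs", "nonmetastatic", "metastatic_1l",
                   "metastatic_subsequent", "death")

STATE_OF_SUBSTATE = {
    "dfs_at_risk": "dfs",
    "dfs_cured": "dfs",
    "nonmet_active": "nonmetastatic",
    "nonmet_supportive": "nonmetastatic",
    "met1l_active_lorlatinib": "metastatic_1l",
    "met1l_active_alectinib": "metastatic_1l",
    "met1l_supportive": "metastatic_1l",
    "met2l_active_alectinib": "metastatic_subsequent",
    "met2l_active_brigatinib": "metastatic_subsequent",
    "met2l_active_chemo_bev": "metastatic_subsequent",
    "met2l_supportive": "metastatic_subsequent",
    "death": "death",
}

_IDX = {name: i for i, name in enumerate(SUBSTATES)}
N_SUB = len(SUBSTATES)


class Lifetable:
    """Age-indexed annual background mortality, converted to monthly."""

    def __init__(self, df: pd.DataFrame):
        df = pd.DataFrame(df, columns=["age", "q_annual"]).astype(float)
        if df["age"].min() > 18 or df["age"].max() < 100:
            raise ValueError("lifetable must cover ages 18-100")
        if ((df["q_annual"] < 0) | (df["q_annual"] > 1)).any():
            raise ValueError("annual mortality must lie in [0,1]")
        self.df = df.sort_values("age").reset_index(drop=True)
        self._ages = self.df["age"].to_numpy()
        self._q = self.df["q_annual"].to_numpy()
        self._warned = False

    @classmethod
    def from_csv(cls, path) -> "Lifetable":
        return cls(pd.read_csv(path))

    def annual_q(self, age: float) -> float:
        if age > self._ages[-1] + 1:
            if not self._warned:
                warnings.warn("age beyond lifetable: using terminal row")
                self._warned = True
            return float(self._q[-1])
        i = np.searchsorted(self._ages, age, side="right") - 1
        i = int(np.clip(i, 0, len(self._ages) - 1))
        return float(self._q[i])

    def monthly_q(self, age: float) -> float:
        return 1.0 - (1.0 - self.annual_q(age)) ** (1.0 / 12.0)


def cure_fraction(t: float, inputs: TransitionInputs) -> float:
    """Cumulative cured share of DFS occupants at month t: zero before the
    cure start, a linear ramp to the cap at the cure end, constant after."""
    if t < inputs.cure_start:
        return 0.0
    if t >= inputs.cure_end:
        return inputs.cure_cap
    return inputs.cure_cap * (t - inputs.cure_start) / (inputs.cure_end - inputs.cure_start)


def _monthly_integrated_hazard(fit: SurvivalFit, t: float) -> float:
    """-ln(S(t+1)/S(t)): the hazard integrated over one monthly cycle."""
    s0 = fit.survival(float(t))
    s1 = fit.survival(float(t) + 1.0)
    if s0 <= 0:
        return np.inf
    h = -np.log(max(s1, 1e-300) / s0)
    if h < -1e-9:
        raise ValueError(f"negative hazard from extrapolated fit at t={t}")
    return max(h, 0.0)


def effective_dfs_hazard(t: float, arm: str, fit_ale: SurvivalFit,
                         fit_chemo: SurvivalFit,
                         inputs: TransitionInputs) -> float:
    """Monthly DFS exit hazard with linear treatment-effect waning.

    The chemotherapy arm always uses its own fitted hazard.  The alectinib
    arm uses its fitted hazard before ``waning_start``, the chemotherapy
    hazard from ``waning_end`` on, and the linear blend
    w(t) h_chemo + (1-w) h_ale with w = (t - start)/(end - start) between.
    """
    h_chemo = _monthly_integrated_hazard(fit_chemo, t)
    if arm == "chemotherapy":
        return h_chemo
    if arm != "alectinib":
        raise ValueError(f"unknown arm {arm!r}")
    h_ale = _monthly_integrated_hazard(fit_ale, t)
    if t < inputs.waning_start:
        return h_ale
    if t >= inputs.waning_end:
        return h_chemo
    w = (t - inputs.waning_start) / (inputs.waning_end - inputs.waning_start)
    return w * h_chemo + (1 - w) * h_ale


def background_mortality(age_years: float, t: float, lifetable: Lifetable,
                         cured: bool = False,
                         multiplier: float = 1.25) -> float:
    """Monthly background death probability at attained age; cured patients
    carry the excess-mortality multiplier.  Capped at 1."""
    q_m = lifetable.monthly_q(age_years + t / 12.0)
    if cured:
        q_m *= multiplier
    return min(q_m, 1.0)


# ---------------------------------------------------------------------------
# transition construction
# ---------------------------------------------------------------------------

def _precompute_curves(arm, fits, inputs: ModelInputs, lifetable, start_age,
                       horizon):
    """Vectors over cycles t = 0..horizon-1 of every curve-driven and
    age-driven probability; shared across DSA/PSA re-runs of one context."""
    tr = inputs.transitions
    t = np.arange(horizon, dtype=float)

    def _monthly_h(fit):
        s0 = fit.survival(t)
        s1 = fit.survival(t + 1.0)
        with np.errstate(divide="ignore"):
            h = -np.log(np.maximum(s1, 1e-300) / np.maximum(s0, 1e-300))
        h = np.where(s0 <= 0, np.inf, h)
        if np.any(h < -1e-9):
            raise ValueError("negative hazard from extrapolated fit")
        return np.maximum(h, 0.0)

    h_chemo = _monthly_h(fits["dfs_chemotherapy"])
    if arm == "chemotherapy":
        h_eff = h_chemo
    else:
        h_ale = _monthly_h(fits["dfs_alectinib"])
        w = np.clip((t - tr.waning_start) / (tr.waning_end - tr.waning_start),
                    0.0, 1.0)
        h_eff = w * h_chemo + (1 - w) * h_ale
    p_exit = 1.0 - np.exp(-h_eff)

    q_bg = np.array([lifetable.monthly_q(start_age + tt / 12.0) for tt in t])
    q_cured = np.minimum(q_bg * tr.excess_mortality_multiplier, 1.0)

    c = np.array([cure_fraction(tt, tr) for tt in np.arange(horizon + 1)])
    with np.errstate(invalid="ignore"):
        phi = np.where(c[:-1] >= 1, 0.0,
                       np.maximum(0.0, (c[1:] - c[:-1]) / (1.0 - c[:-1])))

    def _ratio(fit):
        s0 = fit.survival(t)
        s1 = fit.survival(t + 1.0)
        return np.where(s0 > 0, s1 / np.maximum(s0, 1e-300), 0.0)

    r_lor = _ratio(fits["pfs_lorlatinib"])
    r_ale1 = _ratio(fits["pfs_alectinib_1l"])
    r_2l = _ratio(fits["os_subsequent"])
    return dict(
        p_exit=np.clip(p_exit, 0, 1),
        q_bg=q_bg, q_cured=q_cured, phi=phi,
        p_lor=np.clip(1 - r_lor, 0, 1),
        p_ale1=np.clip(1 - r_ale1, 0, 1),
        p_2l={
            "alectinib": np.clip(1 - r_2l, 0, 1),
            "brigatinib": np.clip(1 - r_2l**tr.hr_2l_brigatinib, 0, 1),
            "chemo_bev": np.clip(1 - r_2l**tr.hr_2l_chemo_bev, 0, 1),
        },
    )


def _cycle_probs(t, arm, fits, inputs: ModelInputs, lifetable, start_age):
    """All scalar/vector probabilities needed for cycle t -> t+1."""
    tr = inputs.transitions
    h = effective_dfs_hazard(t, arm, fits["dfs_alectinib"],
                             fits["dfs_chemotherapy"], tr)
    p_exit = 1.0 - np.exp(-h)
    q_bg = background_mortality(start_age, t, lifetable, cured=False)
    q_cured = background_mortality(start_age, t, lifetable, cured=True,
                                   multiplier=tr.excess_mortality_multiplier)
    c_now = cure_fraction(t, tr)
    c_next = cure_fraction(t + 1, tr)
    phi = 0.0 if c_now >= 1 else max(0.0, (c_next - c_now) / (1.0 - c_now))

    from .survival import monthly_transition_prob

    p_lor = monthly_transition_prob(fits["pfs_lorlatinib"], float(t))
    p_ale1 = monthly_transition_prob(fits["pfs_alectinib_1l"], float(t))
    s2_0 = fits["os_subsequent"].survival(float(t))
    s2_1 = fits["os_subsequent"].survival(float(t) + 1.0)
    ratio = s2_1 / s2_0 if s2_0 > 0 else 0.0
    p_2l = {
        "alectinib": 1.0 - ratio,
        "brigatinib": 1.0 - ratio ** tr.hr_2l_brigatinib,
        "chemo_bev": 1.0 - ratio ** tr.hr_2l_chemo_bev,
    }
    return dict(p_exit=p_exit, q_bg=q_bg, q_cured=q_cured, phi=phi,
                p_lor=p_lor, p_ale1=p_ale1, p_2l=p_2l)


def build_cycle_transitions(t, arm, fits, inputs: ModelInputs,
                            lifetable: Lifetable,
                            start_age: float | None = None) -> np.ndarray:
    """Row-stochastic transition matrix over the expanded substates for the
    cycle starting at month t."""
    start_age = inputs.start_age if start_age is None else start_age
    pr = _cycle_probs(t, arm, fits, inputs, lifetable, start_age)
    tr = inputs.transitions
    d = tr.distant_prop[arm]
    a_nm, a_1l, a_2l = tr.active_props
    mix1 = tr.drug_mix_1l
    mix2 = tr.drug_mix_2l

    M = np.zeros((N_SUB, N_SUB))
    I = _IDX
    q, qc = pr["q_bg"], pr["q_cured"]
    p, phi = pr["p_exit"], pr["phi"]

    def met1l_alloc(mass):
        """Split an entering flow into the 1L substates."""
        return {
            I["met1l_active_lorlatinib"]: mass * a_1l * mix1["lorlatinib"],
            I["met1l_active_alectinib"]: mass * a_1l * mix1["alectinib"],
            I["met1l_supportive"]: mass * (1 - a_1l),
        }

    def met2l_alloc(mass):
        return {
            I["met2l_active_alectinib"]: mass * a_2l * mix2["alectinib"],
            I["met2l_active_brigatinib"]: mass * a_2l * mix2["brigatinib"],
            I["met2l_active_chemo_bev"]: mass * a_2l * mix2["chemo_bev"],
            I["met2l_supportive"]: mass * (1 - a_2l),
        }

    # DFS at-risk
    row = I["dfs_at_risk"]
    M[row, I["death"]] = q
    alive = 1 - q
    M[row, I["nonmet_active"]] = alive * p * (1 - d) * a_nm
    M[row, I["nonmet_supportive"]] = alive * p * (1 - d) * (1 - a_nm)
    for j, v in met1l_alloc(alive * p * d).items():
        M[row, j] += v
    stay = alive * (1 - p)
    M[row, I["dfs_cured"]] = stay * phi
    M[row, I["dfs_at_risk"]] = stay * (1 - phi)

    # DFS cured: background (excess) mortality only
    row = I["dfs_cured"]
    M[row, I["death"]] = qc
    M[row, I["dfs_cured"]] = 1 - qc

    # nonmetastatic active: progresses to 1L metastatic, never disease death
    row = I["nonmet_active"]
    M[row, I["death"]] = q
    alive = 1 - q
    for j, v in met1l_alloc(alive * tr.p_nonmet_to_1l_active).items():
        M[row, j] += v
    M[row, row] = alive * (1 - tr.p_nonmet_to_1l_active)

    # nonmetastatic supportive: death only
    row = I["nonmet_supportive"]
    M[row, I["death"]] = q + (1 - q) * tr.p_nonmet_death_supportive
    M[row, row] = (1 - q) * (1 - tr.p_nonmet_death_supportive)

    # 1L active substates: progress to subsequent line
    for sub, p_prog in (("met1l_active_lorlatinib", pr["p_lor"]),
                        ("met1l_active_alectinib", pr["p_ale1"])):
        row = I[sub]
        M[row, I["death"]] = q
        alive = 1 - q
        for j, v in met2l_alloc(alive * p_prog).items():
            M[row, j] += v
        M[row, row] = alive * (1 - p_prog)

    # 1L supportive
    row = I["met1l_supportive"]
    M[row, I["death"]] = q + (1 - q) * tr.p_met_death_supportive
    M[row, row] = (1 - q) * (1 - tr.p_met_death_supportive)

    # subsequent-line active: death per the regimen's survival fit
    for sub, key in (("met2l_active_alectinib", "alectinib"),
                     ("met2l_active_brigatinib", "brigatinib"),
                     ("met2l_active_chemo_bev", "chemo_bev")):
        row = I[sub]
        pd_ = pr["p_2l"][key]
        M[row, I["death"]] = q + (1 - q) * pd_
        M[row, row] = (1 - q) * (1 - pd_)

    # subsequent-line supportive
    row = I["met2l_supportive"]
    M[row, I["death"]] = q + (1 - q) * tr.p_met_death_supportive
    M[row, row] = (1 - q) * (1 - tr.p_met_death_supportive)

    M[I["death"], I["death"]] = 1.0

    rowsums = M.sum(axis=1)
    if np.any(np.abs(rowsums - 1) > 1e-9):
        raise ValueError(f"transition rows deviate from 1: {rowsums}")
    return M


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class CohortTrace:
    """Cycle-by-cycle occupancy of the expanded substates.

    ``occupancy`` has shape (horizon+1, ..., n_substates) where the middle
    axes broadcast over probabilistic-draw dimensions.  ``disease_deaths``
    and ``background_deaths`` are the per-cycle flows into death from
    recurrence-state disease pathways and from background mortality.
    """

    arm: str
    occupancy: np.ndarray
    disease_deaths: np.ndarray
    background_deaths: np.ndarray

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0] - 1

    def collapse(self) -> np.ndarray:
        """Occupancy over the five reported states."""
        out = np.zeros(self.occupancy.shape[:-1] + (len(REPORTED_STATES),))
        for i, sub in enumerate(SUBSTATES):
            j = REPORTED_STATES.index(STATE_OF_SUBSTATE[sub])
            out[..., j] += self.occupancy[..., i]
        return out

    def mid_cycle(self) -> np.ndarray:
        """Half-cycle-corrected occupancy: mean of cycle start and end."""
        return 0.5 * (self.occupancy[:-1] + self.occupancy[1:])

    def life_years(self, annual_rate: float = 0.0) -> dict:
        """Discounted life-years per reported state (half-cycle corrected,
        mid-cycle discounting)."""
        mid = 0.5 * (self.collapse()[:-1] + self.collapse()[1:])
        t = np.arange(self.horizon)
        df = (1.0 + annual_rate) ** (-(t + 0.5) / 12.0)
        ly = np.tensordot(df, mid, axes=(0, 0)) / 12.0
        return {s: ly[..., i] for i, s in enumerate(REPORTED_STATES)}

    def to_frame(self) -> pd.DataFrame:
        if self.occupancy.ndim != 2:
            raise ValueError("to_frame requires a scalar (non-PSA) trace")
        df = pd.DataFrame(self.occupancy, columns=list(SUBSTATES))
        df.index.name = "cycle"
        return df


def _as_arr(x):
    return np.asarray(x, dtype=float)


def run_cohort(arm: str, fits: dict, inputs: ModelInputs,
               lifetable: Lifetable, horizon_months: int | None = None,
               start_age: float | None = None) -> CohortTrace:
    """Run the cohort through the monthly model.

    Fields of ``inputs`` may be numpy arrays (probabilistic draws); the
    occupancy then carries a draw axis.  Survival-curve fits are shared
    across draws.
    """
    if arm not in ("alectinib", "chemotherapy"):
        raise ValueError(f"unknown arm {arm!r}")
    horizon = int(inputs.horizon_months if horizon_months is None else horizon_months)
    if horizon < 1:
        raise ValueError("horizon must be >= 1 month")
    start_age = inputs.start_age if start_age is None else start_age
    tr = inputs.transitions

    d = _as_arr(tr.distant_prop[arm])
    a_nm, a_1l, a_2l = (_as_arr(a) for a in tr.active_props)
    mix1_l = _as_arr(tr.drug_mix_1l["lorlatinib"])
    mix1_a = _as_arr(tr.drug_mix_1l["alectinib"])
    mix2 = {k: _as_arr(v) for k, v in tr.drug_mix_2l.items()}
    p_nm = _as_arr(tr.p_nonmet_to_1l_active)
    q_nms = _as_arr(tr.p_nonmet_death_supportive)
    q_ms = _as_arr(tr.p_met_death_supportive)

    shape = np.broadcast_shapes(d.shape, a_nm.shape, p_nm.shape,
                                q_nms.shape, q_ms.shape)
    x = np.zeros(shape + (N_SUB,))
    x[..., _IDX["dfs_at_risk"]] = 1.0

    occ = np.zeros((horizon + 1,) + shape + (N_SUB,))
    occ[0] = x
    dis_deaths = np.zeros((horizon,) + shape)
    bg_deaths = np.zeros((horizon,) + shape)
    I = _IDX
    curves = _precompute_curves(arm, fits, inputs, lifetable, start_age, horizon)

    for t in range(horizon):
        pr = {k: (v[t] if k != "p_2l" else {kk: vv[t] for kk, vv in v.items()})
              for k, v in curves.items()}
        q, qc = pr["q_bg"], pr["q_cured"]
        p, phi = pr["p_exit"], pr["phi"]
        x = occ[t]
        y = np.zeros_like(x)

        # background mortality first
        bg = 0.0
        for i, sub in enumerate(SUBSTATES):
            if sub == "death":
                continue
            qi = qc if sub == "dfs_cured" else q
            bg = bg + x[..., i] * qi
        bg_deaths[t] = bg

        surv = lambda i, sub: x[..., i] * ((1 - qc) if sub == "dfs_cured" else (1 - q))

        # DFS at-risk
        s = surv(I["dfs_at_risk"], "dfs_at_risk")
        exits = s * p
        y[..., I["nonmet_active"]] += exits * (1 - d) * a_nm
        y[..., I["nonmet_supportive"]] += exits * (1 - d) * (1 - a_nm)
        y[..., I["met1l_active_lorlatinib"]] += exits * d * a_1l * mix1_l
        y[..., I["met1l_active_alectinib"]] += exits * d * a_1l * mix1_a
        y[..., I["met1l_supportive"]] += exits * d * (1 - a_1l)
        stay = s * (1 - p)
        y[..., I["dfs_cured"]] += stay * phi
        y[..., I["dfs_at_risk"]] += stay * (1 - phi)

        # DFS cured
        y[..., I["dfs_cured"]] += surv(I["dfs_cured"], "dfs_cured")

        # nonmetastatic active
        s = surv(I["nonmet_active"], "nonmet_active")
        prog = s * p_nm
        y[..., I["met1l_active_lorlatinib"]] += prog * a_1l * mix1_l
        y[..., I["met1l_active_alectinib"]] += prog * a_1l * mix1_a
        y[..., I["met1l_supportive"]] += prog * (1 - a_1l)
        y[..., I["nonmet_active"]] += s - prog

        dd = 0.0
        # nonmetastatic supportive
        s = surv(I["nonmet_supportive"], "nonmet_supportive")
        dd = dd + s * q_nms
        y[..., I["nonmet_supportive"]] += s * (1 - q_nms)

        # 1L active
        for sub, p_prog in (("met1l_active_lorlatinib", pr["p_lor"]),
                            ("met1l_active_alectinib", pr["p_ale1"])):
            s = surv(I[sub], sub)
            prog = s * p_prog
            y[..., I["met2l_active_alectinib"]] += prog * a_2l * mix2["alectinib"]
            y[..., I["met2l_active_brigatinib"]] += prog * a_2l * mix2["brigatinib"]
            y[..., I["met2l_active_chemo_bev"]] += prog * a_2l * mix2["chemo_bev"]
            y[..., I["met2l_supportive"]] += prog * (1 - a_2l)
            y[..., I[sub]] += s - prog

        # 1L supportive
        s = surv(I["met1l_supportive"], "met1l_supportive")
        dd = dd + s * q_ms
        y[..., I["met1l_supportive"]] += s * (1 - q_ms)

        # subsequent-line active
        for sub, key in (("met2l_active_alectinib", "alectinib"),
                         ("met2l_active_brigatinib", "brigatinib"),
                         ("met2l_active_chemo_bev", "chemo_bev")):
            s = surv(I[sub], sub)
            dth = s * pr["p_2l"][key]
            dd = dd + dth
            y[..., I[sub]] += s - dth

        # subsequent-line supportive
        s = surv(I["met2l_supportive"], "met2l_supportive")
        dd = dd + s * q_ms
        y[..., I["met2l_supportive"]] += s * (1 - q_ms)

        dis_deaths[t] = dd
        y[..., I["death"]] = x[..., I["death"]] + bg + dd
        occ[t + 1] = y

        if np.any(~np.isfinite(y)) or np.any(y < -1e-12):
            raise ValueError(f"invalid occupancy at cycle {t + 1}")

    return CohortTrace(arm=arm, occupancy=occ, disease_deaths=dis_deaths,
                       background_deaths=bg_deaths)
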