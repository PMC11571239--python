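"""Model inputs: the full parameter ledger for the cohort model.

Holds transition probabilities, per-cycle costs, utilities, adverse-event
terms, discounting, survival-curve parameter blocks, and the deterministic/
probabilistic sensitivity ranges, with YAML round-tripping.  Values carry
their units in the field docstrings: probabilities are per month unless
noted, costs are 2024 USD (1 USD = 7.23 CNY), utilities are per year.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "ARMS",
    "TransitionInputs",
    "CostInputs",
    "UtilityInputs",
    "DiscountSpec",
    "SurvivalParams",
    "ModelInputs",
    "ParamSpec",
    "default_inputs",
    "default_param_specs",
    "DAYS_PER_MONTH",
    "ALECTINIB_MONTHLY_COST",
]

ARMS = ("alectinib", "chemotherapy")

DAYS_PER_MONTH = 30.4375

# Placeholder adjuvant alectinib price (the published table leaves this row
# to a supplement): synthetic unit price CNY 54.40 per 150 mg capsule,
# 600 mg twice daily = 8 capsules/day, converted at 7.23 CNY/USD.
ALECTINIB_MONTHLY_COST = round(54.40 * 8 * DAYS_PER_MONTH / 7.23, 2)  # 1832.11


@dataclass
class TransitionInputs:
    """Monthly transition probabilities and structural assumptions."""

    p_nonmet_to_1l_active: float = 0.018
    p_nonmet_death_supportive: float = 0.0762
    p_met_death_supportive: float = 0.1036
    distant_prop: dict = field(
        default_factory=lambda: {"alectinib": 0.357, "chemotherapy": 0.551})
    #: share receiving active treatment in (nonmetastatic, 1L, subsequent)
    active_props: tuple = (0.839, 0.909, 0.875)
    drug_mix_1l: dict = field(
        default_factory=lambda: {"lorlatinib": 0.5, "alectinib": 0.5})
    # published proportions 0.363/0.272/0.363 sum to 0.998; renormalized
    drug_mix_2l: dict = field(
        default_factory=lambda: {"alectinib": 0.363 / 0.998,
                                 "brigatinib": 0.272 / 0.998,
                                 "chemo_bev": 0.363 / 0.998})
    cure_start: float = 24.0       # months
    cure_end: float = 120.0        # months
    cure_cap: float = 0.975
    excess_mortality_multiplier: float = 1.25
    waning_start: float = 28.0     # months
    waning_end: float = 60.0       # months
    #: hazard ratios vs the fitted subsequent-line alectinib curve
    hr_2l_brigatinib: float = 1.0
    hr_2l_chemo_bev: float = 1.0

    def validate(self):
        for name in ("p_nonmet_to_1l_active", "p_nonmet_death_supportive",
                     "p_met_death_supportive", "cure_cap"):
            v = np.asarray(getattr(self, name))
            if np.any(v < 0) or np.any(v > 1):
                raise ValueError(f"{name} outside [0,1]")
        for arm, v in self.distant_prop.items():
            if np.any(np.asarray(v) < 0) or np.any(np.asarray(v) > 1):
                raise ValueError(f"distant_prop[{arm}] outside [0,1]")
        for mix in (self.drug_mix_1l, self.drug_mix_2l):
            tot = np.sum([np.asarray(v, dtype=float) for v in mix.values()], axis=0)
            if np.any(np.abs(tot - 1) > 1e-9):
                raise ValueError("drug mix must sum to 1")
        if not self.waning_start < self.waning_end:
            raise ValueError("waning_start must precede waning_end")
        if not self.cure_start < self.cure_end:
            raise ValueError("cure_start must precede cure_end")


@dataclass
class CostInputs:
    """Per-cycle direct medical costs, 2024 USD."""

    chemo_dfs_per_21d: float = 412.87
    alectinib_dfs_monthly: float = ALECTINIB_MONTHLY_COST
    chemo_n_cycles: int = 4                 # 21-day cycles
    alectinib_duration_months: float = 24.0
    followup_0_5y: float = 24.42            # per month, first 60 months
    followup_post5y: float = 12.21          # per month thereafter
    administration_per_21d: float = 43.36   # intravenous therapy only
    nonmet_treatment: dict = field(
        default_factory=lambda: {"alectinib": 334.95, "chemotherapy": 338.15})
    met1l_lorlatinib: float = 2 * 1855.02 - ALECTINIB_MONTHLY_COST
    met1l_alectinib: float = ALECTINIB_MONTHLY_COST
    met_subsequent: dict = field(
        default_factory=lambda: {"alectinib": 2659.42, "chemotherapy": 2719.49})
    end_of_life: float = 1967.49
    #: expected adverse-event cost applied once at the first treatment cycle
    ae_cost: dict = field(
        default_factory=lambda: {"alectinib": 0.40, "chemotherapy": 17.65})
    ae_risk: dict = field(
        default_factory=lambda: {"alectinib": 0.062, "chemotherapy": 0.102})

    @property
    def met1l_blend(self) -> float:
        return 0.5 * (self.met1l_lorlatinib + self.met1l_alectinib)


@dataclass
class UtilityInputs:
    """Annual health-state utilities and adverse-event disutilities."""

    dfs_on_treatment: float = 0.845
    dfs_off_treatment: float = 0.872
    nonmetastatic: float = 0.845
    metastatic_1l: float = 0.805
    metastatic_subsequent: float = 0.741
    ae_disutility: dict = field(
        default_factory=lambda: {"alectinib": 0.062, "chemotherapy": 0.200})


@dataclass
class DiscountSpec:
    """Annual discount rates for costs and health outcomes."""

    cost_rate: float = 0.05
    outcome_rate: float = 0.05

    def validate(self):
        for r in (self.cost_rate, self.outcome_rate):
            if np.any(np.asarray(r) < 0) or np.any(np.asarray(r) > 0.20):
                raise ValueError("discount rates must lie in [0, 0.20]")


@dataclass
class SurvivalParams:
    """Survival-curve parameter blocks (family name + natural parameters).

    The base-case analysis consumes these directly; they are either fitted
    from reconstructed pseudo-IPD or loaded from config.  Keys:
    ``dfs_alectinib``, ``dfs_chemotherapy`` (disease-free survival),
    ``pfs_lorlatinib``, ``pfs_alectinib_1l`` (first-line progression),
    ``os_subsequent`` (subsequent-line survival).
    """

    curves: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.curves[key]


@dataclass
class ModelInputs:
    """Everything the cohort model and economics need for one run."""

    transitions: TransitionInputs = field(default_factory=TransitionInputs)
    costs: CostInputs = field(default_factory=CostInputs)
    utilities: UtilityInputs = field(default_factory=UtilityInputs)
    discount: DiscountSpec = field(default_factory=DiscountSpec)
    survival: SurvivalParams = field(default_factory=SurvivalParams)
    start_age: float = 56.0
    horizon_months: int = 600

    def copy(self) -> "ModelInputs":
        return copy.deepcopy(self)

    def validate(self):
        self.transitions.validate()
        self.discount.validate()

    # -- YAML round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        def plain(o):
            if dataclasses.is_dataclass(o):
                return {k: plain(v) for k, v in dataclasses.asdict(o).items()}
            if isinstance(o, dict):
                return {k: plain(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [plain(v) for v in o]
            if isinstance(o, np.generic):
                return o.item()
            if isinstance(o, np.ndarray):
                return o.tolist()
            return o

        return plain(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelInputs":
        tr = TransitionInputs(**{**d.get("transitions", {})})
        tr.active_props = tuple(tr.active_props)
        co = CostInputs(**d.get("costs", {}))
        ut = UtilityInputs(**d.get("utilities", {}))
        di = DiscountSpec(**d.get("discount", {}))
        sv = SurvivalParams(**d.get("survival", {}))
        return cls(transitions=tr, costs=co, utilities=ut, discount=di,
                   survival=sv, start_age=d.get("start_age", 56.0),
                   horizon_months=d.get("horizon_months", 600))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelInputs":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_inputs() -> ModelInputs:
    """The published base-case parameter ledger (survival block empty)."""
    mi = ModelInputs()
    mi.validate()
    return mi


# ---------------------------------------------------------------------------
# sensitivity-analysis parameter specs
# ---------------------------------------------------------------------------

@dataclass
class ParamSpec:
    """One uncertain parameter: base value, DSA bounds, PSA distribution,
    and a setter path into :class:`ModelInputs`."""

    name: str
    base: float
    low: float
    high: float
    dist: str  # BETA | GAMMA | CONSTANT
    path: str

    def __post_init__(self):
        if not (self.low <= self.base <= self.high):
            raise ValueError(f"{self.name}: bounds must bracket the base value")
        if self.dist not in ("BETA", "GAMMA", "CONSTANT"):
            raise ValueError(f"{self.name}: unknown distribution {self.dist}")

    def apply(self, mi: ModelInputs, value) -> None:
        parts = self.path.split(".")
        if parts == ["costs", "met1l_blend"]:
            # scale both first-line drug costs, preserving their ratio
            f = value / mi.costs.met1l_blend
            mi.costs.met1l_lorlatinib = mi.costs.met1l_lorlatinib * f
            mi.costs.met1l_alectinib = mi.costs.met1l_alectinib * f
            return
        obj = mi
        for p in parts[:-1]:
            obj = getattr(obj, p)
        last = parts[-1]
        if "[" in last:  # dict entry, e.g. distant_prop[alectinib]
            attr, key = last[:-1].split("[")
            getattr(obj, attr)[key] = value
        else:
            setattr(obj, last, value)


def default_param_specs(mi: ModelInputs | None = None) -> list[ParamSpec]:
    """The published uncertainty ledger.

    Ranges are the printed low/high columns; parameters without published
    bounds use +/-10% (utilities, AE risks) or +/-20% (other inputs).
    Discount rates vary 0-8% in the DSA but are CONSTANT in the PSA.
    """
    mi = mi or default_inputs()
    ale_c = mi.costs.alectinib_dfs_monthly
    specs = [
        ParamSpec("Distant metastases proportion (Ale)", 0.357, 0.286, 0.429,
                  "BETA", "transitions.distant_prop[alectinib]"),
        ParamSpec("Distant metastases proportion (Chemo)", 0.551, 0.441, 0.661,
                  "BETA", "transitions.distant_prop[chemotherapy]"),
        ParamSpec("Nonmetastatic to 1L metastatic (active)", 0.018, 0.015, 0.022,
                  "BETA", "transitions.p_nonmet_to_1l_active"),
        ParamSpec("Nonmetastatic to death (supportive)", 0.0762, 0.061, 0.091,
                  "BETA", "transitions.p_nonmet_death_supportive"),
        ParamSpec("Metastatic to death (supportive)", 0.1036, 0.083, 0.124,
                  "BETA", "transitions.p_met_death_supportive"),
        ParamSpec("Chemo cost in DFS (per 21d cycle)", 412.87, 245.49, 691.93,
                  "GAMMA", "costs.chemo_dfs_per_21d"),
        ParamSpec("Alectinib cost in DFS (per month)", ale_c,
                  0.8 * ale_c, 1.2 * ale_c, "GAMMA", "costs.alectinib_dfs_monthly"),
        ParamSpec("Follow-up visit, years 0-5", 24.42, 19.54, 29.31,
                  "GAMMA", "costs.followup_0_5y"),
        ParamSpec("Follow-up visit, after year 5", 12.21, 9.77, 14.65,
                  "GAMMA", "costs.followup_post5y"),
        ParamSpec("Administration", 43.36, 34.69, 52.03,
                  "GAMMA", "costs.administration_per_21d"),
        ParamSpec("Nonmetastatic treatment cost (Ale)", 334.95, 267.96, 401.94,
                  "GAMMA", "costs.nonmet_treatment[alectinib]"),
        ParamSpec("Nonmetastatic treatment cost (Chemo)", 338.15, 270.52, 405.77,
                  "GAMMA", "costs.nonmet_treatment[chemotherapy]"),
        ParamSpec("1L metastatic treatment cost", 1855.02, 1484.01, 2226.02,
                  "GAMMA", "costs.met1l_blend"),
        ParamSpec("Subsequent-line treatment cost (Ale)", 2659.42, 2127.53, 3191.30,
                  "GAMMA", "costs.met_subsequent[alectinib]"),
        ParamSpec("Subsequent-line treatment cost (Chemo)", 2719.49, 2175.43, 3263.14,
                  "GAMMA", "costs.met_subsequent[chemotherapy]"),
        ParamSpec("End-of-life cost", 1967.49, 764.34, 5254.75,
                  "GAMMA", "costs.end_of_life"),
        ParamSpec("AE cost: CPK increased", 0.40, 0.32, 0.48,
                  "GAMMA", "costs.ae_cost[alectinib]"),
        ParamSpec("AE cost: neutrophil decreased", 17.65, 14.12, 21.18,
                  "GAMMA", "costs.ae_cost[chemotherapy]"),
        ParamSpec("AE risk: CPK increased", 0.062, 0.056, 0.068,
                  "BETA", "costs.ae_risk[alectinib]"),
        ParamSpec("AE risk: neutrophil decreased", 0.102, 0.092, 0.112,
                  "BETA", "costs.ae_risk[chemotherapy]"),
        ParamSpec("Utility: DFS on treatment", 0.845, 0.820, 0.870,
                  "BETA", "utilities.dfs_on_treatment"),
        ParamSpec("Utility: DFS off treatment", 0.872, 0.845, 0.951,
                  "BETA", "utilities.dfs_off_treatment"),
        ParamSpec("Utility: nonmetastatic recurrence", 0.845, 0.820, 0.870,
                  "BETA", "utilities.nonmetastatic"),
        ParamSpec("Utility: 1L metastatic recurrence", 0.805, 0.775, 0.835,
                  "BETA", "utilities.metastatic_1l"),
        ParamSpec("Utility: subsequent-line recurrence", 0.741, 0.703, 0.779,
                  "BETA", "utilities.metastatic_subsequent"),
        ParamSpec("AE disutility: CPK increased", 0.062, 0.045, 0.093,
                  "BETA", "utilities.ae_disutility[alectinib]"),
        ParamSpec("AE disutility: neutrophil decreased", 0.200, 0.180, 0.220,
                  "BETA", "utilities.ae_disutility[chemotherapy]"),
        ParamSpec("Cost discount rate", 0.05, 0.0, 0.08,
                  "CONSTANT", "discount.cost_rate"),
        ParamSpec("Outcome discount rate", 0.05, 0.0, 0.08,
                  "CONSTANT", "discount.outcome_rate"),
    ]
    return specs
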