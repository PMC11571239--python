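"""Synthetic study inputs with known parametric ground truth.

Generates everything the pipeline needs without external downloads:
pseudo-IPD drawn from stated families by inverse transform, digitized-KM
fixtures with numbers-at-risk tables (exact or with digitization jitter),
a smooth background-mortality lifetable, and a fully populated model
config.

The trial-like DFS/PFS/OS ground-truth parameters in ``FIXTURE_TRUTH``
are synthetic stand-ins calibrated once from public trial-level summary
anchors (landmark survival probabilities and medians); they emulate the
qualitative shape of the source curves — a plateauing targeted-therapy arm
against a steadily declining comparator — and are not the trials' fitted
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .inputs import ModelInputs, default_inputs
from .survival import PseudoIPD, family_ppf, family_sf

__all__ = [
    "SimulationSpec",
    "gen_ipd",
    "gen_km_fixture",
    "make_lifetable",
    "default_fixture_set",
    "FIXTURE_TRUTH",
    "FIXTURE_N",
]

# family name, natural parameters (see alkcea.survival for conventions)
FIXTURE_TRUTH = {
    "dfs_alectinib": ("gompertz", (-0.0039894, 0.0027969)),
    "dfs_chemotherapy": ("lognormal", (3.7209, 1.6357)),
    "pfs_lorlatinib": ("loglogistic", (203.046, 0.33256)),
    "pfs_alectinib_1l": ("weibull", (1.28603, 46.5418)),
    "os_subsequent": ("weibull", (1.17924, 27.2904)),
}

#: subjects per synthetic dataset (adjuvant arms at trial scale)
FIXTURE_N = {
    "dfs_alectinib": 130,
    "dfs_chemotherapy": 128,
    "pfs_lorlatinib": 149,
    "pfs_alectinib_1l": 120,
    "os_subsequent": 100,
}

_FIXTURE_FOLLOWUP = {  # (accrual months, administrative horizon months)
    "dfs_alectinib": (24.0, 44.0),
    "dfs_chemotherapy": (24.0, 44.0),
    "pfs_lorlatinib": (18.0, 60.0),
    "pfs_alectinib_1l": (18.0, 54.0),
    "os_subsequent": (18.0, 48.0),
}


@dataclass
class SimulationSpec:
    """Ground-truth recipe for one synthetic dataset."""

    family: str
    params: tuple
    n: int
    horizon: float            # administrative censoring horizon (months)
    accrual: float = 0.0      # uniform accrual window (months)
    censor_rate: float = 0.0  # exponential random-censoring rate (/month)
    seed: int = 0
    arm: str = ""
    endpoint: str = ""
    cure_fraction: float | None = None  # mixture-cure ground truth

    def __post_init__(self):
        if self.n < 10:
            raise ValueError("n must be >= 10")
        if not (0 <= self.censor_rate < np.inf):
            raise ValueError("censor_rate must be >= 0")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def gen_ipd(spec: SimulationSpec) -> PseudoIPD:
    """Draw event times by inverse transform, apply administrative and
    random censoring; deterministic under the spec's seed."""
    rng = np.random.default_rng(spec.seed)
    u = rng.uniform(size=spec.n)
    if spec.cure_fraction is not None:
        cured = rng.uniform(size=spec.n) < spec.cure_fraction
        t_event = np.where(cured, np.inf, family_ppf(spec.family, u, spec.params))
    else:
        t_event = family_ppf(spec.family, u, spec.params)
    entry = rng.uniform(0, spec.accrual, size=spec.n) if spec.accrual > 0 else np.zeros(spec.n)
    t_admin = np.maximum(spec.horizon - entry, 0.0)
    if spec.censor_rate > 0:
        t_rand = rng.exponential(1.0 / spec.censor_rate, size=spec.n)
    else:
        t_rand = np.full(spec.n, np.inf)
    t_cens = np.minimum(t_admin, t_rand)
    obs = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return PseudoIPD(obs, event, arm=spec.arm, endpoint=spec.endpoint)


def gen_km_fixture(ipd: PseudoIPD, risk_interval: float = 3.0,
                   jitter_sd: float = 0.0, seed: int = 0,
                   include_total_events: bool = True,
                   risk_at_events: bool = False):
    """Digitized-KM fixture from an IPD set: KM step coordinates at event
    times plus a numbers-at-risk table on a regular grid (or at the event
    times themselves with ``risk_at_events``, which makes reconstruction
    exact).  ``jitter_sd`` adds Gaussian digitization noise to the
    survival coordinates."""
    from lifelines import KaplanMeierFitter

    from .reconstruct import DigitizedKM

    kmf = KaplanMeierFitter()
    kmf.fit(ipd.time, ipd.event)
    sf = kmf.survival_function_
    t = sf.index.to_numpy(dtype=float)
    s = sf.iloc[:, 0].to_numpy(dtype=float)
    # keep t=0 plus the event-time drops
    keep = np.concatenate([[True], np.diff(s) < 0])
    t, s = t[keep], s[keep]
    if t[0] > 0:
        t, s = np.insert(t, 0, 0.0), np.insert(s, 0, 1.0)
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0, jitter_sd, size=s.size)
        noise[0] = 0.0
        s = np.minimum.accumulate(np.clip(s + noise, 0.0, 1.0))

    t_max = ipd.time.max()
    if risk_at_events:
        grid = t
    else:
        grid = np.arange(0.0, t_max + 1e-9, risk_interval)
    n_at_risk = [(ipd.time >= g).sum() for g in grid]
    coords = pd.DataFrame({"time": t, "survival": s})
    risk = pd.DataFrame({"time": grid, "n_at_risk": n_at_risk})
    return DigitizedKM(coords, risk,
                       total_events=ipd.n_events if include_total_events else None,
                       arm=ipd.arm, endpoint=ipd.endpoint)


def make_lifetable(a: float = 2e-4, b: float = 2.7e-5,
                   theta: float = 0.092) -> pd.DataFrame:
    """Gompertz-Makeham background-mortality lifetable, ages 18-100.

    A synthetic stand-in for a national census lifetable: annual
    q(age) = 1 - exp(-(a + b e^{theta age})); swap in a real table via the
    same (age, q_annual) CSV layout.
    """
    ages = np.arange(18, 101)
    hazard = a + b * np.exp(theta * ages)
    q = 1.0 - np.exp(-hazard)
    return pd.DataFrame({"age": ages, "q_annual": q})


def curve_specs(seed: int) -> dict[str, SimulationSpec]:
    """SimulationSpecs for the five survival curves, seeds derived from a
    single master seed."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(FIXTURE_TRUTH))
    specs = {}
    for (key, (family, params)), child in zip(FIXTURE_TRUTH.items(), children):
        accrual, horizon = _FIXTURE_FOLLOWUP[key]
        arm = "alectinib" if "alectinib" in key else (
            "chemotherapy" if "chemo" in key else "lorlatinib")
        endpoint = "DFS" if key.startswith("dfs") else (
            "PFS" if key.startswith("pfs") else "OS")
        specs[key] = SimulationSpec(
            family=family, params=params, n=FIXTURE_N[key],
            horizon=horizon, accrual=accrual,
            seed=int(child.generate_state(1)[0] % (2**31)),
            arm=arm, endpoint=endpoint)
    return specs


def default_fixture_set(seed: int, outdir: str | Path | None = None) -> dict:
    """Materialize the full study-input tree.

    Returns a dict with the model config (``inputs``), per-curve pseudo-IPD
    (``ipd``), digitized-KM fixtures (``km``), the lifetable, and the
    generating ground truth.  When ``outdir`` is given, everything is also
    written as CSV/YAML.
    """
    specs = curve_specs(seed)
    ipd = {k: gen_ipd(sp) for k, sp in specs.items()}
    km = {k: gen_km_fixture(v, risk_interval=3.0 if k.startswith("dfs") else 6.0)
          for k, v in ipd.items()}
    lifetable = make_lifetable()

    inputs = default_inputs()
    inputs.survival.curves = {
        k: {"family": fam, "params": list(par)}
        for k, (fam, par) in FIXTURE_TRUTH.items()
    }

    out = {"inputs": inputs, "ipd": ipd, "km": km, "lifetable": lifetable,
           "truth": dict(FIXTURE_TRUTH), "specs": specs}

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        inputs.to_yaml(outdir / "model_inputs.yaml")
        lifetable.to_csv(outdir / "lifetable.csv", index=False)
        for k, v in ipd.items():
            v.to_csv(outdir / f"ipd_{k}.csv")
        for k, v in km.items():
            v.coords.to_csv(outdir / f"km_{k}_coords.csv", index=False)
            v.risk_table.to_csv(outdir / f"km_{k}_risk.csv", index=False)
    return out


def true_survival(key: str, t) -> np.ndarray:
    """Closed-form ground-truth survival for a fixture curve."""
    family, params = FIXTURE_TRUTH[key]
    return family_sf(family, np.asarray(t, dtype=float), params)
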