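"""End-to-end assembly: fixtures -> survival fits -> cohort model -> CEA.

Two routes build the same :class:`~alkcea.sensitivity.ModelContext`:

``route='config'``
    Survival curves are taken directly from the parameter blocks in the
    model config (the workflow when fitted parameters are supplied rather
    than re-estimated).

``route='refit'``
    The full evidence chain is exercised: synthetic pseudo-IPD are turned
    into digitized-KM fixtures, reconstructed back to pseudo-IPD, fitted,
    and selected.  Disease-free survival uses the pre-specified families
    (Gompertz for alectinib, log-normal for chemotherapy); the metastatic
    curves are AIC-selected among the five standard families.
"""

from __future__ import annotations

import numpy as np

from .inputs import ModelInputs
from .markov import Lifetable
from .reconstruct import reconstruct
from .sensitivity import ModelContext
from .survival import (FAMILIES, PseudoIPD, SurvivalFit, fit_standard,
                       ranking_table, select_model)
from .synthetic import default_fixture_set, gen_km_fixture

__all__ = ["fit_from_params", "build_context", "fit_all_curves"]

#: pre-specified base-case DFS families
DFS_FAMILY = {"dfs_alectinib": "gompertz", "dfs_chemotherapy": "lognormal"}


def fit_from_params(family: str, params) -> SurvivalFit:
    """Wrap externally supplied curve parameters as a SurvivalFit
    (no likelihood attached)."""
    params = np.asarray(params, dtype=float)
    return SurvivalFit(family=family, params=params, n_params=params.size,
                       loglik=np.nan, aic=np.nan, message="from config")


def fit_all_curves(ipd_by_curve: dict[str, PseudoIPD]) -> tuple[dict, dict]:
    """Fit every model curve from pseudo-IPD.

    Returns (selected fits, AIC ranking tables).  DFS curves use their
    pre-specified family; other curves are AIC-selected over the five
    standard families.
    """
    fits, rankings = {}, {}
    for key, ipd in ipd_by_curve.items():
        candidates = [fit_standard(ipd, fam) for fam in FAMILIES]
        rankings[key] = ranking_table(candidates)
        if key in DFS_FAMILY:
            fits[key] = next(f for f in candidates if f.family == DFS_FAMILY[key])
        else:
            fits[key] = select_model(candidates)
    return fits, rankings


def build_context(seed: int = 0, route: str = "config",
                  inputs: ModelInputs | None = None) -> ModelContext:
    """Build a ready-to-run model context from the synthetic fixture set."""
    fx = default_fixture_set(seed)
    mi = fx["inputs"] if inputs is None else inputs
    lifetable = Lifetable(fx["lifetable"])
    if route == "config":
        fits = {k: fit_from_params(v["family"], v["params"])
                for k, v in mi.survival.curves.items()}
    elif route == "refit":
        recon = {k: reconstruct(km) for k, km in fx["km"].items()}
        fits, _ = fit_all_curves(recon)
    else:
        raise ValueError(f"unknown route {route!r}")
    return ModelContext(fits=fits, inputs=mi, lifetable=lifetable)
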