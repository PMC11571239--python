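"""Figure helpers for the analysis drivers (all save to file)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .survival import PseudoIPD, SurvivalFit, _km_estimate

__all__ = ["km_overlay", "tornado", "ceac_plot", "ce_plane"]


def km_overlay(ipd: PseudoIPD, fits: list[SurvivalFit], labels, path,
               horizon: float = 240.0):
    """Kaplan-Meier step function with fitted extrapolations overlaid:
    the visual fit-adequacy check."""
    t_km, s_km = _km_estimate(ipd)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.step(t_km, s_km, where="post", color="k", lw=1.5, label="KM")
    grid = np.linspace(0, horizon, 400)
    for fit, lab in zip(fits, labels):
        ax.plot(grid, fit.survival(grid), lw=1, label=lab)
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def tornado(dsa: pd.DataFrame, path, top: int = 10):
    """Top-N one-way sensitivity bars around the base-case ICER."""
    df = dsa.dropna(subset=["width"]).head(top).iloc[::-1]
    base = dsa["base_icer"].iloc[0]
    fig, ax = plt.subplots(figsize=(7, 0.45 * len(df) + 1.2))
    for i, (_, row) in enumerate(df.iterrows()):
        lo, hi = sorted([row["icer_low"], row["icer_high"]])
        ax.barh(i, hi - lo, left=lo, color="steelblue", height=0.6)
    ax.axvline(base, color="k", lw=1, ls="--", label="base case")
    ax.set_yticks(range(len(df)))
    ax.set_yticklabels(df["parameter"], fontsize=7)
    ax.set_xlabel("ICER (USD per QALY)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def ceac_plot(curve: pd.DataFrame, path, thresholds=()):
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve["wtp"], curve["probability"], lw=1.5)
    for thr in thresholds:
        ax.axvline(thr, color="gray", lw=0.8, ls=":")
    ax.set_xlabel("willingness to pay (USD per QALY)")
    ax.set_ylabel("probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def ce_plane(draws: pd.DataFrame, path, wtp: float | None = None):
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.scatter(draws["delta_qaly"], draws["delta_cost"], s=3, alpha=0.25)
    ax.axhline(0, color="k", lw=0.8)
    ax.axvline(0, color="k", lw=0.8)
    if wtp is not None:
        q = np.linspace(*ax.get_xlim(), 10)
        ax.plot(q, wtp * q, "r--", lw=0.8, label=f"WTP {wtp:,.0f}/QALY")
        ax.legend(fontsize=7)
    ax.set_xlabel("incremental QALYs")
    ax.set_ylabel("incremental cost (USD)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
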