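"""Deterministic and probabilistic sensitivity analysis.

One-way DSA over the published parameter ranges (tornado table + figure),
a 5000-draw PSA (draw-level CSV), the cost-effectiveness acceptability
curve, and the incremental cost-effectiveness scatter.
"""

import argparse
from pathlib import Path

from alkcea.inputs import default_param_specs
from alkcea.pipeline import build_context
from alkcea.plots import ce_plane, ceac_plot, tornado
from alkcea.sensitivity import (WTP_1X_GDP, WTP_3X_GDP, ceac, run_dsa,
                                run_psa)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-draws", type=int, default=5000)
    ap.add_argument("--out", type=Path, default=Path("results/sensitivity"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    ctx = build_context(seed=args.seed, route="config")
    specs = default_param_specs(ctx.inputs)

    dsa = run_dsa(specs, ctx)
    dsa.to_csv(args.out / "dsa.csv", index=False)
    tornado(dsa, args.out / "tornado.png")
    finite = dsa[["icer_low", "icer_high"]].stack().dropna()
    print(f"DSA: base ICER {dsa['base_icer'].iloc[0]:,.0f}/QALY; "
          f"{int(dsa[['flag_low','flag_high']].eq('dominant').to_numpy().sum())} "
          f"bounds give dominance")
    if len(finite):
        print(f"     finite-ICER range [{finite.min():,.0f}, {finite.max():,.0f}]")
    print(f"     widest bar: {dsa['parameter'].iloc[0]}")

    draws = run_psa(args.n_draws, seed=args.seed, specs=specs, ctx=ctx)
    draws.to_csv(args.out / "psa_draws.csv", index=False)
    curve = ceac(draws)
    curve.to_csv(args.out / "ceac.csv", index=False)
    ceac_plot(curve, args.out / "ceac.png",
              thresholds=(WTP_1X_GDP, WTP_3X_GDP))
    ce_plane(draws, args.out / "ce_plane.png", wtp=WTP_1X_GDP)
    for thr in (WTP_1X_GDP, WTP_3X_GDP):
        p = curve.loc[curve["wtp"] == thr, "probability"].iloc[0]
        print(f"PSA: P(cost-effective) at ${thr:,.0f}/QALY = {100 * p:.1f}% "
              f"({args.n_draws} draws)")
    ne = ((draws["delta_qaly"] > 0) & (draws["delta_cost"] > 0)).mean()
    print(f"     {100 * ne:.1f}% of draws in the northeast quadrant")
    print(f"outputs in {args.out}/")


if __name__ == "__main__":
    main()
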