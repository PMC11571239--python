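"""Shared test utilities."""

import numpy as np

from alkcea.survival import SurvivalFit

CURVE_KEYS = ("dfs_alectinib", "dfs_chemotherapy", "pfs_lorlatinib",
              "pfs_alectinib_1l", "os_subsequent")


def const_fit(h):
    """Constant-hazard curve (exponential): S(t) = e^{-h t}."""
    return SurvivalFit("gompertz", np.array([0.0, float(h)]), 2, 0.0, 0.0)


def flat_fits():
    """No-event curves for every model slot (S = 1 everywhere)."""
    f = const_fit(0.0)
    return {k: f for k in CURVE_KEYS}
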