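import warnings

import numpy as np
import pytest

from alkcea.markov import Lifetable
from alkcea.pipeline import build_context
from alkcea.synthetic import SimulationSpec, default_fixture_set, gen_ipd, make_lifetable

warnings.filterwarnings("ignore", message="age beyond lifetable")


@pytest.fixture(scope="session")
def fixture_set():
    return default_fixture_set(seed=1)


@pytest.fixture(scope="session")
def ctx():
    """Base-case model context with curves taken straight from config."""
    return build_context(seed=1, route="config")


@pytest.fixture(scope="session")
def base_pair(ctx):
    return ctx.run_pair()


@pytest.fixture(scope="session")
def lifetable():
    return Lifetable(make_lifetable())


@pytest.fixture(scope="session")
def zero_lifetable():
    import pandas as pd
    return Lifetable(pd.DataFrame({"age": np.arange(18, 101),
                                   "q_annual": np.zeros(83)}))


@pytest.fixture(scope="session")
def gompertz_ipd():
    """Synthetic adjuvant-trial-like dataset: Gompertz ground truth,
    n=257, ~30% administrative censoring."""
    return gen_ipd(SimulationSpec("gompertz", (0.03, 0.012), n=257,
                                  horizon=52.0, accrual=24.0, seed=7))
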