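import numpy as np
import pytest

from attractortest.experiments import FoodChainEnsemble
from attractortest.series import RegimeSeries
from attractortest.simulators import FoodChainParams, simulate_food_chain


def make_series(values, label="", name="x", times=None, standardized=False):
    values = np.asarray(values, dtype=float)
    if times is None:
        times = np.arange(len(values), dtype=float)
    return RegimeSeries(
        values, times, regime_label=label, variable_name=name,
        standardized=standardized,
    )


@pytest.fixture(scope="session")
def food_chain_trajectories():
    """Deterministic post-burn-in trajectories for the four study regimes."""
    return {
        K: simulate_food_chain(FoodChainParams(K=K))
        for K in (0.78, 0.85, 0.92, 0.997)
    }


@pytest.fixture(scope="session")
def ensemble():
    """Shared replicate factory over cached food-chain trajectories."""
    return FoodChainEnsemble()


@pytest.fixture()
def rng():
    return np.random.default_rng(20210817)
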