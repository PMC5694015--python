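import numpy as np
import pytest

from axisbreak import EmbryoState, ModelParameters


@pytest.fixture
def small_params() -> ModelParameters:
    """A small, fast parameter set for structural tests (not calibrated)."""
    return ModelParameters(n_cells=12, coupling_radius=1)


@pytest.fixture
def ring5() -> EmbryoState:
    B = np.array([3.0, 0.0, 0.0, 0.0, 0.0])
    V = np.array([0.5, 1.0, 0.2, 0.0, 0.7])
    FB = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
    FV = np.array([1.0, 0.0, 0.5, 0.25, 0.75])
    return EmbryoState(B, V, FB, FV)


def random_state(n: int, seed: int, cuts=()) -> EmbryoState:
    rng = np.random.default_rng(seed)
    vals = rng.uniform(0.0, 2.0, size=(4, n))
    return EmbryoState(vals[0], vals[1], vals[2], vals[3], cuts=cuts)
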