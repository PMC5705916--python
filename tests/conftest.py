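import numpy as np
import pytest

from syntrosim import (
    CultureState,
    ModelVariant,
    default_initial_state,
    default_parameters,
)
from syntrosim.model import rhs_array
from syntrosim.params import UNIT_CONV


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def init():
    return default_initial_state()


@pytest.fixture(scope="session")
def batch_trajectory(params, init):
    """One default 300-h batch at affinity ratio 1, shared across tests."""
    from syntrosim import simulate_batch
    return simulate_batch(params, init, 300.0)


def rk4_fixed_step(params, y0, t_end, dt, variant=ModelVariant.DEFAULT):
    """Independent fixed-step RK4 oracle for integrator cross-checks."""
    y = np.asarray(y0, dtype=float).copy()
    t = 0.0
    for _ in range(int(round(t_end / dt))):
        k1 = rhs_array(t, y, params, variant)
        k2 = rhs_array(t + dt / 2, y + dt / 2 * k1, params, variant)
        k3 = rhs_array(t + dt / 2, y + dt / 2 * k2, params, variant)
        k4 = rhs_array(t + dt, y + dt * k3, params, variant)
        y = np.maximum(y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4), 0.0)
        t += dt
    return y


#: per-component scale floors for relative comparisons (cells vs mM)
STATE_SCALE = np.array([1.0, 1.0, 1e-6, 1e-9, 1e-6, 1e-6, 1e-6, 1e-6])


def rel_diff(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return np.abs(a - b) / np.maximum(np.maximum(np.abs(a), np.abs(b)), STATE_SCALE)
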