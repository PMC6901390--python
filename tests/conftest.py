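import math
from dataclasses import replace

import numpy as np
import pytest

import cascadekin as ck


@pytest.fixture(scope="session")
def params():
    return ck.default_params()


@pytest.fixture(scope="session")
def onepot_recipe():
    return ck.builtin_recipe("onepot_standard")


@pytest.fixture(scope="session")
def nmr_recipe():
    return ck.builtin_recipe("nmr_onepot")


@pytest.fixture(scope="session")
def sequential_recipe():
    return ck.builtin_recipe("sequential_paper")


@pytest.fixture(scope="session")
def onepot_course(onepot_recipe):
    """Standard one-pot simulation, shared across tests (read-only)."""
    return ck.simulate_onepot(onepot_recipe)


@pytest.fixture(scope="session")
def nmr_course(nmr_recipe):
    """Noiseless simulation of the isotope-labelled one-pot run."""
    return ck.simulate_onepot(nmr_recipe, ck.nmr_grid())


@pytest.fixture
def no_decay_params(params):
    """Parameter set with thermal deactivation switched off."""
    enzymes = {
        name: replace(e, half_life_h=math.inf) for name, e in params.enzymes.items()
    }
    return params.updated(enzymes=enzymes)


def rk4_trajectory(rhs, y0, t_grid, dt):
    """Independent fixed-step classical RK4 integrator used as an oracle."""
    t_grid = np.asarray(t_grid, dtype=float)
    y = np.asarray(y0, dtype=float).copy()
    out = np.empty((y.size, t_grid.size))
    out[:, 0] = y
    gi = 1
    t = t_grid[0]
    n = int(round((t_grid[-1] - t_grid[0]) / dt))
    for i in range(n):
        k1 = rhs(t, y)
        k2 = rhs(t + dt / 2, y + dt / 2 * k1)
        k3 = rhs(t + dt / 2, y + dt / 2 * k2)
        k4 = rhs(t + dt, y + dt * k3)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t = t_grid[0] + (i + 1) * dt
        while gi < t_grid.size and t_grid[gi] <= t + dt / 2:
            out[:, gi] = y
            gi += 1
    return out
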