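"""Shared fixtures: small DPD systems and analytic point clouds."""

import numpy as np
import pytest

from capsim.builder import make_uniform_gas
from capsim.core import (
    ForceField, S_W, SimulationBox, SimulationState, maxwell_velocities,
)


@pytest.fixture(scope="session")
def standard_ff() -> ForceField:
    return ForceField.standard()


@pytest.fixture()
def solvent_gas():
    """Factory for an ideal DPD fluid (all-W gas) at rho = 3."""

    def _make(edge: float = 5.0, seed: int = 0, kBT: float = 1.0) -> SimulationState:
        box = SimulationBox(edges=[edge] * 3)
        n = int(round(3.0 * box.volume))
        rng = np.random.default_rng(seed)
        state = SimulationState(
            positions=make_uniform_gas(n, box, seed=seed),
            velocities=np.zeros((n, 3)),
            species=np.full(n, S_W, dtype=np.int64),
            box=box,
        )
        state.velocities = maxwell_velocities(n, kBT, rng)
        return state

    return _make


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
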