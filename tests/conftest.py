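import numpy as np
import pytest

from msmselect.synthetic_data import (DiffusionSpec, GroundTruthMSM,
                                      make_three_state_toy,
                                      sample_discrete_trajectories,
                                      simulate_diffusion)


@pytest.fixture(scope="session")
def toy_model() -> GroundTruthMSM:
    return make_three_state_toy()


@pytest.fixture(scope="session")
def toy_dtrajs(toy_model):
    """Moderate-length trajectories from the three-state truth."""
    return sample_discrete_trajectories(toy_model, n_traj=10, length=2000, seed=42)


@pytest.fixture(scope="session")
def two_state_model() -> GroundTruthMSM:
    return GroundTruthMSM.from_matrix(np.array([[0.9, 0.1], [0.2, 0.8]]))


@pytest.fixture(scope="session")
def double_well_traj():
    """One strided double-well Brownian trajectory of 6 independent particles.

    Simulated at dt=2e-3 and strided by 25 so the stored frame interval is
    0.05 time units; the slowest relaxation (interwell hopping) is a few time
    units, i.e. tens of frames.
    """
    spec = DiffusionSpec(potential="double_well", parameters={"barrier": 2.5},
                         diffusion_coefficient=1.0, timestep=2e-3, n_particles=6)
    traj = simulate_diffusion(spec, 500_000, seed=7)[::25]
    return spec, traj


@pytest.fixture(scope="session")
def random_counts():
    """A few dense random count matrices for oracle comparisons."""
    rng = np.random.default_rng(11)
    out = []
    for n in (2, 2, 3, 3, 4):
        C = rng.integers(1, 60, size=(n, n)).astype(float)
        out.append(C)
    return out
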