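import numpy as np
import pytest

from mhcdyn import io as mio
from mhcdyn import synthetic


@pytest.fixture(scope="session")
def toy_complex():
    return synthetic.make_toy_complex()


@pytest.fixture(scope="session")
def toy_kinetics():
    """4-state reversible ground truth with distinct structural offsets."""
    t = synthetic.example_reversible_matrix(4, seed=1)
    # orthogonal anchor/conformational combinations keep the four states
    # distinct in (periodic) dihedral feature space
    return synthetic.KineticSpec(
        transition_matrix=t,
        anchor_displacements=np.array([0.0, 0.0, 3.0, 3.0]),
        conformational_offsets=np.array([0.0, 2.0, 0.0, 2.0]),
        noise_sigma=0.05,
    )


@pytest.fixture(scope="session")
def toy_trajectory(toy_complex, toy_kinetics):
    traj, path = synthetic.make_kinetic_trajectory(
        toy_complex, toy_kinetics, n_frames=400, seed=11
    )
    return traj, path


@pytest.fixture()
def static_trajectory(toy_complex):
    frames = np.repeat(toy_complex.coords[None], 5, axis=0)
    return mio.Trajectory(toy_complex, frames, np.arange(5.0), equilibration_cutoff=0.0)
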