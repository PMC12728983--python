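import numpy as np
import pytest

from polymelt.synth import GaussianMeltSpec, generate_gaussian_melt


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_melt():
    """A small freely-jointed melt shared by conformation/dynamics tests."""
    spec = GaussianMeltSpec(n_chains=64, n_bonds=50, bond_length=0.15,
                            box_length=8.0, n_frames=40, seed=5)
    traj, topo = generate_gaussian_melt(spec)
    return spec, traj, topo
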