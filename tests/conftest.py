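import numpy as np
import pytest

from flexmd.model import Atom, ChannelDefinition, Topology, Trajectory
from flexmd.synthetic import (
    ChannelSimConfig,
    LigaseSimConfig,
    gen_channel_trajectory,
    gen_ligase_trajectory,
)


def make_single_ion_trajectory(z_path, lz=90.0, dt=1.0, species="K", valence=1):
    """A one-ion trajectory whose z follows `z_path` (x = y = 0)."""
    z = np.asarray(z_path, dtype=float)
    top = Topology([Atom(1, species, species, 1, "I", species, valence)])
    coords = np.zeros((len(z), 1, 3))
    coords[:, 0, 2] = z
    times = np.arange(len(z)) * dt
    boxes = np.tile([60.0, 60.0, lz], (len(z), 1))
    return Trajectory(top, times, coords, boxes)


@pytest.fixture
def slab_channel():
    return ChannelDefinition(z_lo=-15.0, z_hi=15.0, voltage=150.0)


@pytest.fixture(scope="session")
def small_channel_sim():
    """A 2 µs gated-channel trajectory with ground truth (cheap, reused)."""
    cfg = ChannelSimConfig(duration=2000.0, seed=11)
    return cfg, *gen_channel_trajectory(cfg)


@pytest.fixture(scope="session")
def ligase_sim():
    """A 500-frame protein mimic with substitution and bridge scripts."""
    cfg = LigaseSimConfig(
        seed=13,
        n_frames=500,
        substitution_script=(250, (28, "GLU", "OE1"), (29, "ASP", "OD1")),
        salt_bridge_script=[(17, 55, 0.6), (61, 43, 0.8)],
    )
    return cfg, *gen_ligase_trajectory(cfg)
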