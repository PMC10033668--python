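import numpy as np
import pytest

from bcri.calibration import effective_volume
from bcri.structure import TrajectoryEnsemble


@pytest.fixture
def focal_cal():
    """Reference-line focal volume: w0 = 0.2 µm, AR = 6."""
    return effective_volume(0.2, 6.0, laser_line=488.0)


@pytest.fixture
def ca_trace():
    """A random-walk Cα trace of 80 residues (reproducible)."""
    rng = np.random.default_rng(11)
    n = 80
    seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), n))
    coords = np.cumsum(rng.normal(0.0, 2.0, (n, 3)), axis=0)
    return seq, np.arange(2, n + 2), coords


def make_bcn_trajectory(n_frames=1, n_env_atoms=0, seed=0, jitter=0.0):
    """Minimal ensemble holding a BCN ring plus optional environment atoms.

    Ring atoms are placed so that C14→C15 runs along +x with the ring
    centroid below the bond midpoint (local y ≈ +y lab axis).
    """
    rng = np.random.default_rng(seed)
    ring = {
        "C11": [-1.5, -1.0, 0.0],
        "C14": [-0.6, 0.0, 0.0],
        "C15": [0.6, 0.0, 0.0],
        "C18": [1.5, -1.0, 0.0],
        "C2": [-3.0, -2.0, 0.0],  # BCN alias of CA, the anchor
    }
    names = list(ring) + [f"X{i}" for i in range(n_env_atoms)]
    res_ids = [7] * len(ring) + [100 + i for i in range(n_env_atoms)]
    res_names = ["BCN"] * len(ring) + ["ALA"] * n_env_atoms
    chains = ["A"] * len(names)
    env = rng.uniform(-8, 8, size=(n_env_atoms, 3))
    base = np.vstack([np.array(list(ring.values())), env]) if n_env_atoms else np.array(
        list(ring.values())
    )
    coords = np.repeat(base[None], n_frames, axis=0)
    if jitter > 0:
        coords = coords + rng.normal(0.0, jitter, coords.shape)
    return TrajectoryEnsemble(
        atom_names=np.array(names),
        res_names=np.array(res_names),
        res_ids=np.array(res_ids),
        chains=np.array(chains),
        coords=coords,
    )
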