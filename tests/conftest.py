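import logging
import warnings

import numpy as np
import pytest

import memfission as mf
from memfission import trajectory_io as tio

logging.getLogger("memfission").setLevel(logging.ERROR)
warnings.filterwarnings("ignore", module="MDAnalysis")


@pytest.fixture(scope="session")
def flat_bilayer():
    """Jitter-free two-plane bilayer at the 2C10:0 PA thickness."""
    return mf.gen_flat_bilayer(200, box_xy=400.0, thickness=36.33,
                               z_jitter=0.0, seed=1)


@pytest.fixture(scope="session")
def brownian_series():
    """1000 Brownian lipids at D = 50 μm² s⁻¹, 500 frames of 100 ps."""
    return mf.gen_brownian_lipids(n=1000, D=50.0, dt=100.0, n_frames=500,
                                  box=400.0, seed=11)


@pytest.fixture(scope="session")
def helfrich_fields():
    """Height-field series with K_C = 25 k_BT, σ = 0, L = 400 Å."""
    _, fields = mf.gen_helfrich_membrane(L=400.0, grid_m=40, K_C=25.0,
                                         sigma=0.0, n_frames=500, seed=5,
                                         make_series=False)
    return fields


@pytest.fixture(scope="session")
def harmonic_windows():
    """41 umbrella windows over a harmonic free-energy well at 17 Å."""
    windows, spec = mf.gen_umbrella_samples(
        "harmonic", {"kappa": 0.02, "z0": 17.0},
        centers=np.arange(0.0, 41.0, 1.0), k=0.776, n_per_window=5000,
        seed=13)
    return windows, spec


@pytest.fixture(scope="session")
def tubulation_movie():
    """Short-tube severing movie: fission scripted at 40 ns."""
    return mf.gen_tubulation_movie(base_lipids=5000, rate_pre=5.0,
                                   rate_post=15.0, fission_time=40.0,
                                   n_frames=70, seed=21, box_xy=420.0)


def single_bead_frame(coords, box, species="DOPC", role="phosphate"):
    """Helper: one-bead-per-lipid Frame + ParticleTable from raw coordinates."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    table = tio.ParticleTable(
        particle_id=np.arange(n), lipid_id=np.arange(n),
        species=np.full(n, species, dtype=object),
        bead_role=np.full(n, role, dtype=object))
    return tio.Frame(0.0, coords, np.asarray(box, dtype=float)), table
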