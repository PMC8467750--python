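import numpy as np
import pytest

from gamdlite import model_systems as ms
from gamdlite import synthetic_data as sd


@pytest.fixture(scope="session")
def double_well_surface():
    surface, key = sd.make_double_well(barrier=5.0, a=2.0, temperature=300.0)
    return surface, key


@pytest.fixture(scope="session")
def complex_fixture():
    """Static-geometry receptor-mG complex (no jitter, always bound)."""
    return sd.synth_complex_trajectory(n_frames=120, seed=11, p_unbind=0.0)


@pytest.fixture(scope="session")
def harmonic_trajectory():
    """Long unboosted harmonic-well run shared by sampling checks."""
    surface = ms.harmonic_well(kappa=2.0)
    spec = ms.LangevinSpec(temperature=300.0, friction=2.0, timestep=0.005,
                           n_steps=200_000, seed=3, x0=(0.0,))
    return surface, spec, ms.run_langevin(surface, spec)


def random_rotation(rng):
    """Uniform random rotation matrix via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
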