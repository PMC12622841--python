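"""Shared fixtures: small trajectories and synthetic samples."""

import numpy as np
import pytest

from k2image.synthetic import (compose_complex, make_phase,
                               procedural_magnitude, simulate_radial_kspace)
from k2image.trajectories import (TrajectorySpec, build_trajectory,
                                  spokes_for_undersampling)


@pytest.fixture(scope="session")
def spec16():
    return TrajectorySpec(w_img=16, n_samples=32,
                          n_spokes=spokes_for_undersampling(16, 4))


@pytest.fixture(scope="session")
def traj16(spec16):
    return build_trajectory(spec16)


@pytest.fixture(scope="session")
def image16():
    mag = procedural_magnitude(16, seed=42)
    return compose_complex(mag, make_phase(mag, seed=43))


@pytest.fixture(scope="session")
def kspace16(image16, traj16):
    return simulate_radial_kspace(image16, traj16)


@pytest.fixture(scope="session")
def spec32():
    return TrajectorySpec(w_img=32, n_samples=64,
                          n_spokes=spokes_for_undersampling(32, 2))


@pytest.fixture(scope="session")
def traj32(spec32):
    return build_trajectory(spec32)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(123)
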