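import numpy as np
import pytest

from veinindex import Hypercube, SkinSimConfig, VesselMask, generate_sample


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_cube(rng):
    """A small random cube covering 400-1000 nm."""
    values = rng.uniform(0.1, 1.0, size=(8, 8, 30))
    return Hypercube(values=values, wavelengths_nm=np.linspace(400, 1000, 30))


@pytest.fixture
def nir_cube(rng):
    """Random cube whose axis covers the 714-882 nm vessel-index window."""
    values = rng.uniform(0.05, 1.0, size=(6, 7, 40))
    return Hypercube(values=values, wavelengths_nm=np.linspace(650, 950, 40))


def make_cube(values, wavelengths=None):
    values = np.asarray(values, dtype=np.float64)
    if wavelengths is None:
        wavelengths = 400.0 + 10.0 * np.arange(values.shape[2])
    return Hypercube(values=values, wavelengths_nm=wavelengths)


@pytest.fixture
def tiny_sample():
    """A small noise-free synthetic sample (fast to generate and search)."""
    cfg = SkinSimConfig(
        height=16,
        width=16,
        wavelengths_nm=np.linspace(400.0, 1000.0, 20),
        n_vessels=1,
        vessel_width_px=(3.0, 4.0),
        vessel_depth_mm=(0.0, 0.5),
        noise_sd=0.0,
        seed=3,
    )
    return generate_sample(cfg)


@pytest.fixture
def random_mask(rng):
    values = np.zeros((8, 8), dtype=bool)
    values[rng.integers(0, 8, 12), rng.integers(0, 8, 12)] = True
    return VesselMask(values=values)
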