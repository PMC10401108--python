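import dataclasses

import numpy as np
import pytest

from ossify import PhantomParams, VolumeLaw, generate_phantom

# A compact but fully featured scene: one cell with seven precursor-bearing
# vesicles of fixed volume, a mineralized slab with canaliculi and
# nanochannels, coarsened to 40 nm voxels so tests stay fast.
SMALL_PARAMS = PhantomParams(
    volume_shape=(96, 96, 96),
    voxel_size=0.04,
    n_cells=1,
    vesicle_density=0.8,
    vesicle_volume_law=VolumeLaw("fixed", 0.05),
    granule_diameter=0.08,
    nanochannel_diameter=0.08,
    cell_radius=1.3,
    frac_empty_vesicles=0.25,
    filling_factor_sd=0.0,
    noise_sd=0.0,
    seed=7,
)


@pytest.fixture(scope="session")
def small_params():
    return SMALL_PARAMS


@pytest.fixture(scope="session")
def small_phantom():
    """Noiseless reference phantom shared across tests (generated once)."""
    return generate_phantom(SMALL_PARAMS)


@pytest.fixture
def regenerate():
    """Re-generate the reference phantom with parameter overrides."""
    def _make(**overrides):
        return generate_phantom(dataclasses.replace(SMALL_PARAMS, **overrides))
    return _make


def make_bimodal_histogram(rng, n_bins=256):
    """Smooth two-Gaussian-mode histogram with known mode positions."""
    mu1 = rng.uniform(40, 90)
    mu2 = rng.uniform(150, 210)
    s1, s2 = rng.uniform(5, 15, size=2)
    a1, a2 = rng.uniform(1e3, 1e5, size=2)
    x = np.arange(n_bins, dtype=float)
    h = a1 * np.exp(-0.5 * ((x - mu1) / s1) ** 2) \
        + a2 * np.exp(-0.5 * ((x - mu2) / s2) ** 2)
    return h, mu1, mu2
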