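import numpy as np
import pytest

from hsiseg import HSICube, extract_patches, make_phantom, make_wavenumber_axis, normalize_patches


@pytest.fixture(scope="session")
def small_phantom() -> HSICube:
    """60x60 phantom with 24 bands: one solid, one striped, one globule band."""
    return make_phantom(height=60, width=60, n_bands=24, seed=7)


@pytest.fixture(scope="session")
def tiny_cube() -> HSICube:
    """Deterministic random 12x14x5 cube for geometry tests."""
    rng = np.random.default_rng(3)
    axis = make_wavenumber_axis(1000.0, 2.0, 5)
    return HSICube(rng.random((12, 14, 5)), axis)


@pytest.fixture(scope="session")
def small_patchset(small_phantom):
    return normalize_patches(extract_patches(small_phantom, 10, 5))
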