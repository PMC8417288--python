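import numpy as np
import pytest

from octafract import PhantomSpec, ScanGeometry, generate_phantom


@pytest.fixture(scope="session")
def geometry():
    return ScanGeometry()


@pytest.fixture(scope="session")
def small_geometry():
    """64-px grid used for fast fractal-oracle comparisons."""
    return ScanGeometry(field_of_view_mm=3.0, grid_size_px=64)


@pytest.fixture(scope="session")
def normal_phantom():
    """Healthy phantom pair (FAZ 0.42 mm^2, no dropout, no artifact)."""
    return generate_phantom(PhantomSpec(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
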