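import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from segmentmar import (  # noqa: E402
    PhantomSpec,
    compute_sector_grid,
    generate_phantom,
    load_extent_model,
)


@pytest.fixture(scope="session")
def default_truth():
    """Default 9-slice LAD phantom: 6-of-24-sector transmural wedge, seed 0."""
    return generate_phantom(PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def default_grid(default_truth):
    return compute_sector_grid(default_truth.stack, default_truth.orient)


@pytest.fixture(scope="session")
def lad_model():
    return load_extent_model("LAD")


def make_annulus(size=128, r_in=14.0, r_out=22.0):
    """Boolean annulus mask centred in a size x size image (pixel units)."""
    rr, cc = np.indices((size, size), dtype=float)
    c = (size - 1) / 2.0
    d = np.hypot(rr - c, cc - c)
    return (d >= r_in) & (d <= r_out), (c, c)
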