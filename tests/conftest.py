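import numpy as np
import pytest

from segcadx import phantom


@pytest.fixture(scope="session")
def small_cohort():
    """A small mixed cohort reused by integration-style unit tests."""
    cfg = phantom.PhantomConfig(
        grid_shape=(64, 64, 64),
        n_scans=6,
        nodules_per_scan=(1, 3),
        diameter_mm=(4.0, 14.0),
        seed=5,
    )
    return phantom.generate_phantom(cfg)


@pytest.fixture(scope="session")
def easy_cohort():
    """Solid >= 8 mm nodules with shape-linked malignancy (easy regime)."""
    cfg = phantom.PhantomConfig(
        grid_shape=(64, 64, 64),
        n_scans=4,
        nodules_per_scan=(1, 2),
        diameter_mm=(8.0, 14.0),
        stratum_mix=(0.0, 0.5, 0.5),
        attenuation_mix={"solid": 1.0, "part_solid": 0.0, "ground_glass": 0.0},
        attribute_link_scale=None,
        seed=6,
    )
    return phantom.generate_phantom(cfg)


def sphere_mask(shape, center, radius):
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius**2
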