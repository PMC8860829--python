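import logging

import numpy as np
import pytest

from osteoload.core import ExplantGeometry, RigidTransform, VolumeScan
from osteoload.synthetic_data import (
    PhantomSpec,
    damage_validation_spec,
    generate_scan_triplet,
)

# crack-clipping warnings are expected noise in phantom generation
logging.getLogger("osteoload.synthetic_data").setLevel(logging.ERROR)


def small_box_scan(shape=(20, 22, 24), box=(slice(5, 15), slice(6, 16), slice(7, 17)),
                   inside=900.0, outside=0.0, voxel_size_um=18.0) -> VolumeScan:
    """A solid-box test volume."""
    v = np.full(shape, outside, dtype=np.float32)
    v[box] = inside
    return VolumeScan(v, voxel_size_um)


@pytest.fixture(scope="session")
def textured_scan() -> VolumeScan:
    """A box volume with seeded internal texture, for registration tests."""
    rng = np.random.default_rng(7)
    v = np.zeros((40, 44, 48), dtype=np.float32)
    v[8:32, 8:36, 8:40] = 900.0
    pores = np.zeros_like(v, dtype=bool)
    pores[10:30, 10:34, 10:38] = rng.random((20, 24, 28)) < 0.05
    v[pores] = 150.0
    return VolumeScan(v, 18.0)


@pytest.fixture(scope="session")
def exact_triplet():
    """Noise-free, perfectly aligned serial-scan triplet with ground truth."""
    spec = damage_validation_spec(seed=1, noise_sd=0.0, misalignment=RigidTransform())
    return generate_scan_triplet(spec)


@pytest.fixture(scope="session")
def default_geometry() -> ExplantGeometry:
    return ExplantGeometry()


# keep property-test runs reproducible across environments
from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("reproducible", deadline=None, derandomize=True)
_hyp_settings.load_profile("reproducible")
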