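import numpy as np
import pytest

from netmtv import (
    PetVolume,
    PhantomConfig,
    SphereSpec,
    generate_phantom,
    paper_like_phantom_config,
)


@pytest.fixture(scope="session")
def lesion_phantom():
    """Baseline phantom with one 25 mm-radius lesion and a physiological
    hot sphere, plus its exclusion mask and ground truth."""
    cfg = paper_like_phantom_config(seed=11)
    vol, excl, truth = generate_phantom(cfg)
    return cfg, vol, excl, truth


@pytest.fixture()
def uniform_volume():
    """Constant-SUV cube at the cohort liver mean, 2 mm voxels."""
    return PetVolume(voxels=np.full((40, 40, 40), 4.41), spacing=(2.0, 2.0, 2.0))


@pytest.fixture()
def two_sphere_config():
    """Two disjoint supra-threshold lesions on a quiet background."""
    return PhantomConfig(
        grid_shape=(60, 60, 40),
        spacing=(2.0, 2.0, 2.0),
        liver_box=((0.0, 1.0), (0.0, 1.0), (0.0, 1.0)),  # negligible liver
        lesions=(
            SphereSpec(center=(30.0, 30.0, 40.0), radius_mm=12.0, suv=12.0),
            SphereSpec(center=(90.0, 90.0, 40.0), radius_mm=8.0, suv=15.0),
        ),
        seed=3,
    )
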