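import numpy as np
import pytest

import orthospect as osp

REF_BOUNDS = np.array([(-25.0, -25.0, 80.0), (25.0, 25.0, 130.0)])
ROI_BOUNDS = np.array([(-40.0, 5.0, -45.0), (40.0, 50.0, 45.0)])


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def noiseless_phantom():
    """One patellofemoral hotspot at uptake ratio 4, no noise, no pose."""
    spec = osp.PhantomSpec(
        hotspots=(osp.Hotspot((0.0, 18.0, 10.0), (12.0, 10.0, 12.0), 4.0),),
        noise="none",
    )
    return osp.make_phantom(spec), spec


@pytest.fixture(scope="session")
def ref_region():
    return osp.ReferenceRegion(REF_BOUNDS, frame_tag="femoral")


@pytest.fixture(scope="session")
def roi_region():
    return osp.ReferenceRegion(ROI_BOUNDS, frame_tag="femoral")


def random_landmarks(rng, side="right"):
    """A random valid landmark set: anatomy-scaled points under a random
    rigid transform."""
    from scipy.spatial.transform import Rotation

    base = {
        "femoral_head_centre": np.array([0.0, 0.0, 380.0]) + rng.normal(0, 15, 3),
        "medial_epicondyle": np.array([-45.0, 0.0, 0.0]) + rng.normal(0, 4, 3),
        "lateral_epicondyle": np.array([45.0, 0.0, 0.0]) + rng.normal(0, 4, 3),
        "talus_centre": np.array([0.0, 0.0, -360.0]) + rng.normal(0, 15, 3),
    }
    R = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    t = rng.normal(0, 100, 3)
    posed = {k: R @ v + t for k, v in base.items()}
    return osp.LandmarkSet(
        medial_epicondyle=posed["medial_epicondyle"],
        lateral_epicondyle=posed["lateral_epicondyle"],
        femoral_head_centre=posed["femoral_head_centre"],
        talus_centre=posed["talus_centre"],
        side=side,
    ), R, t
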