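import numpy as np
import pytest

from lsccframe import LsccLandmarkSet, PhantomSpec, RigidTransform, rotation_about_axis


def random_rotation(rng, max_degrees=25.0):
    """Random rotation of bounded angle (heads are roughly upright, and the
    landmark-set side check assumes the +x=left convention survives)."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(-max_degrees, max_degrees)
    return rotation_about_axis(axis, angle)


def random_rigid(rng, max_degrees=25.0, max_shift=50.0):
    return RigidTransform(
        rotation=random_rotation(rng, max_degrees),
        translation=rng.uniform(-max_shift, max_shift, size=3),
    )


def random_landmark_set(rng, z_jitter=0.3):
    """A plausible, generally non-coplanar bilateral landmark set."""
    s2 = rng.uniform(25.0, 35.0)
    a = rng.uniform(2.0, 4.0)
    pts = np.array(
        [[s2, -a, 0.0], [s2, a, 0.0], [-s2, -a, 0.0], [-s2, a, 0.0]]
    )
    pts += rng.uniform(-0.2, 0.2, size=(4, 3))
    pts[:, 2] += rng.uniform(-z_jitter, z_jitter, size=4)
    t = random_rigid(rng)
    pts = t.apply_many(pts)
    return LsccLandmarkSet(
        left_anterior=pts[0], left_posterior=pts[1],
        right_anterior=pts[2], right_posterior=pts[3],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def square_landmarks():
    """Symmetric planar configuration aligned with the world axes."""
    return LsccLandmarkSet(
        left_anterior=(10.0, -5.0, 0.0),
        left_posterior=(10.0, 5.0, 0.0),
        right_anterior=(-10.0, -5.0, 0.0),
        right_posterior=(-10.0, 5.0, 0.0),
    )


@pytest.fixture
def small_spec():
    """A scaled-down phantom: coarser grids and fewer patients keep
    image-level tests fast while preserving the geometry's structure."""
    return PhantomSpec(
        ear_separation=16.0,
        n_patients=4,
        voxel_spacing={"CT": (0.5, 0.5, 0.5), "MR": (0.6, 0.6, 0.7)},
        scene_offset=(15.0, 10.0, 10.0),
        patient_pose_sigma_mm=1.5,
        patient_pose_sigma_deg=3.0,
        repositioning_sigma_mm=1.0,
        repositioning_sigma_deg=1.5,
    )
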