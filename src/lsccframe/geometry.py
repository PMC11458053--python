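"""Anatomical coordinate frames from lateral-semicircular-canal landmarks.

The frame is built from four labelled points — the anterior and posterior
junctions of the left and right lateral semicircular canals (LSCC) with the
vestibule — expressed in a right-handed LPS-like world convention
(+x right→left, +y anterior→posterior, +z inferior→superior, millimetres):

1. fit a total-least-squares plane to the four landmarks;
2. orthogonally project the landmarks onto that plane;
3. origin = mean of the four projections;
4. x axis through the midpoints of the anterior–posterior segments on each
   side, directed right→left;
5. y axis = in-plane anterior→posterior direction orthogonal to x;
6. z axis = x × y (right-handed, inferior→superior);
7. finally tilt the y/z axes about the x axis (default +20°, right-hand
   rule about +x) so the frame's horizontal plane sits near the Reid
   horizontal plane rather than the canal plane itself.

Mapping a volume or point set of each modality into its own LSCC frame
places all of them in a shared patient-independent coordinate system, which
is what makes multi-modal co-registration a by-product of the construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryError, InputError

__all__ = [
    "Point3",
    "as_point",
    "Plane",
    "LsccLandmarkSet",
    "RigidFrame",
    "RigidTransform",
    "fit_plane_total_least_squares",
    "project_onto_plane",
    "rotation_about_axis",
    "build_lscc_frame",
    "frame_difference",
    "world_to_frame",
    "frame_to_world",
    "compose",
    "invert",
]

#: A 3-vector of world coordinates in millimetres (LPS-like convention).
Point3 = np.ndarray

_ORTHONORMALITY_TOL = 1e-10
_UNIT_TOL = 1e-12


def as_point(p) -> Point3:
    """Coerce ``p`` to a finite float ``(3,)`` array."""
    arr = np.asarray(p, dtype=float)
    if arr.shape != (3,):
        raise InputError(f"expected a 3-vector, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise InputError(f"point has non-finite components: {arr}")
    return arr


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n == 0.0:
        raise DegenerateGeometryError(f"{what} has zero length")
    return v / n


@dataclass(frozen=True)
class Plane:
    """A plane as unit normal + a point on it (the fit centroid).

    The normal is deterministic: its z component is non-negative
    (superior-pointing); at z == 0 a non-negative y component breaks the
    tie, then non-negative x.
    """

    normal: np.ndarray
    centroid: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "normal", np.asarray(self.normal, dtype=float))
        object.__setattr__(self, "centroid", as_point(self.centroid))
        if abs(np.linalg.norm(self.normal) - 1.0) > _UNIT_TOL:
            raise InputError("plane normal must be a unit vector")

    def signed_distance(self, p) -> float:
        """Signed orthogonal distance of ``p`` from the plane (mm)."""
        return float(np.dot(as_point(p) - self.centroid, self.normal))


def _canonical_normal(n: np.ndarray) -> np.ndarray:
    x, y, z = n
    if z < 0 or (z == 0 and (y < 0 or (y == 0 and x < 0))):
        return -n
    return n


def fit_plane_total_least_squares(points) -> Plane:
    """Fit a plane minimizing summed squared *orthogonal* distances.

    The solution is the classical one: centroid of the points plus the
    singular direction of least variance of the centered coordinates.
    Orthogonal (total) least squares — rather than a z-on-(x,y)
    regression — is required for the construction to be self-consistent,
    because the landmarks are subsequently projected orthogonally onto
    this same plane.

    Parameters
    ----------
    points : sequence of 3-vectors, length >= 3

    Raises
    ------
    DegenerateGeometryError
        If the points are coincident or collinear (no unique plane).
    """
    pts = np.asarray([as_point(p) for p in points], dtype=float)
    if pts.shape[0] < 3:
        raise DegenerateGeometryError(
            f"plane fit needs at least 3 points, got {pts.shape[0]}"
        )
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    # Smallest principal direction of the centered cloud = plane normal.
    _, s, vt = np.linalg.svd(centered, full_matrices=True)
    sv = np.zeros(3)
    sv[: len(s)] = s
    scale = max(sv[0], 1.0)
    if sv[1] <= 1e-12 * scale:
        raise DegenerateGeometryError(
            "points are collinear or coincident; they do not define a plane: "
            + np.array2string(pts, precision=4)
        )
    normal = _canonical_normal(vt[2])
    return Plane(normal=normal, centroid=centroid)


def project_onto_plane(p, plane: Plane) -> Point3:
    """Orthogonal projection of ``p`` onto ``plane``."""
    p = as_point(p)
    return p - plane.signed_distance(p) * plane.normal


def rotation_about_axis(axis, angle_degrees: float) -> np.ndarray:
    """Rotation matrix about a unit ``axis`` by ``angle_degrees`` (Rodrigues,
    right-hand rule)."""
    axis = np.asarray(axis, dtype=float)
    n = float(np.linalg.norm(axis))
    if n == 0.0:
        raise DegenerateGeometryError("rotation axis must be nonzero")
    if abs(n - 1.0) > 1e-9:
        raise InputError(f"rotation axis must be a unit vector (norm {n:.3g})")
    return Rotation.from_rotvec(np.deg2rad(angle_degrees) * axis).as_matrix()


@dataclass(frozen=True)
class LsccLandmarkSet:
    """The four labelled LSCC landmarks defining one frame (world mm).

    In the +x=left world convention the two left landmarks must have
    strictly greater x than the two right landmarks; a violation is
    rejected rather than silently reordered, because swapped labels in a
    clinical table are a data-entry error worth surfacing.
    """

    left_anterior: np.ndarray
    left_posterior: np.ndarray
    right_anterior: np.ndarray
    right_posterior: np.ndarray

    def __post_init__(self):
        for name in ("left_anterior", "left_posterior", "right_anterior", "right_posterior"):
            object.__setattr__(self, name, as_point(getattr(self, name)))
        left_x = min(self.left_anterior[0], self.left_posterior[0])
        right_x = max(self.right_anterior[0], self.right_posterior[0])
        if not left_x > right_x:
            raise InputError(
                "left landmarks must have strictly greater x than right "
                f"landmarks in the +x=left convention (left min x {left_x:.4g}, "
                f"right max x {right_x:.4g}); labels look swapped or mis-sided"
            )
        pts = self.as_array()
        centered = pts - pts.mean(axis=0)
        if np.linalg.svd(centered, compute_uv=False)[1] <= 1e-12 * max(
            np.linalg.norm(centered), 1.0
        ):
            raise DegenerateGeometryError("the four landmarks are collinear")

    def as_array(self) -> np.ndarray:
        """Points stacked as rows: LA, LP, RA, RP."""
        return np.array(
            [self.left_anterior, self.left_posterior, self.right_anterior, self.right_posterior]
        )


@dataclass(frozen=True)
class RigidFrame:
    """An anatomical frame: origin (world mm) + rotation whose columns are
    the frame axes expressed in world coordinates."""

    origin: np.ndarray
    rotation: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "origin", as_point(self.origin))
        R = np.asarray(self.rotation, dtype=float)
        object.__setattr__(self, "rotation", R)
        _check_rotation(R)

    def world_to_frame(self, p) -> Point3:
        return self.rotation.T @ (as_point(p) - self.origin)

    def frame_to_world(self, p) -> Point3:
        return self.rotation @ as_point(p) + self.origin

    def as_transform(self) -> "RigidTransform":
        """The world→frame rigid map this frame induces."""
        return RigidTransform(
            rotation=self.rotation.T, translation=-self.rotation.T @ self.origin
        )


def _check_rotation(R: np.ndarray) -> None:
    if R.shape != (3, 3):
        raise InputError(f"rotation must be 3x3, got {R.shape}")
    if not np.all(np.isfinite(R)):
        raise InputError("rotation has non-finite entries")
    if np.max(np.abs(R.T @ R - np.eye(3))) > _ORTHONORMALITY_TOL:
        raise InputError("rotation is not orthonormal")
    if abs(np.linalg.det(R) - 1.0) > _ORTHONORMALITY_TOL:
        raise InputError("rotation must have determinant +1 (no reflections)")


@dataclass(frozen=True)
class RigidTransform:
    """A rigid map p ↦ rotation·p + translation (mm).

    Built from a :class:`RigidFrame` via :meth:`RigidFrame.as_transform` it
    maps world coordinates to frame coordinates.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", as_point(self.translation))
        _check_rotation(R)

    def apply(self, p) -> Point3:
        return self.rotation @ as_point(p) + self.translation

    def apply_many(self, pts) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return pts @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(rotation=np.eye(3), translation=np.zeros(3))

    def as_matrix(self) -> np.ndarray:
        """4×4 homogeneous matrix (row-major when serialized)."""
        H = np.eye(4)
        H[:3, :3] = self.rotation
        H[:3, 3] = self.translation
        return H

    @classmethod
    def from_matrix(cls, H) -> "RigidTransform":
        H = np.asarray(H, dtype=float)
        if H.shape != (4, 4) or np.max(np.abs(H[3] - [0, 0, 0, 1])) > 1e-12:
            raise InputError("expected a 4x4 homogeneous rigid matrix")
        return cls(rotation=H[:3, :3], translation=H[:3, 3])

    def to_json(self) -> str:
        """Serialize as a homogeneous-matrix sidecar with a convention tag."""
        return json.dumps(
            {
                "convention": "LPS",
                "units": "mm",
                "order": "row-major",
                "matrix": self.as_matrix().tolist(),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "RigidTransform":
        doc = json.loads(text)
        if doc.get("convention") != "LPS":
            raise InputError(
                f"transform sidecar uses convention {doc.get('convention')!r}; "
                "only 'LPS' is supported"
            )
        return cls.from_matrix(np.asarray(doc["matrix"], dtype=float))


def world_to_frame(t: RigidTransform, p) -> Point3:
    """Apply a world→frame transform to a world point."""
    return t.apply(p)


def frame_to_world(t: RigidTransform, p) -> Point3:
    """Apply the inverse of a world→frame transform to a frame point."""
    return invert(t).apply(p)


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """The transform applying ``b`` first, then ``a``: (a∘b)(p) = a(b(p))."""
    return RigidTransform(
        rotation=a.rotation @ b.rotation,
        translation=a.rotation @ b.translation + a.translation,
    )


def invert(t: RigidTransform) -> RigidTransform:
    return RigidTransform(rotation=t.rotation.T, translation=-t.rotation.T @ t.translation)


def frame_difference(a: RigidFrame, b: RigidFrame) -> tuple[float, float]:
    """Origin distance (mm) and rotation geodesic angle (rad) between frames.

    The angle uses ‖Ra−Rb‖_F = 2√2·sin(θ/2), which keeps full precision
    for nearly identical frames.
    """
    origin_err = float(np.linalg.norm(a.origin - b.origin))
    fro = np.linalg.norm(a.rotation - b.rotation)
    angle = float(2.0 * np.arcsin(min(1.0, fro / (2.0 * np.sqrt(2.0)))))
    return origin_err, angle


def build_lscc_frame(landmarks: LsccLandmarkSet, tilt_degrees: float = 20.0) -> RigidFrame:
    """Construct the LSCC coordinate frame from four labelled landmarks.

    Parameters
    ----------
    landmarks
        The four LSCC landmarks in world mm (LPS-like convention).
    tilt_degrees
        Signed rotation of the y/z axes about the frame x axis applied
        last, right-hand rule about +x (which points right→left). The
        default +20° tips the frame's xy plane from the canal plane toward
        the Reid horizontal plane. The sense is configurable because
        "clockwise" depends on the viewing direction; pass a negative
        angle for the opposite convention.

    Returns
    -------
    RigidFrame
        Origin at the mean of the four projected landmarks; rotation
        columns are the frame x, y, z axes in world coordinates.
    """
    if not np.isfinite(tilt_degrees):
        raise InputError("tilt_degrees must be finite")
    plane = fit_plane_total_least_squares(landmarks.as_array())
    la = project_onto_plane(landmarks.left_anterior, plane)
    lp = project_onto_plane(landmarks.left_posterior, plane)
    ra = project_onto_plane(landmarks.right_anterior, plane)
    rp = project_onto_plane(landmarks.right_posterior, plane)

    origin = (la + lp + ra + rp) / 4.0

    left_mid = (la + lp) / 2.0
    right_mid = (ra + rp) / 2.0
    if np.linalg.norm(left_mid - right_mid) < 1e-12:
        raise DegenerateGeometryError("left and right landmark midpoints coincide")
    x_axis = _unit(left_mid - right_mid, "left-right midpoint segment")

    ap = (lp + rp) / 2.0 - (la + ra) / 2.0  # anterior→posterior
    y0 = ap - np.dot(ap, x_axis) * x_axis
    if np.linalg.norm(y0) < 1e-12:
        raise DegenerateGeometryError(
            "anterior and posterior midpoints coincide along the x axis"
        )
    y_axis = _unit(y0, "in-plane anterior-posterior direction")
    z_axis = np.cross(x_axis, y_axis)

    if tilt_degrees != 0.0:
        tilt = rotation_about_axis(x_axis, tilt_degrees)
        y_axis = tilt @ y_axis
        z_axis = tilt @ z_axis

    return RigidFrame(origin=origin, rotation=np.column_stack([x_axis, y_axis, z_axis]))
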