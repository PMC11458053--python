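"""Synthetic ground-truth landmarks and phantom volumes.

The generator emulates the geometry and measurement process the
evaluation statistics assume: a bilateral, mirror-symmetric pair of
lateral semicircular canals whose four vestibule-junction landmarks lie
exactly on a plane tilted (default 20°) from the world horizontal about
the left–right axis; held-out superior-canal (SSCC) probe points above
that plane; per-patient and per-scan rigid head poses; per-rater Gaussian
selection jitter; and quantization of every selection to the modality's
voxel grid. Because the truth is known exactly, frame-construction error,
target registration error and the reliability statistics can all be
checked against closed-form or Monte-Carlo expectations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import InputError
from .geometry import (
    LsccLandmarkSet,
    RigidFrame,
    RigidTransform,
    rotation_about_axis,
)
from .image import ImageVolume
from .io import ALL_LABELS, CT_SPACING, LSCC_LABELS, MR_SPACING, LandmarkObservation

__all__ = [
    "PhantomSpec",
    "LandmarkTruth",
    "SimulatedStudy",
    "generate_landmark_truth",
    "simulate_observations",
    "rasterize_phantom",
]


def _random_rigid(rng: np.random.Generator, sigma_mm: float, sigma_deg: float) -> RigidTransform:
    """Small random rigid motion: rotation angle and translation components
    drawn from centered normals."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.normal(0.0, sigma_deg)
    return RigidTransform(
        rotation=rotation_about_axis(axis, angle),
        translation=rng.normal(0.0, sigma_mm, size=3),
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic bilateral-labyrinth study.

    Defaults describe a realistic adult temporal-bone geometry: canal
    radius of curvature ~3 mm, labyrinths ~64 mm apart, canal plane
    tilted 20° from the horizontal, selection jitter of 0.1 mm per axis
    (on the order of one CT voxel), and the CT/MR acquisition voxel
    spacings.
    """

    canal_radius: float = 3.0  # mm; half the anterior–posterior landmark separation
    ear_separation: float = 64.0  # mm between left and right canal centers
    plane_tilt_degrees: float = 20.0  # canal plane vs world horizontal, about x
    sscc_height: float = 4.0  # mm superior offset of the SSCC probe points
    canal_tube_radius: float = 0.65  # mm lumen radius used when rasterizing
    n_patients: int = 20
    raters: tuple[str, ...] = ("A", "B", "C")
    n_attempts: int = 2
    #: selection jitter SD in mm, per rater (fallback key "*") and axis
    jitter_sigma: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {"*": (0.1, 0.1, 0.1)}
    )
    voxel_spacing: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {"CT": CT_SPACING, "MR": MR_SPACING}
    )
    #: systematic scanner-table pose per modality (applied after the
    #: patient pose); MR differs from CT by a few degrees / millimetres
    modality_pose: Mapping[str, RigidTransform] = field(
        default_factory=lambda: {
            "CT": RigidTransform.identity(),
            "MR": RigidTransform(
                rotation=rotation_about_axis(
                    np.array([0.2672612419124244, 0.5345224838248488, 0.8017837257372732]), 4.0
                ),
                translation=np.array([1.5, -1.0, 2.0]),
            ),
        }
    )
    #: per-patient anatomy placement scatter (head position in the scanner)
    patient_pose_sigma_mm: float = 3.0
    patient_pose_sigma_deg: float = 4.0
    #: additional per-scan repositioning between the patient's CT and MR
    repositioning_sigma_mm: float = 2.0
    repositioning_sigma_deg: float = 2.0
    #: world offset keeping all voxel indices non-negative
    scene_offset: tuple[float, float, float] = (55.0, 25.0, 25.0)
    seed: int = 0

    def __post_init__(self):
        if self.canal_radius <= 0 or self.ear_separation <= 0:
            raise InputError("canal_radius and ear_separation must be positive")
        if any(s < 0 for v in self.jitter_sigma.values() for s in v):
            raise InputError("jitter sigma must be >= 0")
        if self.n_patients < 1 or self.n_attempts < 1 or len(self.raters) < 1:
            raise InputError("need at least one patient, rater and attempt")
        for mod, sp in self.voxel_spacing.items():
            if any(s <= 0 for s in sp):
                raise InputError(f"non-positive voxel spacing for {mod}")

    def sigma_for(self, rater: str) -> np.ndarray:
        sig = self.jitter_sigma.get(rater, self.jitter_sigma.get("*"))
        if sig is None:
            raise InputError(f"no jitter sigma for rater {rater!r} and no '*' fallback")
        return np.asarray(sig, dtype=float)


@dataclass(frozen=True)
class LandmarkTruth:
    """Exact landmark geometry: canonical points plus per-modality copies
    under each modality's systematic pose."""

    canonical: dict[str, np.ndarray]  # label -> world mm (scene-offset applied)
    per_modality: dict[str, dict[str, np.ndarray]]

    def lscc_set(self, modality: str | None = None) -> LsccLandmarkSet:
        pts = self.canonical if modality is None else self.per_modality[modality]
        return LsccLandmarkSet(
            left_anterior=pts["left_anterior"],
            left_posterior=pts["left_posterior"],
            right_anterior=pts["right_anterior"],
            right_posterior=pts["right_posterior"],
        )


def generate_landmark_truth(spec: PhantomSpec) -> LandmarkTruth:
    """Exact landmark positions implied by a phantom specification.

    The four LSCC landmarks are mirror-symmetric across the mid-sagittal
    plane and exactly coplanar on the plane obtained by rotating the
    world horizontal by ``-plane_tilt_degrees`` about +x, so that
    building a frame with ``tilt_degrees = plane_tilt_degrees`` recovers
    a world-axis-aligned orientation. SSCC probes sit superior to the
    canal plane, off-plane by construction.
    """
    s2 = spec.ear_separation / 2.0
    a = spec.canal_radius
    flat = {
        "left_anterior": np.array([s2, -a, 0.0]),
        "left_posterior": np.array([s2, a, 0.0]),
        "right_anterior": np.array([-s2, -a, 0.0]),
        "right_posterior": np.array([-s2, a, 0.0]),
        "left_superior_sscc": np.array([s2, 0.0, spec.sscc_height]),
        "right_superior_sscc": np.array([-s2, 0.0, spec.sscc_height]),
    }
    tilt = rotation_about_axis(np.array([1.0, 0.0, 0.0]), -spec.plane_tilt_degrees)
    offset = np.asarray(spec.scene_offset, dtype=float)
    canonical = {lab: tilt @ p + offset for lab, p in flat.items()}
    per_modality = {
        mod: {lab: spec.modality_pose[mod].apply(p) for lab, p in canonical.items()}
        for mod in spec.voxel_spacing
    }
    return LandmarkTruth(canonical=canonical, per_modality=per_modality)


@dataclass(frozen=True)
class SimulatedStudy:
    """A simulated landmark-selection study with its generating truth."""

    observations: list[LandmarkObservation]
    #: (patient, modality) -> rigid map canonical scene → scan world
    poses: dict[tuple[str, str], RigidTransform]
    #: (patient, modality, label) -> exact (pre-jitter) world position
    true_points: dict[tuple[str, str, str], np.ndarray]
    spec: PhantomSpec


def _quantize(p: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    idx = np.round(p / spacing)
    if np.any(idx < 0):
        raise InputError(
            f"quantized landmark fell outside the non-negative voxel grid: {p}; "
            "increase PhantomSpec.scene_offset"
        )
    return idx * spacing


def simulate_observations(
    truth: LandmarkTruth,
    spec: PhantomSpec,
    *,
    seed: int | None = None,
    include_sscc: bool = True,
) -> SimulatedStudy:
    """Simulate expert landmark selections for a whole study.

    For every patient a random anatomy pose is drawn, plus an independent
    per-scan repositioning for each modality on top of the modality's
    systematic pose. Each rater × attempt selection is the posed true
    point plus zero-mean Gaussian jitter (per-rater, per-axis SD), rounded
    to the nearest voxel of that modality's grid. Deterministic for a
    given seed.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    labels = ALL_LABELS if include_sscc else LSCC_LABELS
    observations: list[LandmarkObservation] = []
    poses: dict[tuple[str, str], RigidTransform] = {}
    true_points: dict[tuple[str, str, str], np.ndarray] = {}
    offset = np.asarray(spec.scene_offset, dtype=float)

    for pi in range(spec.n_patients):
        patient = f"P{pi + 1:02d}"
        patient_pose = _random_rigid(rng, spec.patient_pose_sigma_mm, spec.patient_pose_sigma_deg)
        for modality in spec.voxel_spacing:
            spacing = np.asarray(spec.voxel_spacing[modality], dtype=float)
            repositioning = _random_rigid(
                rng, spec.repositioning_sigma_mm, spec.repositioning_sigma_deg
            )
            # poses act on centered anatomy; the scene offset is re-applied
            # afterwards so the random translations do not scale with it
            def pose_point(p, _chain=(repositioning, spec.modality_pose[modality], patient_pose)):
                q = p - offset
                for t in reversed(_chain):
                    q = t.apply(q)
                return q + offset
            R = repositioning.rotation @ spec.modality_pose[modality].rotation @ patient_pose.rotation
            t = pose_point(np.zeros(3) + offset) - R @ offset
            poses[(patient, modality)] = RigidTransform(rotation=R, translation=t)
            for label in labels:
                p_true = pose_point(truth.canonical[label])
                true_points[(patient, modality, label)] = p_true
                for rater in spec.raters:
                    sigma = spec.sigma_for(rater)
                    for attempt in range(1, spec.n_attempts + 1):
                        jitter = rng.normal(0.0, 1.0, size=3) * sigma
                        pos = _quantize(p_true + jitter, spacing)
                        observations.append(
                            LandmarkObservation(
                                patient_id=patient,
                                modality=modality,
                                rater_id=rater,
                                attempt=attempt,
                                label=label,
                                position=pos,
                            )
                        )
    return SimulatedStudy(
        observations=observations, poses=poses, true_points=true_points, spec=spec
    )


# ---------------------------------------------------------------------------
# phantom rasterization


def rasterize_phantom(
    spec: PhantomSpec,
    modality: str,
    *,
    pose: RigidTransform | None = None,
    margin_mm: float = 4.0,
    dims=None,
    origin=None,
) -> ImageVolume:
    """Render the phantom labyrinth into a modality-like volume.

    Each side carries the lateral half-arc of an LSCC torus (lumen radius
    ``canal_tube_radius``) whose endpoints are exactly the anterior and
    posterior landmarks, an ellipsoidal vestibule whose surface passes
    through those landmarks, and a small SSCC knob at the probe point.
    CT-like volumes show dark lumen inside bright bone; MR-like volumes
    show bright fluid on a dark background, i.e. inverted contrast.
    """
    if modality not in spec.voxel_spacing:
        raise InputError(f"unknown modality {modality!r}; spec defines {list(spec.voxel_spacing)}")
    spacing = np.asarray(spec.voxel_spacing[modality], dtype=float)
    truth = generate_landmark_truth(spec)
    pts = np.array([truth.per_modality[modality][lab] for lab in ALL_LABELS])
    if pose is not None:
        pts = pose.apply_many(pts)
    pad = spec.canal_radius + spec.canal_tube_radius + margin_mm
    lo = pts.min(axis=0) - pad
    hi = pts.max(axis=0) + pad
    if origin is None:
        origin = lo
    origin = np.asarray(origin, dtype=float)
    if dims is None:
        dims = np.ceil((hi - origin) / spacing).astype(int) + 1
    dims = np.asarray(dims, dtype=int)
    if np.any(origin > lo + 1e-9) or np.any(origin + (dims - 1) * spacing < hi - 1e-9):
        raise InputError(
            f"volume (origin {origin}, dims {dims}) too small to contain the "
            f"phantom geometry spanning {lo}..{hi}"
        )

    # world coordinates of every voxel, mapped back to plane-local coords
    ii = origin[0] + spacing[0] * np.arange(dims[0])
    jj = origin[1] + spacing[1] * np.arange(dims[1])
    kk = origin[2] + spacing[2] * np.arange(dims[2])
    X, Y, Z = np.meshgrid(ii, jj, kk, indexing="ij")
    world = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)

    total = spec.modality_pose[modality]
    if pose is not None:
        total = RigidTransform(
            rotation=pose.rotation @ total.rotation,
            translation=pose.rotation @ total.translation + pose.translation,
        )
    # undo total pose, scene offset and plane tilt → flat canal coordinates
    local = (world - total.translation) @ total.rotation
    local = local - np.asarray(spec.scene_offset, dtype=float)
    untilt = rotation_about_axis(np.array([1.0, 0.0, 0.0]), spec.plane_tilt_degrees)
    local = local @ untilt.T

    a, tube = spec.canal_radius, spec.canal_tube_radius
    lumen = np.zeros(local.shape[0], dtype=bool)
    for side in (1.0, -1.0):
        center = np.array([side * spec.ear_separation / 2.0, 0.0, 0.0])
        rel = local - center
        # lateral half-torus whose endpoints are the two landmarks
        rho = np.hypot(rel[:, 0], rel[:, 1])
        torus_d = np.hypot(rho - a, rel[:, 2])
        lateral = side * rel[:, 0] >= 0
        lumen |= (torus_d <= tube) & lateral
        # vestibule ellipsoid through the landmarks (semi-axis a along y)
        semi = np.array([2.0, a, 2.2])
        lumen |= np.sum((rel / semi) ** 2, axis=1) <= 1.0
        # SSCC knob at the probe point
        probe = np.array([side * spec.ear_separation / 2.0, 0.0, spec.sscc_height])
        lumen |= np.linalg.norm(local - probe, axis=1) <= 1.0

    lumen = lumen.reshape(tuple(dims))
    if modality.upper().startswith("CT"):
        data = np.where(lumen, 0.0, 1000.0).astype(np.float32)  # dark lumen in bone
    else:
        data = np.where(lumen, 1000.0, 0.0).astype(np.float32)  # bright fluid
    return ImageVolume.from_spacing(data, spacing, origin=origin)
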