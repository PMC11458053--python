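"""Volume resampling into an LSCC frame and multi-modal co-registration.

Volumes carry an affine mapping 0-based voxel indices to world millimetres
in the LPS convention (+x left, +y posterior, +z superior). NIfTI files,
which conventionally use RAS world coordinates, are converted at the I/O
boundary by negating the x and y rows of the affine.

Resampling every modality of a patient into its own LSCC frame on a shared
isotropic grid places the volumes in one patient-independent coordinate
system — co-registration falls out of the frame construction with no
intensity-based optimisation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import InputError
from .geometry import RigidFrame, compose, invert

__all__ = [
    "ImageVolume",
    "load_nifti",
    "save_nifti",
    "resample_to_frame",
    "coregister_pair",
    "overlay_slices",
    "DEFAULT_OUT_SPACING",
]

#: Isotropic output spacing (mm) for frame-space grids; the coarser of the
#: two acquisition in-plane spacings, so neither modality is upsampled far
#: beyond its native resolution.
DEFAULT_OUT_SPACING = 0.2604

_RAS_TO_LPS = np.diag([-1.0, -1.0, 1.0, 1.0])

_INTERPOLATION_ORDERS = {"nearest": 0, "linear": 1, "cubic": 3}


@dataclass
class ImageVolume:
    """Intensities on a voxel grid plus a voxel→world (LPS, mm) affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise InputError(f"volume must be 3-D, got {self.data.ndim}-D")
        if self.affine.shape != (4, 4):
            raise InputError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-15:
            raise InputError("affine linear part is singular")

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel spacing (mm): column norms of the affine."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape(self):
        return self.data.shape

    def voxel_to_world(self, index) -> np.ndarray:
        idx = np.asarray(index, dtype=float)
        return self.affine[:3, :3] @ idx + self.affine[:3, 3]

    def world_to_voxel(self, p) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        return np.linalg.solve(self.affine[:3, :3], p - self.affine[:3, 3])

    @property
    def center_world(self) -> np.ndarray:
        """World position of the grid's geometric center, (dims−1)/2."""
        return self.voxel_to_world((np.asarray(self.shape) - 1) / 2.0)

    @classmethod
    def from_spacing(cls, data, spacing, origin=(0.0, 0.0, 0.0)) -> "ImageVolume":
        """Axis-aligned volume: world = index × spacing + origin (LPS)."""
        affine = np.eye(4)
        affine[:3, :3] = np.diag(np.asarray(spacing, dtype=float))
        affine[:3, 3] = origin
        return cls(data=np.asarray(data), affine=affine)


def load_nifti(path) -> ImageVolume:
    """Load a NIfTI-1 volume, converting its RAS affine to LPS."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"NIfTI file not found: {path}")
    try:
        img = nib.load(path)
        data = np.asarray(img.dataobj, dtype=np.float32)
        affine = img.affine
    except Exception as exc:  # nibabel raises several classes for bad files
        raise InputError(f"cannot read NIfTI file {path}: {exc}") from exc
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    return ImageVolume(data=data, affine=_RAS_TO_LPS @ affine)


def save_nifti(vol: ImageVolume, path) -> None:
    """Write a volume as NIfTI-1 (affine converted back to RAS)."""
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), _RAS_TO_LPS @ vol.affine)
    nib.save(img, str(path))


def _default_out_dims(vol: ImageVolume, out_spacing: np.ndarray) -> np.ndarray:
    extent = np.asarray(vol.shape) * vol.spacing
    return np.maximum(np.ceil(extent / out_spacing).astype(int), 1)


def resample_to_frame(
    vol: ImageVolume,
    frame: RigidFrame,
    out_spacing=DEFAULT_OUT_SPACING,
    out_dims=None,
    *,
    interpolation: str = "linear",
    fill: float = 0.0,
) -> ImageVolume:
    """Resample a volume onto an isotropic grid aligned with ``frame``.

    The frame origin maps to the output grid's geometric center
    ((dims−1)/2 in index space), and the output affine expresses voxel
    indices directly in frame coordinates, so the returned volume lives in
    the anatomical frame. Out-of-field voxels take ``fill``.

    ``interpolation`` is ``"linear"`` (trilinear, default), ``"nearest"``
    or ``"cubic"``.
    """
    if interpolation not in _INTERPOLATION_ORDERS:
        raise InputError(
            f"interpolation must be one of {sorted(_INTERPOLATION_ORDERS)}, got {interpolation!r}"
        )
    order = _INTERPOLATION_ORDERS[interpolation]
    out_spacing = np.broadcast_to(np.asarray(out_spacing, dtype=float), (3,)).copy()
    if np.any(out_spacing <= 0):
        raise InputError("out_spacing must be positive")
    if out_dims is None:
        out_dims = _default_out_dims(vol, out_spacing)
    out_dims = np.asarray(out_dims, dtype=int)
    if np.any(out_dims < 1):
        raise InputError("out_dims must be >= 1 per axis")

    center = (out_dims - 1) / 2.0
    # out index v → frame coords f = S(v − c) → world w = R f + o → in index.
    R, o = frame.rotation, frame.origin
    A_in = vol.affine
    lin_world = R @ np.diag(out_spacing)
    off_world = o - lin_world @ center
    A_in_inv_lin = np.linalg.inv(A_in[:3, :3])
    matrix = A_in_inv_lin @ lin_world
    offset = A_in_inv_lin @ (off_world - A_in[:3, 3])

    out = ndimage.affine_transform(
        np.asarray(vol.data, dtype=float),
        matrix=matrix,
        offset=offset,
        output_shape=tuple(out_dims),
        order=order,
        mode="constant",
        cval=float(fill),
        prefilter=order > 1,
    )
    out_affine = np.eye(4)
    out_affine[:3, :3] = np.diag(out_spacing)
    out_affine[:3, 3] = -out_spacing * center
    return ImageVolume(data=out, affine=out_affine)


def coregister_pair(
    ct: ImageVolume,
    ct_landmarks,
    mr: ImageVolume,
    mr_landmarks,
    *,
    out_spacing=DEFAULT_OUT_SPACING,
    out_dims=None,
    tilt_degrees: float = 20.0,
    interpolation: str = "linear",
    fill: float = 0.0,
):
    """Co-register a CT/MR pair by mapping both into their LSCC frames.

    Returns ``(ct_in_frame, mr_in_frame, cross)`` where both volumes share
    one isotropic grid and ``cross`` is the implied CT-world → MR-world
    rigid map, ``invert(T_mr) ∘ T_ct`` with ``T`` the world→frame
    transforms.
    """
    from .geometry import build_lscc_frame  # deferred: avoids import cycle in docs builds

    frame_ct = build_lscc_frame(ct_landmarks, tilt_degrees=tilt_degrees)
    frame_mr = build_lscc_frame(mr_landmarks, tilt_degrees=tilt_degrees)
    out_spacing_v = np.broadcast_to(np.asarray(out_spacing, dtype=float), (3,))
    if out_dims is None:
        out_dims = np.maximum(
            _default_out_dims(ct, out_spacing_v), _default_out_dims(mr, out_spacing_v)
        )
    ct_out = resample_to_frame(
        ct, frame_ct, out_spacing, out_dims, interpolation=interpolation, fill=fill
    )
    mr_out = resample_to_frame(
        mr, frame_mr, out_spacing, out_dims, interpolation=interpolation, fill=fill
    )
    cross = compose(invert(frame_mr.as_transform()), frame_ct.as_transform())
    return ct_out, mr_out, cross


def overlay_slices(
    a: ImageVolume,
    b: ImageVolume,
    out_prefix=None,
    *,
    alpha: float = 0.5,
) -> dict[str, np.ndarray]:
    """Alpha-blend the mid sagittal/coronal/axial slices of two volumes.

    Both volumes must live on the same grid. Each volume is min–max
    normalised independently before blending, so a dark-lumen CT and a
    bright-fluid MR remain jointly visible. Returns the three uint8 slices
    and, when ``out_prefix`` is given, writes them as
    ``<prefix>_sagittal.png`` etc.
    """
    if a.shape != b.shape or not np.allclose(a.affine, b.affine, atol=1e-9):
        raise InputError("overlay requires two volumes on the identical grid")

    def norm(x):
        x = np.asarray(x, dtype=float)
        lo, hi = float(x.min()), float(x.max())
        return (x - lo) / (hi - lo) if hi > lo else np.zeros_like(x)

    na, nb = norm(a.data), norm(b.data)
    blend = (1.0 - alpha) * na + alpha * nb
    mids = [s // 2 for s in a.shape]
    # data axes are (x, y, z) in LPS: fixing x gives a sagittal slice, etc.
    slices = {
        "sagittal": blend[mids[0], :, :],
        "coronal": blend[:, mids[1], :],
        "axial": blend[:, :, mids[2]],
    }
    out = {k: np.clip(np.round(v * 255), 0, 255).astype(np.uint8) for k, v in slices.items()}
    if out_prefix is not None:
        out_prefix = Path(out_prefix)
        for name, img in out.items():
            iio.imwrite(f"{out_prefix}_{name}.png", img)
    return out
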