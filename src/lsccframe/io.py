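"""Reading and writing landmark observation tables.

A table holds one labelled 3-D point per row, keyed by
(patient, modality, rater, attempt, label). Comma/tab-delimited text and
XLSX (first sheet) are accepted, with a case-insensitive header row:

    patient, modality, rater, attempt, label, x, y, z

Coordinates may be world millimetres or 0-based voxel indices; indices are
converted at read time using the modality voxel spacing. When not stated
explicitly the reader auto-detects: all-integral coordinate columns plus
available spacing metadata are taken to be indices, and the choice is
logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .geometry import LsccLandmarkSet, Point3, as_point

__all__ = [
    "LSCC_LABELS",
    "SSCC_LABELS",
    "ALL_LABELS",
    "CT_SPACING",
    "MR_SPACING",
    "LandmarkObservation",
    "VoxelGrid",
    "voxel_to_world",
    "world_to_voxel",
    "read_landmark_table",
    "write_landmark_table",
    "write_itk_snap_points",
    "observations_to_dataframe",
    "dataframe_to_observations",
    "median_landmark",
    "landmark_set_from_observations",
]

logger = logging.getLogger(__name__)

LSCC_LABELS = ("left_anterior", "left_posterior", "right_anterior", "right_posterior")
SSCC_LABELS = ("left_superior_sscc", "right_superior_sscc")
ALL_LABELS = LSCC_LABELS + SSCC_LABELS

#: Default acquisition voxel spacings (mm/voxel).
CT_SPACING = (0.15, 0.15, 0.15)
MR_SPACING = (0.2604, 0.2604, 0.3)

MODALITIES = ("CT", "MR")

_REQUIRED_COLUMNS = ("patient", "modality", "rater", "attempt", "label", "x", "y", "z")

# Tolerated label spellings, e.g. the clinical "Left Anterior LSCC".
def _normalize_label(raw: str) -> str:
    s = str(raw).strip().lower().replace("-", " ").replace("_", " ")
    s = " ".join(tok for tok in s.split() if tok != "lscc")
    aliases = {
        "left anterior": "left_anterior",
        "left posterior": "left_posterior",
        "right anterior": "right_anterior",
        "right posterior": "right_posterior",
        "left superior sscc": "left_superior_sscc",
        "right superior sscc": "right_superior_sscc",
        "left superior": "left_superior_sscc",
        "right superior": "right_superior_sscc",
    }
    if s not in aliases:
        raise InputError(f"unrecognized landmark label {raw!r}")
    return aliases[s]


@dataclass(frozen=True)
class LandmarkObservation:
    """One labelled landmark selection with its provenance."""

    patient_id: str
    modality: str
    rater_id: str
    attempt: int
    label: str
    position: np.ndarray  # world mm

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise InputError(f"modality must be one of {MODALITIES}, got {self.modality!r}")
        if int(self.attempt) != self.attempt or self.attempt < 1:
            raise InputError(f"attempt must be a positive integer, got {self.attempt!r}")
        if self.label not in ALL_LABELS:
            raise InputError(f"unknown label {self.label!r}")
        object.__setattr__(self, "attempt", int(self.attempt))
        object.__setattr__(self, "position", as_point(self.position))

    @property
    def key(self):
        return (self.patient_id, self.modality, self.rater_id, self.attempt, self.label)


@dataclass(frozen=True)
class VoxelGrid:
    """Regular 0-based voxel grid: spacing (mm/voxel) and dimensions."""

    spacing: np.ndarray
    dimensions: np.ndarray

    def __post_init__(self):
        sp = np.asarray(self.spacing, dtype=float)
        dims = np.asarray(self.dimensions, dtype=int)
        if sp.shape != (3,) or np.any(sp <= 0):
            raise InputError(f"spacing must be 3 positive values, got {self.spacing}")
        if dims.shape != (3,) or np.any(dims < 1):
            raise InputError(f"dimensions must be 3 values >= 1, got {self.dimensions}")
        object.__setattr__(self, "spacing", sp)
        object.__setattr__(self, "dimensions", dims)


def voxel_to_world(index, grid: VoxelGrid, *, half_voxel_offset: bool = False) -> Point3:
    """World mm of a (possibly fractional) 0-based voxel index.

    The default convention is ``world = index × spacing`` with no
    half-voxel shift, matching tables whose coordinate differences are
    exact multiples of the voxel size. Pass ``half_voxel_offset=True`` for
    a voxel-center origin.
    """
    idx = np.asarray(index, dtype=float)
    if idx.shape != (3,):
        raise InputError(f"voxel index must be a 3-vector, got shape {idx.shape}")
    if np.any(idx < 0):
        raise InputError(f"voxel index must be non-negative, got {idx}")
    offset = 0.5 if half_voxel_offset else 0.0
    return (idx + offset) * grid.spacing


def world_to_voxel(p, grid: VoxelGrid, *, half_voxel_offset: bool = False):
    """Continuous voxel index of a world point; exact inverse of
    :func:`voxel_to_world`."""
    offset = 0.5 if half_voxel_offset else 0.0
    return as_point(p) / grid.spacing - offset


def observations_to_dataframe(observations: Iterable[LandmarkObservation]) -> pd.DataFrame:
    rows = [
        {
            "patient": o.patient_id,
            "modality": o.modality,
            "rater": o.rater_id,
            "attempt": o.attempt,
            "label": o.label,
            "x": o.position[0],
            "y": o.position[1],
            "z": o.position[2],
        }
        for o in observations
    ]
    return pd.DataFrame(rows, columns=list(_REQUIRED_COLUMNS))


def dataframe_to_observations(df: pd.DataFrame) -> list[LandmarkObservation]:
    return [
        LandmarkObservation(
            patient_id=str(r.patient),
            modality=str(r.modality),
            rater_id=str(r.rater),
            attempt=int(r.attempt),
            label=str(r.label),
            position=(r.x, r.y, r.z),
        )
        for r in df.itertuples(index=False)
    ]


def _read_raw_table(path: Path, dialect: str | None) -> pd.DataFrame:
    if dialect is None:
        suffix = path.suffix.lower()
        dialect = {".csv": "csv", ".tsv": "tsv", ".txt": "tsv", ".xlsx": "xlsx"}.get(suffix)
        if dialect is None:
            raise InputError(f"cannot infer table dialect from suffix {suffix!r}")
    if dialect == "csv":
        return pd.read_csv(path)
    if dialect == "tsv":
        return pd.read_csv(path, sep="\t")
    if dialect == "xlsx":
        return pd.read_excel(path, sheet_name=0)
    raise InputError(f"unknown dialect {dialect!r} (use csv, tsv or xlsx)")


def read_landmark_table(
    path,
    dialect: str | None = None,
    *,
    coordinates: str = "auto",
    spacing: Mapping[str, Sequence[float]] | None = None,
) -> list[LandmarkObservation]:
    """Read a landmark table into validated observations.

    Parameters
    ----------
    path
        CSV/TSV/XLSX file; dialect inferred from the suffix unless given.
    coordinates
        ``"mm"``, ``"voxel"``, or ``"auto"``. In voxel mode the x/y/z
        columns are non-negative 0-based indices converted to mm with the
        per-modality ``spacing``. Auto mode chooses voxel only when every
        coordinate is integral *and* spacing is available, and logs the
        decision.
    spacing
        Mapping modality → (sx, sy, sz) mm. Defaults to the CT/MR
        acquisition spacings when voxel conversion is needed.

    Raises
    ------
    InputError
        Missing columns, duplicate keys, or unparseable rows — each error
        names the offending row (1-based, counting the header as row 1).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"landmark table not found: {path}")
    df = _read_raw_table(path, dialect)
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path.name}: missing required column(s) {missing}")

    for col in ("x", "y", "z"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna() & df[col].notna()]
        if len(bad) > 0:
            raise InputError(
                f"{path.name}: non-numeric {col!r} value {df.loc[bad[0], col]!r} "
                f"at row {int(bad[0]) + 2}"
            )
        if converted.isna().any():
            row = int(converted.index[converted.isna()][0]) + 2
            raise InputError(f"{path.name}: empty {col!r} value at row {row}")
        df[col] = converted

    coords = df[["x", "y", "z"]].to_numpy(dtype=float)
    if coordinates not in ("auto", "mm", "voxel"):
        raise InputError(f"coordinates must be 'auto', 'mm' or 'voxel', got {coordinates!r}")
    use_voxel = coordinates == "voxel"
    if coordinates == "auto":
        integral = np.allclose(coords, np.round(coords), atol=1e-9)
        use_voxel = bool(integral and coords.size > 0)
        logger.info(
            "%s: auto-detected %s coordinates",
            path.name,
            "voxel-index" if use_voxel else "millimetre",
        )
    if use_voxel:
        if np.any(coords < 0):
            row = int(np.argwhere(np.any(coords < 0, axis=1))[0][0]) + 2
            raise InputError(f"{path.name}: negative voxel index at row {row}")
        sp = dict(spacing) if spacing else {"CT": CT_SPACING, "MR": MR_SPACING}

    observations: list[LandmarkObservation] = []
    seen: dict[tuple, int] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        rowno = i + 2
        try:
            label = _normalize_label(row.label)
            pos = np.array([row.x, row.y, row.z], dtype=float)
            modality = str(row.modality).strip().upper()
            if use_voxel:
                if modality not in sp:
                    raise InputError(f"no voxel spacing given for modality {modality!r}")
                pos = pos * np.asarray(sp[modality], dtype=float)
            obs = LandmarkObservation(
                patient_id=str(row.patient).strip(),
                modality=modality,
                rater_id=str(row.rater).strip(),
                attempt=int(row.attempt),
                label=label,
                position=pos,
            )
        except InputError as exc:
            raise InputError(f"{path.name}: row {rowno}: {exc}") from exc
        if obs.key in seen:
            raise InputError(
                f"{path.name}: row {rowno}: duplicate key {obs.key} "
                f"(first seen at row {seen[obs.key]})"
            )
        seen[obs.key] = rowno
        observations.append(obs)
    return observations


def write_landmark_table(
    observations: Iterable[LandmarkObservation], path, dialect: str | None = None
) -> None:
    """Write observations to CSV/TSV/XLSX (world mm)."""
    path = Path(path)
    df = observations_to_dataframe(observations)
    if dialect is None:
        dialect = {".csv": "csv", ".tsv": "tsv", ".xlsx": "xlsx"}.get(path.suffix.lower())
    if dialect == "csv":
        df.to_csv(path, index=False)
    elif dialect == "tsv":
        df.to_csv(path, index=False, sep="\t")
    elif dialect == "xlsx":
        df.to_excel(path, index=False)
    else:
        raise InputError(f"unknown dialect {dialect!r} for {path.name}")


def write_itk_snap_points(
    observations: Iterable[LandmarkObservation], path, grid: VoxelGrid
) -> None:
    """Export landmarks as an ITK-SNAP-style label-point text file.

    One point per line: ``x y z label-index`` in 0-based voxel indices,
    with a comment header mapping indices to label names.
    """
    path = Path(path)
    obs = list(observations)
    with open(path, "w") as fh:
        fh.write("# ITK-SNAP label points (0-based voxel indices)\n")
        for i, name in enumerate(ALL_LABELS, start=1):
            fh.write(f"# label {i} = {name}\n")
        for o in obs:
            idx = world_to_voxel(o.position, grid)
            li = ALL_LABELS.index(o.label) + 1
            fh.write(f"{idx[0]:.3f} {idx[1]:.3f} {idx[2]:.3f} {li}\n")


def median_landmark(observations: Sequence[LandmarkObservation]) -> Point3:
    """Componentwise median position of repeated selections of one landmark.

    All observations must share patient, modality and label; an even count
    yields the mean of the two middle values per component. Using the
    median across raters and attempts damps selection outliers before a
    frame is built.
    """
    obs = list(observations)
    if not obs:
        raise InputError("median_landmark: empty observation group")
    keys = {(o.patient_id, o.modality, o.label) for o in obs}
    if len(keys) != 1:
        raise InputError(
            f"median_landmark: observations span multiple (patient, modality, label) groups: {sorted(keys)}"
        )
    return np.median(np.array([o.position for o in obs]), axis=0)


def landmark_set_from_observations(
    observations: Iterable[LandmarkObservation],
    patient: str,
    modality: str,
    *,
    rater: str | None = None,
    attempt: int | None = None,
) -> LsccLandmarkSet:
    """Build the four-landmark set for one patient/modality.

    With ``rater``/``attempt`` unset, the componentwise median over all
    available selections of each landmark is used.
    """
    groups: dict[str, list[LandmarkObservation]] = {lab: [] for lab in LSCC_LABELS}
    for o in observations:
        if o.patient_id != patient or o.modality != modality or o.label not in groups:
            continue
        if rater is not None and o.rater_id != rater:
            continue
        if attempt is not None and o.attempt != attempt:
            continue
        groups[o.label].append(o)
    empty = [lab for lab, g in groups.items() if not g]
    if empty:
        raise InputError(
            f"missing LSCC landmark(s) {empty} for patient {patient!r}, modality {modality!r}"
        )
    med = {lab: median_landmark(g) for lab, g in groups.items()}
    return LsccLandmarkSet(
        left_anterior=med["left_anterior"],
        left_posterior=med["left_posterior"],
        right_anterior=med["right_anterior"],
        right_posterior=med["right_posterior"],
    )
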