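"""End-to-end evaluation workflows over a landmark table.

These functions reproduce the structure of a full reliability/accuracy
study from a single observation table: per-rater intra-rater reliability,
worst-pair inter-rater reliability, cross-modality accuracy of the frame
(held-out SSCC landmarks compared after each modality is mapped into its
own LSCC frame), and the planarity validation.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .errors import InputError
from .geometry import build_lscc_frame
from .io import (
    LandmarkObservation,
    SSCC_LABELS,
    landmark_set_from_observations,
    median_landmark,
    observations_to_dataframe,
)
from .stats import (
    bland_altman,
    inter_rater_report,
    intra_rater_report,
    paired_coordinate_report,
    planarity_report,
    target_registration_error,
)

__all__ = ["frame_coordinates_of_probes", "accuracy_report", "evaluate_study"]

_COORDS = ("x", "y", "z")


def frame_coordinates_of_probes(
    observations: Iterable[LandmarkObservation],
    patient: str,
    modality: str,
    *,
    tilt_degrees: float = 20.0,
) -> dict[str, np.ndarray]:
    """Held-out SSCC probe positions of one scan, in its own LSCC frame.

    The frame is built from the componentwise-median LSCC landmarks of the
    scan (medians damp selection outliers and avoid favouring any single
    rater); the median SSCC selections are then expressed in that frame.
    """
    obs = list(observations)
    frame = build_lscc_frame(
        landmark_set_from_observations(obs, patient, modality), tilt_degrees=tilt_degrees
    )
    out: dict[str, np.ndarray] = {}
    for label in SSCC_LABELS:
        group = [
            o
            for o in obs
            if o.patient_id == patient and o.modality == modality and o.label == label
        ]
        if not group:
            raise InputError(
                f"no {label!r} selections for patient {patient!r}, modality {modality!r}"
            )
        out[label] = frame.world_to_frame(median_landmark(group))
    return out


def accuracy_report(
    observations: Iterable[LandmarkObservation],
    *,
    tilt_degrees: float = 20.0,
    modalities: tuple[str, str] = ("CT", "MR"),
):
    """Cross-modality accuracy on held-out SSCC landmarks.

    For every patient, both scans are mapped into their own LSCC frame
    (shared anatomical coordinates), and the SSCC probe coordinates are
    compared between the two modalities: a per-landmark, per-coordinate
    agreement table, the Euclidean target registration error, and
    per-coordinate Bland–Altman analyses.

    Returns ``(table, tre, bland_altman_by_coordinate)``.
    """
    obs = list(observations)
    df = observations_to_dataframe(obs)
    patients = sorted(df["patient"].unique())
    mod_a, mod_b = modalities
    pts_a, pts_b, labels = [], [], []
    for patient in patients:
        probes_a = frame_coordinates_of_probes(obs, patient, mod_a, tilt_degrees=tilt_degrees)
        probes_b = frame_coordinates_of_probes(obs, patient, mod_b, tilt_degrees=tilt_degrees)
        for label in SSCC_LABELS:
            pts_a.append(probes_a[label])
            pts_b.append(probes_b[label])
            labels.append(label)
    pts_a, pts_b = np.array(pts_a), np.array(pts_b)
    table = paired_coordinate_report(pts_a, pts_b, labels)
    tre = target_registration_error(pts_a, pts_b, labels)
    ba = {
        coord.upper(): bland_altman(pts_a[:, ci], pts_b[:, ci])
        for ci, coord in enumerate(_COORDS)
    }
    return table, tre, ba


def evaluate_study(
    observations: Iterable[LandmarkObservation], *, tilt_degrees: float = 20.0
) -> dict[str, object]:
    """Run the complete evaluation over a study table.

    Returns a mapping of report names to pandas DataFrames (plus the
    TRE/Bland–Altman objects under ``"tre"`` and ``"bland_altman"``):
    ``intra_<MOD>``, ``inter_<MOD>``, ``planarity_<MOD>``, ``accuracy``.
    Accuracy reports are produced only when both modalities carry SSCC
    probe selections.
    """
    obs = list(observations)
    df = observations_to_dataframe(obs)
    if df.empty:
        raise InputError("empty observation table")
    reports: dict[str, object] = {}
    modalities = sorted(df["modality"].unique())
    for mod in modalities:
        sub = [o for o in obs if o.modality == mod]
        frames = []
        for rater in sorted({o.rater_id for o in sub}):
            rep = intra_rater_report(sub, rater, modality=mod)
            rep.insert(0, "rater", rater)
            frames.append(rep)
        reports[f"intra_{mod}"] = pd.concat(frames, ignore_index=True)
        if len({o.rater_id for o in sub}) >= 2:
            reports[f"inter_{mod}"] = inter_rater_report(sub, modality=mod)
        reports[f"planarity_{mod}"] = planarity_report(sub, modality=mod)
    has_sscc = {
        mod: any(o.modality == mod and o.label in SSCC_LABELS for o in obs)
        for mod in modalities
    }
    if len(modalities) == 2 and all(has_sscc.values()):
        table, tre, ba = accuracy_report(
            obs, tilt_degrees=tilt_degrees, modalities=tuple(modalities)
        )
        reports["accuracy"] = table
        reports["tre"] = tre
        reports["bland_altman"] = ba
    return reports
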