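"""Reliability and accuracy statistics for landmark selections.

Implements the evaluation suite around the LSCC coordinate frame:

* intraclass correlation under the two-way random-effects model with
  absolute agreement (single- and average-measure forms), with the
  F test of H0: ICC = 0;
* mean / SD / max absolute-difference summaries;
* intra-rater (two attempts) and worst-pair inter-rater reports;
* target registration error (TRE) on held-out landmarks;
* Bland–Altman limits of agreement;
* a planarity check comparing median landmarks with their orthogonal
  projections onto the best-fit canal plane.

All coordinates are in millimetres; x, y, z are analysed separately
because the axes are treated as independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError
from .geometry import fit_plane_total_least_squares, project_onto_plane
from .io import LSCC_LABELS, LandmarkObservation, observations_to_dataframe

__all__ = [
    "IccResult",
    "DifferenceSummary",
    "TreSummary",
    "BlandAltmanResult",
    "icc_two_way_random_absolute",
    "difference_summary",
    "intra_rater_report",
    "inter_rater_report",
    "target_registration_error",
    "bland_altman",
    "paired_coordinate_report",
    "planarity_pairs",
    "planarity_report",
]

_COORDS = ("x", "y", "z")


@dataclass(frozen=True)
class IccResult:
    """An intraclass correlation estimate with its significance test.

    ``model`` is fixed: two-way random effects, absolute agreement
    (ICC(A,1) for ``form="single"``, ICC(A,k) for ``form="average"``).
    ``degenerate`` marks matrices with zero total variance, for which the
    agreement is perfect by definition and r = 1 is returned.
    """

    r: float
    p: float
    form: str
    F: float
    df1: float
    df2: float
    msr: float
    msc: float
    mse: float
    n: int
    k: int
    model: str = "two-way random, absolute agreement"
    degenerate: bool = False


def _ratings_matrix(values) -> np.ndarray:
    m = np.asarray(values, dtype=float)
    if m.ndim != 2:
        raise InputError(f"ratings matrix must be 2-D (subjects × measurements), got {m.ndim}-D")
    n, k = m.shape
    if n < 2 or k < 2:
        raise InputError(f"ratings matrix needs n >= 2 subjects and k >= 2 measurements, got {n}×{k}")
    if not np.all(np.isfinite(m)):
        raise InputError("ratings matrix contains missing or non-finite cells")
    return m


def icc_two_way_random_absolute(values, form: str = "single") -> IccResult:
    """ICC under the two-way random-effects, absolute-agreement model.

    With n subjects and k measurements the two-way mean squares are

        MSR — between subjects (rows),  df n−1
        MSC — between measurements (columns),  df k−1
        MSE — residual,  df (n−1)(k−1)

    and

        ICC(A,1) = (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n)
        ICC(A,k) = (MSR − MSE) / (MSR + (MSC − MSE)/n).

    The p-value tests H0: ICC = 0 with F = MSR/MSE on (n−1, (n−1)(k−1))
    degrees of freedom — the Satterthwaite-style denominator of the
    absolute-agreement test collapses to MSE when the null value is zero.

    A matrix with zero total variance is perfect agreement by definition
    and is returned as r = 1, p = 0 with ``degenerate=True`` rather than
    NaN.
    """
    if form not in ("single", "average"):
        raise InputError(f"form must be 'single' or 'average', got {form!r}")
    m = _ratings_matrix(values)
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_total = float(((m - grand) ** 2).sum())
    ss_rows = float(k * ((row_means - grand) ** 2).sum())
    ss_cols = float(n * ((col_means - grand) ** 2).sum())
    ss_err = max(ss_total - ss_rows - ss_cols, 0.0)
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    df1 = n - 1.0
    df2 = (n - 1.0) * (k - 1.0)

    scale = max(abs(grand), 1.0)
    if ss_total <= (1e-14 * scale) ** 2 * m.size:
        return IccResult(
            r=1.0, p=0.0, form=form, F=np.inf, df1=df1, df2=df2,
            msr=msr, msc=msc, mse=mse, n=n, k=k, degenerate=True,
        )

    if form == "single":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    else:
        denom = msr + (msc - mse) / n
    r = (msr - mse) / denom if denom != 0 else 1.0

    if mse == 0.0:
        F, p = np.inf, 0.0
    else:
        F = msr / mse
        p = float(sps.f.sf(F, df1, df2))
    return IccResult(
        r=float(r), p=p, form=form, F=float(F), df1=df1, df2=df2,
        msr=msr, msc=msc, mse=mse, n=n, k=k,
    )


@dataclass(frozen=True)
class DifferenceSummary:
    """Mean, sample SD and max of absolute differences (mm)."""

    mean: float
    sd: float
    max: float
    n: int


def difference_summary(differences) -> DifferenceSummary:
    """Summarise a vector of differences by |mean|/SD/max of absolute values.

    The SD is the sample standard deviation (ddof = 1) of the absolute
    differences; absolute values are used because the summaries describe
    selection scatter, not signed bias.
    """
    d = np.abs(np.asarray(differences, dtype=float).ravel())
    if d.size == 0:
        raise InputError("cannot summarise an empty difference vector")
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    return DifferenceSummary(mean=float(d.mean()), sd=sd, max=float(d.max()), n=int(d.size))


# ---------------------------------------------------------------------------
# table wrangling helpers


def _pivot(observations: Iterable[LandmarkObservation]) -> pd.DataFrame:
    df = observations_to_dataframe(observations)
    if df.empty:
        raise InputError("no observations supplied")
    return df


def _require_modality(df: pd.DataFrame, modality: str | None) -> pd.DataFrame:
    if modality is not None:
        df = df[df["modality"] == modality]
        if df.empty:
            raise InputError(f"no observations for modality {modality!r}")
    elif df["modality"].nunique() > 1:
        raise InputError(
            "observations span multiple modalities; pass modality= to select one"
        )
    return df


def intra_rater_report(
    observations: Iterable[LandmarkObservation],
    rater: str,
    *,
    modality: str | None = None,
    labels: Sequence[str] = LSCC_LABELS,
) -> pd.DataFrame:
    """Intra-rater reliability of one rater's two selection attempts.

    For every landmark × coordinate the n_patients × 2 matrix of the two
    attempts is scored with the absolute-agreement ICC (the two attempts
    play the role of the k = 2 measurements), and the per-patient
    |attempt 1 − attempt 2| differences are summarised.

    Returns a tidy frame with columns ``landmark, coordinate, r, p,
    r_average, p_average, mean, sd, max``; ``r`` is the single-measure
    form.
    """
    df = _require_modality(_pivot(observations), modality)
    df = df[(df["rater"] == rater) & df["label"].isin(labels)]
    if df.empty:
        raise InputError(f"no observations for rater {rater!r}")
    attempts = sorted(df["attempt"].unique())
    if len(attempts) != 2:
        raise InputError(
            f"intra-rater analysis needs exactly 2 attempts, rater {rater!r} has {attempts}"
        )
    rows = []
    for label in labels:
        sub = df[df["label"] == label]
        wide = sub.pivot(index="patient", columns="attempt", values=list(_COORDS))
        if wide.isna().any().any():
            missing = wide.index[wide.isna().any(axis=1)].tolist()
            raise InputError(
                f"rater {rater!r}, landmark {label!r}: missing attempt for patient(s) {missing}"
            )
        for coord in _COORDS:
            m = wide[coord][attempts].to_numpy()
            icc1 = icc_two_way_random_absolute(m, form="single")
            icck = icc_two_way_random_absolute(m, form="average")
            ds = difference_summary(m[:, 0] - m[:, 1])
            rows.append(
                {
                    "landmark": label,
                    "coordinate": coord.upper(),
                    "r": icc1.r,
                    "p": icc1.p,
                    "r_average": icck.r,
                    "p_average": icck.p,
                    "mean": ds.mean,
                    "sd": ds.sd,
                    "max": ds.max,
                }
            )
    return pd.DataFrame(rows)


def inter_rater_report(
    observations: Iterable[LandmarkObservation],
    *,
    modality: str | None = None,
    labels: Sequence[str] = LSCC_LABELS,
    criterion: str = "icc",
) -> pd.DataFrame:
    """Worst-pair inter-rater reliability.

    Each rater's two attempts are first averaged per patient × landmark;
    every rater pair is then compared (absolute-agreement ICC and
    difference summary per landmark × coordinate) and the worst of the
    pairs is reported. ``criterion`` selects what "worst" means: lowest
    single-measure ICC (``"icc"``, default) or highest mean absolute
    difference (``"mean_diff"``).

    Columns: ``landmark, coordinate, pair, r, p, r_average, p_average,
    mean, sd, max``.
    """
    if criterion not in ("icc", "mean_diff"):
        raise InputError(f"criterion must be 'icc' or 'mean_diff', got {criterion!r}")
    df = _require_modality(_pivot(observations), modality)
    df = df[df["label"].isin(labels)]
    raters = sorted(df["rater"].unique())
    if len(raters) < 2:
        raise InputError(f"inter-rater analysis needs >= 2 raters, got {raters}")
    # mean of the attempts per rater
    mean_df = (
        df.groupby(["patient", "rater", "label"], as_index=False)[list(_COORDS)].mean()
    )
    counts = df.groupby(["patient", "rater", "label"]).size()
    n_attempts = df["attempt"].nunique()
    short = counts[counts != n_attempts]
    if len(short) > 0:
        raise InputError(f"missing attempts for {short.index.tolist()[:5]} ...")

    rows = []
    for label in labels:
        sub = mean_df[mean_df["label"] == label]
        wide = sub.pivot(index="patient", columns="rater", values=list(_COORDS))
        if wide.isna().any().any():
            missing = wide.index[wide.isna().any(axis=1)].tolist()
            raise InputError(f"landmark {label!r}: missing rater data for patient(s) {missing}")
        for coord in _COORDS:
            candidates = []
            for ra, rb in combinations(raters, 2):
                m = wide[coord][[ra, rb]].to_numpy()
                icc1 = icc_two_way_random_absolute(m, form="single")
                icck = icc_two_way_random_absolute(m, form="average")
                ds = difference_summary(m[:, 0] - m[:, 1])
                candidates.append((f"{ra}-{rb}", icc1, icck, ds))
            if criterion == "icc":
                pair, icc1, icck, ds = min(candidates, key=lambda c: c[1].r)
            else:
                pair, icc1, icck, ds = max(candidates, key=lambda c: c[3].mean)
            rows.append(
                {
                    "landmark": label,
                    "coordinate": coord.upper(),
                    "pair": pair,
                    "r": icc1.r,
                    "p": icc1.p,
                    "r_average": icck.r,
                    "p_average": icck.p,
                    "mean": ds.mean,
                    "sd": ds.sd,
                    "max": ds.max,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TreSummary:
    """Target registration error: per-point distances plus summaries."""

    distances: np.ndarray
    mean: float
    sd: float
    max: float
    per_coordinate: dict[str, DifferenceSummary] = field(default_factory=dict)


def target_registration_error(
    points_a, points_b, labels: Sequence[str] | None = None
) -> TreSummary:
    """Euclidean distances between matched points in a common frame.

    The points must be targets held out from the registration: passing
    any of the frame-defining LSCC labels is rejected, because an error
    measured on the landmarks that built the frame is a fiducial — not a
    target — registration error.
    """
    a = np.atleast_2d(np.asarray(points_a, dtype=float))
    b = np.atleast_2d(np.asarray(points_b, dtype=float))
    if a.shape != b.shape or a.shape[1] != 3 or a.shape[0] < 1:
        raise InputError(f"matched point lists required, got shapes {a.shape} and {b.shape}")
    if labels is not None:
        bad = sorted(set(labels) & set(LSCC_LABELS))
        if bad:
            raise InputError(
                f"TRE landmarks must be independent of the frame; got frame-defining label(s) {bad}"
            )
    d = np.linalg.norm(a - b, axis=1)
    per_coord = {
        c: difference_summary(a[:, i] - b[:, i]) for i, c in enumerate(_COORDS)
    }
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    return TreSummary(
        distances=d, mean=float(d.mean()), sd=sd, max=float(d.max()), per_coordinate=per_coord
    )


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bland–Altman agreement: pairwise means vs differences with 95%
    limits of agreement (mean difference ± 1.96·SD)."""

    means: np.ndarray
    differences: np.ndarray
    mean_difference: float
    sd_difference: float
    lower: float
    upper: float


def bland_altman(a, b) -> BlandAltmanResult:
    """Bland–Altman analysis of two paired measurement lists (a − b)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape or a.size < 2:
        raise InputError(f"paired lists of equal length >= 2 required, got {a.size} and {b.size}")
    diffs = a - b
    means = (a + b) / 2.0
    md = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltmanResult(
        means=means,
        differences=diffs,
        mean_difference=md,
        sd_difference=sd,
        lower=md - 1.96 * sd,
        upper=md + 1.96 * sd,
    )


def paired_coordinate_report(points_a, points_b, labels: Sequence[str]) -> pd.DataFrame:
    """Per-landmark, per-coordinate agreement between two matched point sets.

    For each label present, the paired coordinate values (one pair per
    point) are scored with the absolute-agreement ICC and an
    absolute-difference summary — the layout used to report CT-vs-MR
    agreement of held-out landmarks after co-registration.
    """
    a = np.atleast_2d(np.asarray(points_a, dtype=float))
    b = np.atleast_2d(np.asarray(points_b, dtype=float))
    labels = list(labels)
    if not (len(labels) == a.shape[0] == b.shape[0]):
        raise InputError("points_a, points_b and labels must have equal length")
    rows = []
    for label in sorted(set(labels)):
        idx = [i for i, l in enumerate(labels) if l == label]
        for ci, coord in enumerate(_COORDS):
            m = np.column_stack([a[idx, ci], b[idx, ci]])
            icc1 = icc_two_way_random_absolute(m, form="single")
            ds = difference_summary(m[:, 0] - m[:, 1])
            rows.append(
                {
                    "landmark": label,
                    "coordinate": coord.upper(),
                    "r": icc1.r,
                    "p": icc1.p,
                    "mean": ds.mean,
                    "sd": ds.sd,
                    "max": ds.max,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# planarity validation


def planarity_pairs(
    observations: Iterable[LandmarkObservation], patient: str, modality: str
):
    """Median LSCC landmarks of one patient/modality and their projections.

    The componentwise median over all raters × attempts is taken per
    landmark, a total-least-squares plane is fitted to the four medians,
    and each median is orthogonally projected onto it. Returns
    ``(medians, projections)`` as 4×3 arrays in the fixed label order
    LA, LP, RA, RP.

    Every landmark must carry the same complete set of (rater, attempt)
    selections; incomplete groups are an error.
    """
    df = _pivot(observations)
    df = df[(df["patient"] == patient) & (df["modality"] == modality)]
    df = df[df["label"].isin(LSCC_LABELS)]
    if df.empty:
        raise InputError(f"no LSCC observations for patient {patient!r}, modality {modality!r}")
    expected = set(map(tuple, df[["rater", "attempt"]].drop_duplicates().to_numpy()))
    medians = []
    for label in LSCC_LABELS:
        sub = df[df["label"] == label]
        got = set(map(tuple, sub[["rater", "attempt"]].to_numpy()))
        if got != expected:
            raise InputError(
                f"patient {patient!r}, landmark {label!r}: incomplete selections "
                f"(missing {sorted(expected - got)})"
            )
        medians.append(np.median(sub[list(_COORDS)].to_numpy(dtype=float), axis=0))
    medians = np.array(medians)
    plane = fit_plane_total_least_squares(medians)
    projections = np.array([project_onto_plane(p, plane) for p in medians])
    return medians, projections


def planarity_report(
    observations: Iterable[LandmarkObservation], *, modality: str | None = None
) -> pd.DataFrame:
    """Pooled planarity check of the LSCC landmarks for one modality.

    Median landmarks and their plane projections are computed per patient
    and pooled over the four landmarks and all patients; for each
    coordinate the pooled original-vs-projected pairs are scored with the
    absolute-agreement ICC and an absolute-difference summary. Values
    near zero support approximating the two canals by a single plane.
    """
    df = _require_modality(_pivot(observations), modality)
    mod = df["modality"].iloc[0]
    obs = list(observations)
    originals, projected = [], []
    for patient in sorted(df["patient"].unique()):
        med, proj = planarity_pairs(obs, patient, mod)
        originals.append(med)
        projected.append(proj)
    originals = np.vstack(originals)
    projected = np.vstack(projected)
    rows = []
    for ci, coord in enumerate(_COORDS):
        m = np.column_stack([originals[:, ci], projected[:, ci]])
        icc1 = icc_two_way_random_absolute(m, form="single")
        ds = difference_summary(m[:, 0] - m[:, 1])
        rows.append(
            {
                "modality": mod,
                "coordinate": coord.upper(),
                "r": icc1.r,
                "p": icc1.p,
                "mean": ds.mean,
                "sd": ds.sd,
                "max": ds.max,
            }
        )
    return pd.DataFrame(rows)
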