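import numpy as np
import pandas as pd
import pytest

from lsccframe import (
    InputError,
    LandmarkObservation,
    bland_altman,
    difference_summary,
    icc_two_way_random_absolute,
    inter_rater_report,
    intra_rater_report,
    planarity_report,
    target_registration_error,
)
from lsccframe.stats import paired_coordinate_report, planarity_pairs

from oracles import icc_anova_loops, plane_by_eigendecomposition, project


def obs(patient, rater, attempt, label, pos, modality="CT"):
    return LandmarkObservation(
        patient_id=patient, modality=modality, rater_id=rater,
        attempt=attempt, label=label, position=pos,
    )


LSCC = ("left_anterior", "left_posterior", "right_anterior", "right_posterior")
BASE = {
    "left_anterior": np.array([10.0, -5.0, 0.0]),
    "left_posterior": np.array([10.0, 5.0, 0.0]),
    "right_anterior": np.array([-10.0, -5.0, 0.0]),
    "right_posterior": np.array([-10.0, 5.0, 0.0]),
}


def study_observations(rng, n_patients=6, sigma=0.0, modality="CT", raters="ABC", attempts=(1, 2)):
    out = []
    for p in range(n_patients):
        shift = rng.normal(0, 2.0, size=3)
        for label in LSCC:
            for rater in raters:
                for attempt in attempts:
                    noise = rng.normal(0, sigma, size=3) if sigma else 0.0
                    out.append(obs(
                        f"P{p:02d}", rater, attempt, label,
                        BASE[label] + shift + noise, modality=modality,
                    ))
    return out


class TestIcc:
    def test_identical_columns_give_one(self):
        m = np.tile(np.arange(5.0)[:, None], (1, 2))
        res = icc_two_way_random_absolute(m)
        assert res.r == pytest.approx(1.0)
        assert res.p < 1e-6

    def test_zero_variance_is_degenerate_one(self):
        res = icc_two_way_random_absolute(np.full((4, 2), 3.0))
        assert res.r == 1.0 and res.p == 0.0 and res.degenerate

    def test_toy_matrix_matches_anova_loop_oracle(self, rng):
        m = rng.normal(10, 2, size=(6, 2))
        single, average, msr, msc, mse = icc_anova_loops(m)
        r1 = icc_two_way_random_absolute(m, form="single")
        rk = icc_two_way_random_absolute(m, form="average")
        assert r1.r == pytest.approx(single, abs=1e-12)
        assert rk.r == pytest.approx(average, abs=1e-12)
        assert (r1.msr, r1.msc, r1.mse) == pytest.approx((msr, msc, mse), abs=1e-10)

    def test_constant_offset_decreases_single_icc(self, rng):
        m = rng.normal(0, 1, size=(10, 2)) + np.arange(10)[:, None]
        shifted = m.copy()
        shifted[:, 1] += 1.5
        assert (
            icc_two_way_random_absolute(shifted).r < icc_two_way_random_absolute(m).r
        )

    def test_average_form_not_below_single(self, rng):
        for _ in range(30):
            m = rng.normal(0, 1, size=(8, 3)) + rng.normal(0, 2, size=(8, 1))
            r1 = icc_two_way_random_absolute(m, form="single").r
            rk = icc_two_way_random_absolute(m, form="average").r
            assert rk >= r1 - 1e-12

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        for k in (2, 3):
            m = rng.normal(50, 5, size=(12, k)) + rng.normal(0, 1, size=(12, 1)) * 3
            long = pd.DataFrame(
                {
                    "subject": np.repeat(np.arange(12), k),
                    "rater": np.tile(np.arange(k), 12),
                    "score": m.ravel(),
                }
            )
            ref = pg.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
            ref = ref.set_index("Type")
            r1 = icc_two_way_random_absolute(m, form="single")
            rk = icc_two_way_random_absolute(m, form="average")
            assert r1.r == pytest.approx(ref.loc["ICC(A,1)", "ICC"], abs=1e-9)
            assert rk.r == pytest.approx(ref.loc["ICC(A,k)", "ICC"], abs=1e-9)
            assert r1.p == pytest.approx(ref.loc["ICC(A,1)", "pval"], abs=1e-9)

    def test_invalid_matrices_rejected(self):
        with pytest.raises(InputError):
            icc_two_way_random_absolute(np.ones((1, 2)))
        with pytest.raises(InputError):
            icc_two_way_random_absolute(np.array([[1.0, np.nan], [2.0, 3.0]]))


class TestDifferenceSummary:
    def test_absolute_and_ordering(self):
        ds = difference_summary([-0.3, 0.1, 0.2])
        assert ds.mean == pytest.approx(0.2)
        assert ds.max == pytest.approx(0.3)
        assert 0 <= ds.mean <= ds.max and ds.sd >= 0


class TestIntraRater:
    def test_identical_attempts(self, rng):
        o = study_observations(rng, sigma=0.0)
        rep = intra_rater_report(o, "A", modality="CT")
        assert np.allclose(rep["mean"], 0) and np.allclose(rep["max"], 0)
        assert np.allclose(rep["r"], 1.0)

    def test_single_voxel_difference_gives_voxel_max(self, rng):
        o = study_observations(rng, sigma=0.0)
        bumped = []
        for ob in o:
            if (ob.patient_id, ob.rater_id, ob.attempt, ob.label) == ("P00", "A", 2, "left_anterior"):
                bumped.append(obs(ob.patient_id, ob.rater_id, ob.attempt, ob.label,
                                  ob.position + np.array([0.15, 0, 0])))
            else:
                bumped.append(ob)
        rep = intra_rater_report(bumped, "A", modality="CT")
        row = rep[(rep.landmark == "left_anterior") & (rep.coordinate == "X")].iloc[0]
        assert row["max"] == pytest.approx(0.15)

    def test_missing_attempt_names_patient(self, rng):
        o = study_observations(rng)
        o = [ob for ob in o if not (
            ob.patient_id == "P03" and ob.rater_id == "A"
            and ob.attempt == 2 and ob.label == "left_anterior")]
        with pytest.raises(InputError, match="P03"):
            intra_rater_report(o, "A", modality="CT")

    def test_jitter_mean_near_folded_normal_expectation(self):
        """|d| of two N(0, σ²) draws has mean 2σ/√π; a simulated study's
        per-attempt differences should land nearby."""
        sigma = 0.1
        rng = np.random.default_rng(7)
        means = []
        for _ in range(30):
            o = study_observations(rng, n_patients=20, sigma=sigma)
            rep = intra_rater_report(o, "A", modality="CT")
            means.append(rep["mean"].mean())
        expect = 2 * sigma / np.sqrt(np.pi)
        assert np.mean(means) == pytest.approx(expect, rel=0.1)


class TestInterRater:
    def test_identical_raters(self, rng):
        o = study_observations(rng, sigma=0.0)
        rep = inter_rater_report(o, modality="CT")
        assert np.allclose(rep["r"], 1.0) and np.allclose(rep["mean"], 0)

    def test_offset_rater_is_worst_pair(self, rng):
        o = study_observations(rng, sigma=0.0)
        shifted = [
            obs(ob.patient_id, ob.rater_id, ob.attempt, ob.label,
                ob.position + np.array([0.3, 0, 0]))
            if ob.rater_id == "C" else ob
            for ob in o
        ]
        rep = inter_rater_report(shifted, modality="CT")
        xrows = rep[rep.coordinate == "X"]
        assert all("C" in pair for pair in xrows["pair"])
        assert np.allclose(xrows["mean"], 0.3)

    def test_worst_pair_matches_exhaustive_enumeration(self, rng):
        from itertools import combinations
        o = study_observations(rng, sigma=0.15)
        rep = inter_rater_report(o, modality="CT")
        df = pd.DataFrame([
            {"patient": ob.patient_id, "rater": ob.rater_id, "label": ob.label,
             "x": ob.position[0], "y": ob.position[1], "z": ob.position[2]}
            for ob in o
        ]).groupby(["patient", "rater", "label"], as_index=False).mean()
        for _, row in rep.iterrows():
            coord = row.coordinate.lower()
            best_r, best_pair = None, None
            for ra, rb in combinations("ABC", 2):
                wide = df[df.label == row.landmark].pivot(
                    index="patient", columns="rater", values=coord
                )
                r = icc_two_way_random_absolute(wide[[ra, rb]].to_numpy()).r
                if best_r is None or r < best_r:
                    best_r, best_pair = r, f"{ra}-{rb}"
            assert row.pair == best_pair
            assert row.r == pytest.approx(best_r, abs=1e-12)

    def test_missing_rater_rejected(self, rng):
        o = [ob for ob in study_observations(rng) if ob.rater_id != "B" or ob.patient_id != "P01"]
        with pytest.raises(InputError):
            inter_rater_report(o, modality="CT")


class TestTre:
    def test_identical_and_345(self):
        a = np.array([[0.0, 0, 0], [1, 1, 1]])
        assert target_registration_error(a, a).max == 0.0
        res = target_registration_error([[0.0, 0, 0]], [[3.0, 4, 0]])
        assert res.mean == pytest.approx(5.0)

    def test_frame_defining_labels_rejected(self):
        with pytest.raises(InputError, match="independent of the frame"):
            target_registration_error(
                [[0.0, 0, 0]], [[1.0, 0, 0]], labels=["left_anterior"]
            )

    def test_rigid_invariance(self, rng):
        from conftest import random_rigid
        a = rng.normal(0, 10, size=(6, 3))
        b = a + rng.normal(0, 0.5, size=(6, 3))
        t = random_rigid(rng)
        d0 = target_registration_error(a, b).distances
        d1 = target_registration_error(t.apply_many(a), t.apply_many(b)).distances
        assert np.allclose(d0, d1, atol=1e-9)

    def test_length_mismatch(self):
        with pytest.raises(InputError):
            target_registration_error([[0.0, 0, 0]], [[1.0, 0, 0], [2.0, 0, 0]])


class TestBlandAltman:
    def test_identical_and_constant_offset(self):
        a = np.arange(5.0)
        res = bland_altman(a, a)
        assert res.mean_difference == 0 and res.lower == 0 and res.upper == 0
        res = bland_altman(a + 2.0, a)
        assert res.mean_difference == pytest.approx(2.0)
        assert res.sd_difference == 0

    def test_gaussian_coverage_near_95_percent(self):
        rng = np.random.default_rng(42)
        a = rng.normal(10, 2, size=10_000)
        b = a + rng.normal(0, 0.5, size=10_000)
        res = bland_altman(a, b)
        inside = np.mean((res.differences >= res.lower) & (res.differences <= res.upper))
        assert inside == pytest.approx(0.95, abs=0.01)
        assert res.lower <= res.mean_difference <= res.upper


class TestPlanarity:
    def test_coplanar_medians_give_zero(self, rng):
        o = study_observations(rng, sigma=0.0)
        rep = planarity_report(o, modality="CT")
        assert np.allclose(rep["mean"], 0, atol=1e-12)
        assert np.allclose(rep["r"], 1.0)

    def test_raised_landmark_moves_mostly_z(self, rng):
        o = []
        for rater in "ABC":
            for attempt in (1, 2):
                for label in LSCC:
                    p = BASE[label].copy()
                    if label == "left_anterior":
                        p[2] += 0.2
                    o.append(obs("P00", rater, attempt, label, p))
        med, proj = planarity_pairs(o, "P00", "CT")
        dz = np.abs(med[:, 2] - proj[:, 2])
        dxy = np.abs(med[:, :2] - proj[:, :2])
        assert np.all(dz > 1e-4)  # all four projections shift in z
        assert dxy.max() < dz.min()  # near-horizontal plane: x/y ≪ z

    def test_matches_normal_equation_oracle(self, rng):
        o = study_observations(rng, sigma=0.2)
        med, proj = planarity_pairs(o, "P01", "CT")
        n, c = plane_by_eigendecomposition(med)
        expect = np.array([project(p, n, c) for p in med])
        assert np.allclose(proj, expect, atol=1e-10)

    def test_incomplete_selections_rejected(self, rng):
        o = study_observations(rng)
        o = [ob for ob in o if not (
            ob.patient_id == "P00" and ob.label == "left_anterior"
            and ob.rater_id == "B" and ob.attempt == 2)]
        with pytest.raises(InputError, match="incomplete"):
            planarity_pairs(o, "P00", "CT")

    def test_patient_order_invariance(self, rng):
        o = study_observations(rng, sigma=0.1)
        rep1 = planarity_report(o, modality="CT")
        rep2 = planarity_report(list(reversed(o)), modality="CT")
        pd.testing.assert_frame_equal(rep1, rep2)


def test_paired_coordinate_report_layout(rng):
    a = rng.normal(0, 5, size=(8, 3))
    b = a + rng.normal(0, 0.1, size=(8, 3))
    labels = ["left_superior_sscc"] * 4 + ["right_superior_sscc"] * 4
    rep = paired_coordinate_report(a, b, labels)
    assert set(rep.landmark) == set(labels)
    assert list(rep.columns) == ["landmark", "coordinate", "r", "p", "mean", "sd", "max"]
    assert len(rep) == 6
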