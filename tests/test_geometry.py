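"""Geometric primitives and the landmark -> parameter extraction."""

import math

import numpy as np
import pytest

from posturekit.errors import (
    DegenerateSegmentError,
    InsufficientDataError,
    UndefinedMeanError,
    WrongViewError,
)
from posturekit.geometry import (
    PARAMETER_NAMES,
    angle_between,
    circular_mean,
    compute_profile,
    fuse_views,
    horizontal_inclination,
    joint_angles,
    lateral_parameters,
    vector_lengths,
    vertical_inclination,
)
from posturekit.model import Landmark, PoseCapture, SubjectRecord
from posturekit.synthetic import SyntheticSpec, generate_cohort


class TestPrimitives:
    @pytest.mark.parametrize(
        "u,v,expected",
        [
            ((1, 0, 0), (0, 1, 0), 90.0),
            ((1, 1, 0), (2, 2, 0), 0.0),
            ((1, 0, 0), (-1, 1e-9, 0), 180.0),
            ((1, 0, 0), (1, 1, 0), 45.0),
        ],
    )
    def test_angle_between(self, u, v, expected):
        assert angle_between(u, v) == pytest.approx(expected, abs=1e-6)

    def test_angle_between_rejects_zero_vector(self):
        with pytest.raises(DegenerateSegmentError):
            angle_between((0, 0, 0), (1, 0, 0))

    @pytest.mark.parametrize(
        "angles,expected",
        [([350, 10], 0.0), ([10, 10, 10], 10.0), ([0, 90], 45.0), ([359, 1], 0.0)],
    )
    def test_circular_mean_wraparound(self, angles, expected):
        got = circular_mean(angles)
        dist = min(abs(got - expected), 360 - abs(got - expected))
        assert dist == pytest.approx(0.0, abs=1e-9)
        assert 0.0 <= got < 360.0

    def test_circular_mean_antipodal_undefined(self):
        with pytest.raises(UndefinedMeanError):
            circular_mean([0.0, 180.0])

    def test_circular_mean_resultant_length(self):
        mean, r = circular_mean([10, 10], return_resultant=True)
        assert r == pytest.approx(1.0)
        _, r2 = circular_mean([0, 90], return_resultant=True)
        assert r2 < 1.0

    def test_circular_mean_tracks_arithmetic_within_narrow_arc(self, rng):
        """Inside a 90-degree arc the circular mean is exactly the midpoint
        for pairs, and stays inside the arc and close to the arithmetic
        mean for larger samples."""
        for _ in range(50):
            base = rng.uniform(0, 360)
            pair = (base + rng.uniform(0, 80, size=2)) % 360
            expected = (np.mean(pair) if abs(pair[0] - pair[1]) < 180 else np.mean(pair) + 180) % 360
            got = circular_mean(pair)
            dist = min(abs(got - expected), 360 - abs(got - expected))
            assert dist == pytest.approx(0.0, abs=1e-9)
        for _ in range(50):
            base = rng.uniform(0, 270)
            a = base + rng.uniform(0, 80, size=6)
            got = circular_mean(a % 360)
            assert a.min() - 1e-9 <= (got if got >= base else got + 360) <= a.max() + 1e-9
            assert abs(got - np.mean(a)) < 3.0

    @pytest.mark.parametrize(
        "a,b,expected",
        [(((0, 100)), ((50, 100)), 0.0), (((0, 0)), ((10, 10)), 45.0)],
    )
    def test_horizontal_inclination(self, a, b, expected):
        assert horizontal_inclination(a, b) == pytest.approx(expected)
        assert horizontal_inclination(b, a) == pytest.approx(expected)

    def test_vertical_inclination_plumb_and_diagonal(self):
        assert vertical_inclination((0, 0), (0, 10)) == pytest.approx(0.0)
        assert vertical_inclination((0, 0), (10, 10)) == pytest.approx(45.0)
        # translation invariance
        assert vertical_inclination((5, 7), (15, 17)) == pytest.approx(45.0)

    def test_inclination_rejects_coincident_points(self):
        with pytest.raises(DegenerateSegmentError):
            horizontal_inclination((1, 1), (1, 1))


class TestCaptureOperations:
    def test_joint_angles_requires_coronal_view(self, mean_male_captures):
        with pytest.raises(WrongViewError):
            joint_angles(mean_male_captures["lateral"])

    def test_lateral_parameters_requires_lateral_view(self, mean_male_captures):
        with pytest.raises(WrongViewError):
            lateral_parameters(mean_male_captures["frontal"])

    def test_frontal_and_dorsal_angles_agree_at_zero_jitter(self, mean_male_captures):
        va_f = joint_angles(mean_male_captures["frontal"])
        va_d = joint_angles(mean_male_captures["dorsal"])
        for param in va_f.angles:
            for side in ("left", "right"):
                assert va_f.angles[param][side] == pytest.approx(
                    va_d.angles[param][side], abs=1e-9
                )

    def test_fuse_views_idempotent_and_fallback(self, mean_male_captures, caplog):
        va = joint_angles(mean_male_captures["frontal"])
        fused_both = fuse_views(va, joint_angles(mean_male_captures["dorsal"]))
        import logging

        with caplog.at_level(logging.WARNING, logger="posturekit.geometry"):
            fused_single = fuse_views(va, None)
        assert caplog.records  # fallback logged
        for param in fused_both:
            assert fused_both[param] == pytest.approx(fused_single[param], abs=1e-9)
        with pytest.raises(InsufficientDataError):
            fuse_views(None, None)

    def test_vector_lengths_hand_toy(self):
        # shoulders at (0,0),(100,0); hips at (20,200),(80,200)
        base = {
            "left_shoulder": (100, 0),
            "right_shoulder": (0, 0),
            "left_hip": (80, 200),
            "right_hip": (20, 200),
            "left_elbow": (100, 100),
            "right_elbow": (0, 100),
            "left_wrist": (100, 180),
            "right_wrist": (0, 180),
            "left_knee": (80, 400),
            "right_knee": (20, 400),
            "left_ankle": (80, 600),
            "right_ankle": (20, 600),
        }
        from posturekit.topology import LANDMARK_NAMES

        landmarks = {
            n: Landmark(n, *base.get(n, (50, -50)), 0.0, 1.0) for n in LANDMARK_NAMES
        }
        cap = PoseCapture("toy", 1, "frontal", landmarks)
        v = vector_lengths(cap)
        assert v["shoulder_hip_difference"] == pytest.approx(40.0)
        assert v["torso_vector"] == pytest.approx(200.0)
        assert v["total_arm_vector"] == pytest.approx(180.0)
        assert v["total_leg_vector"] == pytest.approx(400.0)

    def test_vectors_scale_linearly_angles_invariant(self, mean_male_captures, mean_male_params):
        cap = mean_male_captures["frontal"]
        from posturekit.topology import LANDMARK_NAMES

        doubled = PoseCapture(
            "s", 1, "frontal",
            {
                n: Landmark(n, 2 * cap[n].x, 2 * cap[n].y, 2 * cap[n].z, 1.0)
                for n in LANDMARK_NAMES
            },
        )
        v1, v2 = vector_lengths(cap), vector_lengths(doubled)
        for key in v1:
            assert v2[key] == pytest.approx(2 * v1[key], rel=1e-12)
        a1, a2 = joint_angles(cap), joint_angles(doubled)
        for param in a1.angles:
            for side in ("left", "right"):
                assert a2.angles[param][side] == pytest.approx(
                    a1.angles[param][side], abs=1e-9
                )


class TestProfile:
    def test_noiseless_profiles_match_ground_truth(self, small_cohort):
        cohort, truth = small_cohort
        for i, subject in enumerate(cohort):
            prof = compute_profile(subject, 1)
            expected = truth.session_profiles[1][i]
            assert np.allclose(prof.as_array(), expected, atol=1e-6)

    def test_lateral_means_recovered(self, mean_male_captures, mean_male_params):
        neck, trunk = lateral_parameters(mean_male_captures["lateral"])
        assert neck == pytest.approx(mean_male_params["neck_inclination"], abs=1e-9)
        assert trunk == pytest.approx(
            mean_male_params["trunk_forward_inclination"], abs=1e-9
        )

    def test_missing_lateral_flags_neck_and_trunk(self, small_cohort):
        cohort, _ = small_cohort
        subject = cohort.subjects[0]
        partial = SubjectRecord(
            subject_id=subject.subject_id,
            sex=subject.sex,
            captures=[c for c in subject.captures if c.view != "lateral"],
        )
        prof = compute_profile(partial, 1)
        assert set(prof.missing) == {"neck_inclination", "trunk_forward_inclination"}
        assert math.isnan(prof["neck_inclination"])
        assert math.isfinite(prof["shoulder_adduction"])

    def test_no_coronal_capture_raises(self, small_cohort):
        cohort, _ = small_cohort
        subject = cohort.subjects[0]
        lateral_only = SubjectRecord(
            subject_id="x",
            captures=[c for c in subject.captures if c.view == "lateral"],
        )
        with pytest.raises(InsufficientDataError):
            compute_profile(lateral_only, 1)

    def test_jitter_error_shrinks_with_noise(self):
        """Mean absolute extraction error decreases when jitter halves."""
        errors = {}
        for jitter in (3.0, 1.5):
            spec = SyntheticSpec(n_subjects=15, seed=11, jitter_sd=jitter, retest_n=0)
            cohort, truth = generate_cohort(spec)
            errs = []
            for i, subject in enumerate(cohort):
                prof = compute_profile(subject, 1)
                idx = PARAMETER_NAMES.index("shoulder_adduction")
                errs.append(abs(prof["shoulder_adduction"] - truth.session_profiles[1][i][idx]))
            errors[jitter] = np.mean(errs)
        assert errors[1.5] < errors[3.0]
        assert errors[1.5] < 1.5  # degrees, well-behaved at 1.5 px


class TestMirrorSymmetry:
    def test_reflection_leaves_parameters_unchanged(self, mean_male_captures):
        """Reflecting a capture about the vertical midline (with left/right
        labels swapped accordingly) leaves all side-averaged parameters
        unchanged."""
        from posturekit.topology import LANDMARK_NAMES

        def reflect(cap, view):
            swapped = {}
            for n in LANDMARK_NAMES:
                other = (
                    n.replace("left", "TMP").replace("right", "left").replace("TMP", "right")
                    if ("left" in n or "right" in n)
                    else n
                )
                lm = cap[other]
                swapped[n] = Landmark(n, 800 - lm.x, lm.y, lm.z, lm.visibility)
            return PoseCapture(cap.subject_id, cap.session, view, swapped)

        frontal, dorsal = mean_male_captures["frontal"], mean_male_captures["dorsal"]
        # reflection turns a frontal photo into a dorsal-convention photo
        subject = SubjectRecord(
            "orig", captures=[frontal, dorsal, mean_male_captures["lateral"]]
        )
        mirrored = SubjectRecord(
            "mirr",
            captures=[
                reflect(frontal, "dorsal"),
                reflect(dorsal, "frontal"),
                mean_male_captures["lateral"],
            ],
        )
        p1 = compute_profile(subject, 1).as_array()
        p2 = compute_profile(mirrored, 1).as_array()
        assert np.allclose(p1, p2, atol=1e-9)
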