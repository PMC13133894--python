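"""Lovibond angle computation, severity grading and the cascade bypass rule."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import clubkit as ck
from clubkit.cfsa import DEFAULT_THRESHOLDS, GRADE_ORDER
from clubkit.landmarks import LandmarkTriplet


def triplet(a, b, c):
    return LandmarkTriplet.from_array([a, b, c])


def polar_c(b, deg_from_x, r=10.0):
    """C placed r away from B at the given direction (y-down coordinates)."""
    return [b[0] + r * math.cos(math.radians(deg_from_x)),
            b[1] + r * math.sin(math.radians(deg_from_x))]


class TestLovibondAngle:
    @pytest.mark.parametrize(
        "direction_deg, expected_theta",
        [
            (0.0, 180.0),     # collinear continuation -> straight profile
            (20.0, 160.0),    # 20 deg palmar turn -> the classic normal angle
            (-10.0, 190.0),   # dorsal (reflex) turn -> clubbing configuration
        ],
    )
    def test_constructed_turns(self, direction_deg, expected_theta):
        b = [10.0, 0.0]
        t = triplet([0.0, 0.0], b, polar_c(b, direction_deg))
        m = ck.compute_lovibond_angle(t)
        assert m.theta_deg == pytest.approx(expected_theta, abs=1e-9)
        assert m.theta_deg + m.turn_deg == pytest.approx(180.0, abs=1e-9)

    def test_matches_arctangent_oracle_on_random_triplets(self, rng):
        """Cross/dot formulation agrees with an azimuth-difference oracle."""
        for _ in range(1000):
            pts = rng.uniform(-100, 100, size=(3, 2))
            u = pts[1] - pts[0]
            v = pts[2] - pts[1]
            if np.linalg.norm(u) < 1e-6 or np.linalg.norm(v) < 1e-6:
                continue
            tau_oracle = math.degrees(
                math.atan2(v[1], v[0]) - math.atan2(u[1], u[0])
            )
            tau_oracle = (tau_oracle + 180.0) % 360.0 - 180.0
            theta_oracle = 180.0 - tau_oracle
            if not 1e-9 < theta_oracle < 360.0 - 1e-9:
                continue
            m = ck.compute_lovibond_angle(LandmarkTriplet.from_array(pts))
            assert m.theta_deg == pytest.approx(theta_oracle, abs=1e-9)

    def test_similarity_invariance_with_frame(self, rng):
        """theta is invariant to rotation/translation/scale and, through the
        canonical frame, to mirror flips."""
        base = triplet([0.0, 0.0], [10.0, 0.0], polar_c([10.0, 0.0], 25.0))
        theta0 = ck.compute_lovibond_angle(base).theta_deg
        for _ in range(200):
            ang = rng.uniform(-180, 180)
            scale = rng.uniform(0.1, 10)
            shift = rng.uniform(-50, 50, 2)
            flip = bool(rng.integers(2))
            a = np.radians(ang)
            rot = scale * np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
            pts = base.as_array() @ rot.T + shift
            if flip:
                pts[:, 0] *= -1
            # the frame undoing the similarity: rotation by -ang and the flip
            frame = ck.CanonicalFrame(
                rotation_deg=-ang if not flip else ang + 180.0,
                translation=np.zeros(2),
                flip_applied=flip,
            )
            theta = ck.compute_lovibond_angle(
                LandmarkTriplet.from_array(pts), frame
            ).theta_deg
            assert theta == pytest.approx(theta0, abs=1e-9)

    def test_degenerate_triplets_raise(self):
        with pytest.raises(ck.DegenerateTripletError):
            ck.compute_lovibond_angle(triplet([0, 0], [0, 0], [5, 5]))
        with pytest.raises(ck.DegenerateTripletError):
            # antiparallel: C back through B towards A
            ck.compute_lovibond_angle(triplet([0, 0], [10, 0], [0, 0]))


class TestGrading:
    @pytest.mark.parametrize(
        "theta, expected",
        [
            (150.0, "normal"),
            (160.0, "normal"),      # boundary belongs to normal
            (160.001, "mild"),
            (170.0, "mild"),
            (179.0, "moderate"),    # edge of the +/-1 deg band
            (180.0, "moderate"),
            (181.0, "moderate"),
            (181.001, "severe"),
            (185.0, "severe"),
            (195.0, "severe"),
        ],
    )
    def test_default_thresholds(self, theta, expected):
        assert str(ck.grade_severity(theta)) == expected

    def test_band_width_is_configurable(self):
        t = ck.SeverityThresholds(moderate_band_deg=1.0)
        assert str(ck.grade_severity(179.5, t)) == "moderate"
        t = ck.SeverityThresholds(moderate_band_deg=0.1)
        assert str(ck.grade_severity(179.5, t)) == "mild"

    def test_out_of_domain_raises(self):
        for theta in (0.0, -5.0, 360.0, 400.0):
            with pytest.raises(ck.ValidationError):
                ck.grade_severity(theta)

    def test_threshold_consistency_enforced(self):
        with pytest.raises(ck.ValidationError):
            ck.SeverityThresholds(normal_max_deg=179.5, moderate_band_deg=1.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        t1=st.floats(min_value=0.001, max_value=359.999),
        t2=st.floats(min_value=0.001, max_value=359.999),
    )
    def test_grading_is_total_and_monotone(self, t1, t2):
        g1, g2 = ck.grade_severity(t1), ck.grade_severity(t2)
        assert g1 in GRADE_ORDER and g2 in GRADE_ORDER
        if t1 <= t2:
            assert g1 <= g2


class TestBinaryStage:
    @pytest.mark.parametrize("theta, expected", [(150.0, False), (160.0, False), (161.0, True)])
    def test_cutoff_convention(self, theta, expected):
        m = ck.AngleMeasurement.from_theta(theta)
        assert ck.classify_clubbing(m) is expected

    def test_agrees_with_grader_about_normal(self, rng):
        """Binary stage and grader agree that non-clubbing <=> normal grade."""
        for theta in rng.uniform(90.1, 269.9, 300):
            m = ck.AngleMeasurement.from_theta(theta)
            is_normal = ck.grade_severity(theta) == ck.SeverityGrade.NORMAL
            assert ck.classify_clubbing(m) == (not is_normal)


class TestAssessCascade:
    def test_severe_sample_graded_severe(self):
        s = ck.render_finger_profile(ck.FingerProfileSpec(lovibond_angle_deg=200, seed=5))
        res = ck.assess(s.image)
        assert res.status == "ok"
        assert res.clubbing_detected is True
        assert str(res.grade) == "severe"
        assert res.angle is not None and res.landmarks is not None

    def test_normal_sample_bypasses_grading(self):
        s = ck.render_finger_profile(ck.FingerProfileSpec(lovibond_angle_deg=155, seed=5))
        res = ck.assess(s.image)
        assert res.status == "ok"
        assert res.clubbing_detected is False
        assert str(res.grade) == "normal"
        assert res.angle is None and res.landmarks is None  # bypass rule

    def test_out_of_range_capture_is_rejected_without_grading(self):
        s = ck.render_finger_profile(
            ck.FingerProfileSpec(lovibond_angle_deg=200, distance_cm=9.0, seed=5)
        )
        res = ck.assess(s.image)
        assert res.status == "rejected"
        assert res.gate.status == "too_far"
        assert res.grade is None and res.angle is None

    def test_stage_error_becomes_failure_record(self):
        res = ck.assess(np.zeros((64, 64), dtype=np.uint8))
        assert res.status == "failed"
        assert res.error["stage"] == "segment"
        assert "no finger" in res.error["message"]

    def test_result_record_is_json_friendly(self):
        import json

        s = ck.render_finger_profile(ck.FingerProfileSpec(lovibond_angle_deg=190, seed=5))
        rec = ck.assess(s.image, provenance={"input": "x.png"}).to_record()
        json.dumps(rec)
        assert rec["grade"] == "severe"
        assert rec["gate"]["status"] == "accept"

    def test_pluggable_detector_contract(self, mild_sample):
        """Any callable with the detector signature can replace the default."""
        from clubkit.landmarks import KeypointPrediction

        def perfect_detector(mask, frame, config):
            return KeypointPrediction(
                triplet=mild_sample.truth_landmarks,
                confidence={"A": 1.0, "B": 1.0, "C": 1.0},
                detector_id="oracle",
            )

        res = ck.assess(mild_sample.image, detect_fn=perfect_detector)
        assert res.status == "ok"
        assert res.landmarks.detector_id == "oracle"
        assert res.angle.theta_deg == pytest.approx(165.0, abs=1e-6)
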