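"""Synthetic fingertip-profile generator: determinism, ground truth, augmentation."""

import numpy as np
import pytest

import clubkit as ck
from clubkit.synthetic import DEFAULT_ANGLE_RANGES, sample_dataset


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kwargs, field",
        [
            (dict(lovibond_angle_deg=80), "lovibond_angle_deg"),
            (dict(lovibond_angle_deg=280), "lovibond_angle_deg"),
            (dict(lovibond_angle_deg=170, distance_cm=0.5), "distance_cm"),
            (dict(lovibond_angle_deg=170, finger_width_mm=-1), "finger_width_mm"),
            (dict(lovibond_angle_deg=170, tip_bulb_ratio=0.8), "tip_bulb_ratio"),
            (dict(lovibond_angle_deg=170, brightness=1.5), "brightness"),
            (dict(lovibond_angle_deg=170, noise_sigma=-0.1), "noise_sigma"),
        ],
    )
    def test_out_of_range_fields_are_named(self, kwargs, field):
        with pytest.raises(ck.ValidationError, match=field):
            ck.FingerProfileSpec(**kwargs)


class TestRender:
    def test_same_spec_same_seed_is_bit_identical(self):
        spec = ck.FingerProfileSpec(lovibond_angle_deg=172, seed=9)
        a = ck.render_finger_profile(spec)
        b = ck.render_finger_profile(spec)
        assert a.image.tobytes() == b.image.tobytes()
        assert np.array_equal(a.truth_landmarks.as_array(), b.truth_landmarks.as_array())
        assert a.bbox == b.bbox

    def test_truth_angle_is_exact_by_construction(self, mild_sample):
        assert mild_sample.truth_angle_deg == 165.0

    @pytest.mark.parametrize("angle", [160.0, 175.0, 190.0, 210.0])
    def test_landmark_triplet_realizes_requested_angle(self, angle):
        s = ck.render_finger_profile(
            ck.FingerProfileSpec(lovibond_angle_deg=angle, seed=3, orientation_deg=20)
        )
        # orientation is a similarity transform: the unsigned profile angle
        # must survive it; undo the rotation with a matching frame
        frame = ck.CanonicalFrame(-20.0, np.zeros(2), False)
        m = ck.compute_lovibond_angle(s.truth_landmarks, frame)
        assert m.theta_deg == pytest.approx(angle, abs=1e-6)

    def test_boundary_angle_is_moderate_by_construction(self):
        s = ck.render_finger_profile(ck.FingerProfileSpec(lovibond_angle_deg=180, seed=7))
        assert str(s.truth_grade) == "moderate"

    def test_flip_preserves_truth_angle(self):
        a = ck.render_finger_profile(ck.FingerProfileSpec(lovibond_angle_deg=160, seed=2))
        b = ck.render_finger_profile(
            ck.FingerProfileSpec(lovibond_angle_deg=160, seed=2, flip=True)
        )
        assert a.truth_angle_deg == b.truth_angle_deg

    def test_landmarks_inside_bbox_inside_image(self, mild_sample):
        x0, y0, x1, y1 = mild_sample.bbox
        h, w = mild_sample.image.shape
        assert 0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h
        for p in mild_sample.truth_landmarks.as_array():
            assert x0 - 1e-9 <= p[0] < x1 and y0 - 1e-9 <= p[1] < y1

    def test_resolution_follows_camera_model(self):
        near = ck.render_finger_profile(
            ck.FingerProfileSpec(lovibond_angle_deg=170, distance_cm=4.0, seed=1)
        )
        far = ck.render_finger_profile(
            ck.FingerProfileSpec(lovibond_angle_deg=170, distance_cm=8.0, seed=1)
        )
        # pixels-per-mm halves from 4 to 8 cm, so the silhouette area drops ~4x
        ratio = near.silhouette.sum() / far.silhouette.sum()
        assert ratio == pytest.approx(4.0, rel=0.05)

    def test_bulb_area_monotone_in_ratio(self):
        areas = []
        for r in (1.0, 1.3, 1.6, 1.9):
            s = ck.render_finger_profile(
                ck.FingerProfileSpec(lovibond_angle_deg=185, tip_bulb_ratio=r, seed=4)
            )
            areas.append(int(s.silhouette.sum()))
        assert all(a2 >= a1 for a1, a2 in zip(areas, areas[1:]))


class TestSampleDataset:
    def test_counts_and_determinism(self):
        s1, m1 = sample_dataset(100, seed=1)
        s2, m2 = sample_dataset(100, seed=1)
        assert len(s1) == len(m1) == 100
        assert m1["grade"].isin(["normal", "mild", "moderate", "severe"]).all()
        assert m1.equals(m2)
        assert s1[17].image.tobytes() == s2[17].image.tobytes()

    def test_empty_cohort(self):
        samples, manifest = sample_dataset(0, seed=1)
        assert samples == [] and len(manifest) == 0

    def test_pure_normal_mix(self):
        _, manifest = sample_dataset(400, grade_mix=(1, 0, 0, 0), seed=2, render=False)
        assert (manifest["grade"] == "normal").all()
        assert (manifest["angle_deg"] <= 160.0).all()

    def test_manifest_labels_consistent_with_grader(self):
        _, manifest = sample_dataset(1000, seed=5, render=False)
        for _, row in manifest.iterrows():
            assert str(ck.grade_severity(row["angle_deg"])) == row["grade"]

    def test_angle_range_straddling_boundary_rejected(self):
        ranges = dict(DEFAULT_ANGLE_RANGES, mild=(158.0, 170.0))
        with pytest.raises(ck.ValidationError, match="straddles"):
            sample_dataset(5, angle_ranges=ranges, seed=1, render=False)

    def test_bad_mix_rejected(self):
        with pytest.raises(ck.ValidationError, match="grade_mix"):
            sample_dataset(5, grade_mix=(0.5, 0.5, 0.5, -0.5), seed=1)


class TestAugment:
    def test_identity_params_bit_identical(self, mild_sample):
        out = ck.augment(mild_sample, ck.AugmentationParams())
        assert out.image.tobytes() == mild_sample.image.tobytes()
        assert np.array_equal(
            out.truth_landmarks.as_array(), mild_sample.truth_landmarks.as_array()
        )

    def test_flip_is_an_involution(self, mild_sample):
        p = ck.AugmentationParams(flip_horizontal=True)
        twice = ck.augment(ck.augment(mild_sample, p), p)
        assert np.allclose(
            twice.truth_landmarks.as_array(),
            mild_sample.truth_landmarks.as_array(),
            atol=0.5,
        )
        assert twice.image.tobytes() == mild_sample.image.tobytes()

    def test_flip_preserves_angle_and_grade(self, mild_sample):
        out = ck.augment(mild_sample, ck.AugmentationParams(flip_horizontal=True))
        assert out.truth_angle_deg == mild_sample.truth_angle_deg
        assert out.truth_grade == mild_sample.truth_grade

    def test_scaling_scales_landmark_radii_exactly(self, mild_sample):
        s = 1.10
        out = ck.augment(mild_sample, ck.AugmentationParams(scale_factor=s))
        h, w = mild_sample.image.shape
        c = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
        r_in = np.linalg.norm(mild_sample.truth_landmarks.as_array() - c, axis=1)
        r_out = np.linalg.norm(out.truth_landmarks.as_array() - c, axis=1)
        assert np.allclose(r_out, s * r_in, rtol=1e-12)
        assert out.truth_angle_deg == mild_sample.truth_angle_deg

    def test_brightness_shifts_with_clipping(self, mild_sample):
        out = ck.augment(mild_sample, ck.AugmentationParams(brightness_delta=0.20))
        delta = out.image.astype(int) - mild_sample.image.astype(int)
        unclipped = mild_sample.image <= 255 - 51
        assert np.all(delta[unclipped] == 51)
        assert out.image.max() <= 255

    @pytest.mark.parametrize(
        "kwargs", [dict(brightness_delta=0.25), dict(scale_factor=0.8)]
    )
    def test_params_out_of_recipe_bounds_rejected(self, kwargs):
        with pytest.raises(ck.ValidationError):
            ck.AugmentationParams(**kwargs)

    def test_scale_below_minimum_size_rejected(self, mild_sample):
        from dataclasses import replace

        tiny = replace(
            mild_sample,
            image=mild_sample.image[:16, :16],
            silhouette=mild_sample.silhouette[:16, :16],
        )
        with pytest.raises(ck.ValidationError, match="scale_factor"):
            ck.augment(tiny, ck.AugmentationParams(scale_factor=0.9))

    def test_param_sampling_respects_recipe(self):
        for seed in range(30):
            p = ck.AugmentationParams.sample(seed)
            assert -0.20 <= p.brightness_delta <= 0.20
            assert 0.90 <= p.scale_factor <= 1.10
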