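"""Morphometric estimators: pitch, width, height, handedness, summaries."""

import numpy as np
import pytest

from peptoidhelix.errors import (
    DetectionError,
    DomainError,
    NoPeriodicityError,
)
from peptoidhelix.measure import (
    classify_handedness,
    estimate_height,
    estimate_pitch,
    estimate_width,
    measure_heightmap,
    measurements_to_frame,
    summarize_population,
)
from peptoidhelix.synthetic import HeightMap, PopulationSpec, generate_population, render_heightmap


def flat_stripe(thickness=2.46):
    return render_heightmap(width=10.7, thickness=thickness, pitch=1e9, length=150.0,
                            noise_sd=0.0)


class TestPitch:
    def test_noise_free_round_trip(self, reference_map):
        pitch, sd, n_periods = estimate_pitch(reference_map)
        assert pitch == pytest.approx(86.4, rel=0.01)
        assert n_periods >= 2
        assert sd >= 0.0

    def test_flat_stripe_has_no_periodicity(self):
        with pytest.raises(NoPeriodicityError):
            estimate_pitch(flat_stripe())

    def test_square_cross_section_quarter_period_is_recognised(self):
        """A near-square cross-section shows four equivalent passages per
        turn; the estimator must quadruple the spacing, not halve the pitch."""
        hm = render_heightmap(width=14.0, thickness=13.9, pitch=90.0, noise_sd=0.0,
                              phase_deg=30.0)
        pitch, _, _ = estimate_pitch(hm)
        assert pitch == pytest.approx(90.0, rel=0.02)

    def test_background_only_map_rejected(self):
        rng = np.random.default_rng(0)
        noise = np.clip(rng.normal(0.0, 0.1, size=(40, 200)), 0, None)
        with pytest.raises(DetectionError):
            estimate_pitch(HeightMap(noise, 1.0))
        with pytest.raises(DetectionError):
            estimate_pitch(HeightMap(np.zeros((40, 200)), 1.0))


class TestWidthHeight:
    @pytest.mark.parametrize("width,thickness", [(10.7, 5.2), (15.0, 5.2), (10.7, 8.0)])
    def test_noise_free_round_trip(self, width, thickness):
        hm = render_heightmap(width=width, thickness=thickness, pitch=86.4,
                              noise_sd=0.0, phase_deg=120.0)
        assert estimate_width(hm) == pytest.approx(width, rel=0.015)
        assert estimate_height(hm) == pytest.approx(thickness, rel=0.015)

    def test_untwisted_stripe_width_within_one_pixel(self):
        hm = flat_stripe()
        assert abs(estimate_width(hm) - 10.7) < 1.0  # pixel_size = 1 nm

    def test_untwisted_stripe_height_equals_thickness(self):
        assert estimate_height(flat_stripe(2.46)) == pytest.approx(2.46, rel=0.01)

    def test_background_only_map_rejected(self):
        with pytest.raises(DetectionError):
            estimate_width(HeightMap(np.zeros((30, 100)), 1.0))


class TestHandedness:
    def test_mirror_flips_label_with_identical_confidence(self, reference_map):
        label, conf = classify_handedness(reference_map)
        m_label, m_conf = classify_handedness(reference_map.mirrored())
        assert label == "right"
        assert m_label == "left"
        assert m_conf == pytest.approx(conf, abs=1e-12)

    def test_label_matches_generator_convention(self):
        for hand in ("right", "left"):
            hm = render_heightmap(width=10.7, thickness=5.2, pitch=86.4,
                                  handedness=hand, noise_sd=0.0, phase_deg=200.0)
            assert classify_handedness(hm)[0] == hand

    def test_perfect_accuracy_on_noise_free_grid(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            hand = "right" if rng.random() < 0.5 else "left"
            hm = render_heightmap(
                width=float(rng.uniform(8, 16)), thickness=float(rng.uniform(4, 7)),
                pitch=float(rng.uniform(60, 140)), handedness=hand,
                noise_sd=0.0, phase_deg=float(rng.uniform(0, 360)),
            )
            label, conf = classify_handedness(hm)
            assert label == hand
            assert conf > 0.1


class TestRotationInvariance:
    @pytest.mark.parametrize("angle", [30.0, 60.0, 90.0])
    def test_estimates_stable_under_in_plane_rotation(self, reference_map, angle):
        from skimage.transform import rotate as sk_rotate

        rotated = HeightMap(
            np.clip(sk_rotate(reference_map.grid, angle, resize=True, order=1,
                              preserve_range=True), 0.0, None),
            reference_map.pixel_size,
            axis_angle=angle,
        )
        base = measure_heightmap(reference_map)
        rot = measure_heightmap(rotated)
        assert rot.pitch_nm == pytest.approx(base.pitch_nm, rel=0.02)
        assert rot.width_nm == pytest.approx(base.width_nm, rel=0.02)
        assert rot.height_nm == pytest.approx(base.height_nm, rel=0.02)
        assert rot.handedness == base.handedness


class TestPopulationRecovery:
    def test_preset_noise_cohort_recovered(self):
        """Small ph7-type cohort at preset noise: means within 3% of the
        generator truth and every handedness call correct."""
        spec = PopulationSpec(n_helices=10, seed=31)
        maps, truth = generate_population(spec)
        results = [measure_heightmap(m) for m in maps]
        assert np.mean([m.pitch_nm for m in results]) == pytest.approx(
            truth.pitch_nm.mean(), rel=0.03
        )
        assert np.mean([m.width_nm for m in results]) == pytest.approx(
            truth.width_nm.mean(), rel=0.03
        )
        assert np.mean([m.height_nm for m in results]) == pytest.approx(
            truth.height_nm.mean(), rel=0.03
        )
        assert [m.handedness for m in results] == list(truth.handedness)


class TestSummary:
    def test_single_measurement_has_no_spread(self, reference_map):
        summary = summarize_population([measure_heightmap(reference_map)])
        assert summary.width_sd is None
        assert summary.width_n == 1
        assert "n = 1" in summary.formatted()["width"]

    def test_identical_measurements_have_zero_spread(self, reference_map):
        m = measure_heightmap(reference_map)
        summary = summarize_population([m, m])
        assert summary.width_sd == pytest.approx(0.0)
        assert summary.pitch_sd == pytest.approx(0.0)
        assert summary.fraction_right == 1.0

    def test_formatted_strings_shape(self, reference_map):
        m = measure_heightmap(reference_map)
        text = summarize_population([m, m]).formatted()["pitch"]
        assert "±" in text and "nm" in text and "(n = 2)" in text

    def test_empty_input_rejected(self):
        with pytest.raises(DomainError):
            summarize_population([])

    def test_frame_has_one_row_per_map(self, reference_map):
        m = measure_heightmap(reference_map)
        frame = measurements_to_frame([m, m, m])
        assert len(frame) == 3
        assert {"pitch_nm", "width_nm", "height_nm", "handedness"} <= set(frame.columns)
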