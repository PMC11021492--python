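"""Synthetic generators: relaxation trajectories, height maps, populations."""

import numpy as np
import pytest
from scipy.optimize import curve_fit

from peptoidhelix.errors import DomainError
from peptoidhelix.synthetic import (
    POPULATION_PRESETS,
    HeightMap,
    PopulationSpec,
    RelaxationParams,
    generate_population,
    load_heightmap,
    render_heightmap,
    save_heightmap,
    simulate_twist_relaxation,
)


class TestRelaxation:
    def test_bit_identical_for_identical_seeds(self):
        a = simulate_twist_relaxation(RelaxationParams(seed=3))
        b = simulate_twist_relaxation(RelaxationParams(seed=3))
        assert np.array_equal(a.theta, b.theta)
        c = simulate_twist_relaxation(RelaxationParams(seed=4))
        assert not np.array_equal(a.theta, c.theta)

    def test_noise_free_closed_form_at_20ns(self):
        """With τ = 5 ns the twist reaches θ_eq·(1 − e⁻⁴) = 98.2% by 20 ns."""
        series = simulate_twist_relaxation(RelaxationParams(sigma=0.0))
        idx = int(round(20.0 / 0.1))
        expected = 98.0 * (1.0 - np.exp(-4.0))
        assert series.mean[idx] == pytest.approx(expected, rel=1e-12)
        assert np.all(series.sd == pytest.approx(0.0))

    def test_exponential_fit_recovers_tau_exactly_without_noise(self):
        series = simulate_twist_relaxation(RelaxationParams(sigma=0.0, n_runs=1))

        def f(t, a, tau):
            return a * (1.0 - np.exp(-t / tau))

        (a, tau), _ = curve_fit(f, series.time, series.mean, p0=(80.0, 2.0))
        assert tau == pytest.approx(5.0, rel=0.01)
        assert a == pytest.approx(98.0, rel=0.01)

    def test_plateau_mean_within_fluctuation_bound(self):
        p = RelaxationParams(seed=0)
        series = simulate_twist_relaxation(p)
        n_fin = int(0.2 * len(series.time))
        final = float(series.mean[-n_fin:].mean())
        # OU time-average variance over a window T >> tau is ~ 2 sigma^2 tau/T
        window = series.time[-1] - series.time[-n_fin]
        se = np.sqrt(2 * p.sigma**2 * p.tau / window / p.n_runs)
        assert abs(final - p.theta_eq) < 2 * se

    def test_single_run_flagged(self):
        series = simulate_twist_relaxation(RelaxationParams(n_runs=1, seed=1))
        assert series.single_run and np.all(series.sd == 0.0)

    @pytest.mark.parametrize("kwargs", [{"tau": 0.0}, {"dt": 0.0}, {"t_total": 0.01}, {"n_runs": 0}])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(DomainError):
            RelaxationParams(**{"dt": 0.1, **kwargs})


class TestHeightMap:
    def test_untwisted_stripe_is_flat_at_thickness(self):
        hm = render_heightmap(width=10.7, thickness=2.46, pitch=1e9, length=120.0,
                              noise_sd=0.0, tip_sigma=0.0)
        on = hm.grid[hm.grid > 1.0]
        assert on.size > 0
        assert np.allclose(on, 2.46, atol=1e-4)
        assert hm.grid.max() == pytest.approx(2.46, abs=1e-4)

    def test_axial_profile_repeats_every_half_pitch(self, reference_map):
        """Two-fold cross-section symmetry: the noise-free max-height profile
        autocorrelation peaks at lag pitch/2."""
        from scipy.signal import find_peaks

        profile = reference_map.grid.max(axis=0)
        y = profile - profile.mean()
        acf = np.correlate(y, y, mode="full")[len(y) - 1 :]
        peaks, _ = find_peaks(acf / acf[0], height=0.5)
        assert peaks.size > 0
        assert peaks[0] == pytest.approx(86.4 / 2.0, abs=2.0)

    def test_footprint_height_bounds(self, reference_map):
        fp = reference_map.grid[reference_map.grid > 1.0]
        assert fp.max() <= np.hypot(10.7, 5.2) + 1e-6
        profile = reference_map.grid.max(axis=0)
        interior = profile[5:-5]
        assert interior.min() >= 5.2 - 0.5  # face-on floor, minus blur tolerance

    def test_bit_identical_for_identical_seeds(self):
        kw = dict(width=10.7, thickness=5.2, pitch=86.4, noise_sd=0.1)
        assert np.array_equal(render_heightmap(**kw, seed=5).grid,
                              render_heightmap(**kw, seed=5).grid)

    def test_height_cap_clips(self):
        hm = render_heightmap(width=10.7, thickness=5.2, pitch=86.4, noise_sd=0.0,
                              height_cap=6.0)
        assert hm.grid.max() <= 6.0

    def test_text_round_trip(self, tmp_path, reference_map):
        path = tmp_path / "map.txt"
        save_heightmap(reference_map, path, seed=9)
        back = load_heightmap(path)
        assert np.allclose(back.grid, reference_map.grid, atol=1e-4)
        assert back.pixel_size == reference_map.pixel_size

    def test_invalid_geometry_rejected(self):
        with pytest.raises(DomainError):
            render_heightmap(width=-1.0, thickness=5.2, pitch=86.4)
        with pytest.raises(DomainError):
            render_heightmap(width=10.7, thickness=5.2, pitch=0.0)
        with pytest.raises(DomainError):
            HeightMap(np.full((4, 4), np.nan), 1.0)


class TestPopulation:
    def test_truth_table_is_complete_and_reproducible(self):
        spec = PopulationSpec(n_helices=8, seed=21)
        maps_a, truth_a = generate_population(spec)
        maps_b, truth_b = generate_population(spec)
        assert len(maps_a) == 8
        assert len(truth_a) == 8
        assert not truth_a.isna().any().any()
        assert truth_a.equals(truth_b)
        for a, b in zip(maps_a, maps_b):
            assert np.array_equal(a.grid, b.grid)

    def test_draws_match_spec_within_sampling_error(self):
        spec = PopulationSpec(n_helices=200, seed=13)
        _, truth = generate_population(spec)
        se = spec.pitch_sd / np.sqrt(spec.n_helices)
        assert abs(truth.pitch_nm.mean() - spec.pitch_mean) < 3 * se
        assert (truth[["width_nm", "height_nm", "pitch_nm"]] > 0).all().all()

    def test_racemic_handedness_counts_are_binomial(self):
        _, truth = generate_population(PopulationSpec(n_helices=200, seed=3))
        n_right = int((truth.handedness == "right").sum())
        # 4 sigma binomial band around 100/200
        assert abs(n_right - 100) < 4 * np.sqrt(200 * 0.25)

    def test_presets_encode_measured_statistics(self):
        ph7, ph4 = POPULATION_PRESETS["ph7"], POPULATION_PRESETS["ph4"]
        assert (ph7.pitch_mean, ph7.pitch_sd) == (86.4, 6.7)
        assert (ph7.height_mean, ph7.height_sd) == (5.2, 0.4)
        assert (ph7.width_mean, ph7.width_sd) == (10.7, 1.7)
        assert (ph4.pitch_mean, ph4.pitch_sd) == (110.1, 20.3)
        assert (ph4.height_mean, ph4.height_sd) == (15.6, 2.4)
        assert ph7.handedness_fraction_right == ph4.handedness_fraction_right == 0.5

    def test_invalid_spec_rejected(self):
        with pytest.raises(DomainError):
            PopulationSpec(n_helices=0)
        with pytest.raises(DomainError):
            PopulationSpec(handedness_fraction_right=1.5)
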