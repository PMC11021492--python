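"""Ribbon building, the twist-dihedral order parameter and pitch geometry."""

import numpy as np
import pytest

from peptoidhelix.errors import (
    DegenerateGeometryError,
    DomainError,
    FlatRibbonError,
    InsufficientDataError,
)
from peptoidhelix.geometry import (
    LabeledCoordinates,
    RibbonLattice,
    build_ribbon,
    pitch_from_twist,
    twist_dihedral,
    twist_profile,
)

from .conftest import twisted_plane


def random_rotation(seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


class TestBuildRibbon:
    def test_lattice_counting(self):
        rib = build_ribbon(n_width=5, n_length=7)
        lattice = RibbonLattice()
        assert rib.n_points == 5 * 7 * 2 * lattice.residues_per_chain
        assert rib.n_monomers == 5 * 7 * 2

    def test_flat_ribbon_backbone_planes_are_coplanar(self):
        rib = build_ribbon(n_width=4, n_length=4)
        lattice = RibbonLattice()
        backbone = rib.residue < lattice.residues_per_chain - 1
        upper = (rib.leaflet > 0) & backbone
        assert np.allclose(rib.positions[upper, 2], lattice.backbone_gap / 2)
        polar_upper = (rib.leaflet > 0) & ~backbone
        assert np.allclose(rib.positions[polar_upper, 2], lattice.bilayer_thickness / 2)

    def test_end_to_end_rotation_matches_construction(self):
        """Pitch 87 nm over a 23.7 nm contour twists the end cross-sections
        by 98° relative to each other, by construction."""
        rib = build_ribbon(n_width=23, length_nm=23.7, pitch_nm=87.0)
        span = rib.positions[:, 0].max() - rib.positions[:, 0].min()
        first = rib.positions[rib.positions[:, 0] == rib.positions[:, 0].min()]
        last = rib.positions[rib.positions[:, 0] == rib.positions[:, 0].max()]
        # width direction at each end from the extreme backbone points
        v1 = first[np.argmax(first[:, 1] ** 2 + first[:, 2] ** 2)][1:]
        v2 = last[np.argmax(last[:, 1] ** 2 + last[:, 2] ** 2)][1:]
        angle = np.degrees(
            np.arccos(np.clip(v1 @ v2 / np.linalg.norm(v1) / np.linalg.norm(v2), -1, 1))
        )
        assert angle == pytest.approx(360.0 * span / 87.0, abs=1e-6)
        assert angle == pytest.approx(98.0, abs=1.0)

    def test_noise_is_seed_reproducible(self):
        a = build_ribbon(4, 4, pitch_nm=87.0, noise_sd=0.05, seed=11)
        b = build_ribbon(4, 4, pitch_nm=87.0, noise_sd=0.05, seed=11)
        assert np.array_equal(a.positions, b.positions)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_width": 1, "n_length": 4},
            {"n_width": 4, "n_length": 1},
            {"n_width": 4, "n_length": 4, "pitch_nm": 0.0},
            {"n_width": 4, "n_length": 4, "noise_sd": -0.1},
            {"n_width": 4, "n_length": 4, "handedness": "up"},
            {"n_width": 4, "n_length": 4, "length_nm": 10.0},
            {"n_width": 4},
        ],
    )
    def test_invalid_arguments_rejected(self, kwargs):
        with pytest.raises(DomainError):
            build_ribbon(**kwargs)


class TestTwistDihedral:
    def test_flat_ribbon_measures_zero(self):
        result = twist_dihedral(build_ribbon(6, 10))
        assert abs(result.theta_deg) < 1e-9
        assert result.handedness == "flat"
        assert result.pitch_nm is None

    def test_ideal_ribbon_matches_printed_twist(self, ideal_ribbon):
        """Pitch 87 nm over 23.7 nm gives the 98° global twist dihedral."""
        result = twist_dihedral(ideal_ribbon)
        assert result.theta_deg == pytest.approx(98.0, abs=1.0)
        assert result.handedness == "right"
        assert result.pitch_nm == pytest.approx(87.0, rel=1e-6)

    @pytest.mark.parametrize("pitch", [60.0, 87.0, 200.0])
    @pytest.mark.parametrize("n_width", [4, 23])
    def test_round_trip_against_analytic_twist(self, pitch, n_width):
        """Measured θ equals 360·L/P within 0.5° for any built ribbon whose
        total twist stays below 170°."""
        n_length = 8
        rib = build_ribbon(n_width=n_width, n_length=n_length, pitch_nm=pitch)
        span = rib.positions[:, 0].max() - rib.positions[:, 0].min()
        expected = 360.0 * span / pitch
        assert expected <= 170.0
        assert twist_dihedral(rib).theta_deg == pytest.approx(expected, abs=0.5)

    def test_degrades_gracefully_under_noise(self):
        rib = build_ribbon(23, length_nm=23.7, pitch_nm=87.0, noise_sd=0.05, seed=5)
        assert twist_dihedral(rib).theta_deg == pytest.approx(98.4, abs=3.0)

    def test_mirror_antisymmetry(self, ideal_ribbon):
        theta = twist_dihedral(ideal_ribbon).theta_deg
        mirrored = twist_dihedral(ideal_ribbon.mirrored())
        assert mirrored.theta_deg == pytest.approx(-theta, abs=1e-8)
        assert mirrored.handedness == "left"

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_rigid_motion_invariance(self, ideal_ribbon, seed):
        theta = twist_dihedral(ideal_ribbon).theta_deg
        rng = np.random.default_rng(seed)
        moved = ideal_ribbon.transformed(random_rotation(seed), rng.normal(size=3) * 10)
        assert twist_dihedral(moved).theta_deg == pytest.approx(theta, abs=1e-6)

    @pytest.mark.parametrize("hand,sign", [("right", 1.0), ("left", -1.0)])
    def test_analytic_twisted_plane_oracle(self, hand, sign):
        """On an exactly parameterised twisted plane the edge-vector θ equals
        the closed-form rotation angle."""
        pitch, length = 120.0, 40.0
        plane = twisted_plane(pitch, length, half_width_nm=5.0, handedness=hand)
        expected = sign * 360.0 * length / pitch
        assert twist_dihedral(plane).theta_deg == pytest.approx(expected, abs=0.1)

    def test_single_column_rejected(self):
        rib = build_ribbon(2, 4)
        narrow = LabeledCoordinates(
            positions=rib.positions[rib.column == 0],
            monomer_id=rib.monomer_id[rib.column == 0],
            leaflet=rib.leaflet[rib.column == 0],
            column=rib.column[rib.column == 0],
            segment=rib.segment[rib.column == 0],
            residue=rib.residue[rib.column == 0],
        )
        with pytest.raises(InsufficientDataError):
            twist_dihedral(narrow)

    def test_coincident_points_rejected(self):
        rib = build_ribbon(3, 4)
        degenerate = rib.copy()
        degenerate.positions[:] = 1.0
        with pytest.raises(DegenerateGeometryError):
            twist_dihedral(degenerate)


class TestTwistProfile:
    def test_replicated_flat_frames_give_constant_zero_series(self):
        flat = build_ribbon(4, 6)
        series = twist_profile([flat] * 5, n_runs=1)
        assert np.allclose(series.mean, 0.0, atol=1e-9)
        assert series.single_run
        assert np.all(series.sd == 0.0)

    def test_identical_runs_have_zero_spread(self, ideal_ribbon):
        series = twist_profile([ideal_ribbon] * 8, n_runs=4)
        assert series.theta.shape == (4, 2)
        assert np.allclose(series.sd, 0.0)
        assert not series.single_run

    def test_mismatched_run_lengths_rejected(self, ideal_ribbon):
        with pytest.raises(DomainError):
            twist_profile([ideal_ribbon] * 7, n_runs=4)
        with pytest.raises(DomainError):
            twist_profile([[ideal_ribbon] * 2, [ideal_ribbon] * 3])

    def test_long_form_table_has_stats_per_time(self, ideal_ribbon):
        series = twist_profile([ideal_ribbon] * 4, n_runs=2)
        frame = series.to_frame()
        assert set(frame.columns) >= {"time", "run", "theta_deg", "mean_theta_deg", "sd_theta_deg"}
        assert len(frame) == 4


class TestPitchFromTwist:
    def test_printed_pair(self):
        assert pitch_from_twist(98.0, 23.7) == pytest.approx(87.06, abs=0.01)

    def test_full_turn_gives_contour_length(self):
        assert pitch_from_twist(360.0, 55.0) == pytest.approx(55.0, rel=1e-12)

    def test_flat_ribbon_has_no_finite_pitch(self):
        with pytest.raises(FlatRibbonError):
            pitch_from_twist(0.0, 55.0)

    def test_nonpositive_contour_rejected(self):
        with pytest.raises(DomainError):
            pitch_from_twist(98.0, 0.0)
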