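"""Bilayer-ribbon coordinates, twist-dihedral order parameter, handedness, pitch.

The ribbon is a two-leaflet rectangular lattice of pseudo-residues built from
the XRD-derived packing distances: peptoid chains run along the ribbon long
axis (x) with a 0.29 nm residue repeat, adjacent chains sit 0.46 nm apart
across the width (y), the two leaflets' backbone planes are separated by
1.36 nm and the polar termini define the 2.46 nm outer bilayer thickness (z).
A uniform twist rotates each cross-section about the long axis by
360°·x/pitch.

The twist dihedral θ is measured from the monomers on the two long edges of
the ribbon (the extreme column indices): per chain segment, the vector from
the lower-edge to the upper-edge centre of mass is projected onto the plane
perpendicular to the ribbon axis, its rotation angle is unwrapped along the
axis and fitted linearly, and θ is that rotation rate times the contour
length, i.e. the total end-to-end rotation of the ribbon cross-section.  For
an ideal uniformly twisted ribbon this recovers 360°·L/pitch exactly,
independent of ribbon width, and is antisymmetric under mirroring.  θ > 0 is a
right-handed twist (right-hand rule about the axis oriented by increasing
segment index).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import (
    DegenerateGeometryError,
    DomainError,
    FlatRibbonError,
    InsufficientDataError,
)

__all__ = [
    "RibbonLattice",
    "LabeledCoordinates",
    "TwistResult",
    "TrajectorySeries",
    "build_ribbon",
    "twist_dihedral",
    "twist_profile",
    "pitch_from_twist",
]

UPPER = 1  #: leaflet code for the upper leaflet (z > 0 before twisting)
LOWER = -1  #: leaflet code for the lower leaflet

#: Twist magnitudes below this many degrees are reported as flat.
FLAT_TOL_DEG = 1.0


@dataclass(frozen=True)
class RibbonLattice:
    """Packing distances of the bilayer ribbon, in nm (XRD d-spacings)."""

    residue_spacing: float = 0.29  # repeat between adjacent residues along a chain
    chain_spacing: float = 0.46  # distance between adjacent parallel chains
    backbone_gap: float = 1.36  # distance between the two leaflets' backbone planes
    bilayer_thickness: float = 2.46  # outer-surface to outer-surface
    residues_per_chain: int = 5  # four hydrophobic units + one polar terminus

    def __post_init__(self) -> None:
        if not (
            0
            < self.residue_spacing
            < self.chain_spacing
            < self.backbone_gap
            < self.bilayer_thickness
        ):
            raise DomainError(
                "lattice must satisfy 0 < residue_spacing < chain_spacing "
                "< backbone_gap < bilayer_thickness"
            )
        if self.residues_per_chain < 1:
            raise DomainError("residues_per_chain must be >= 1")

    @property
    def segment_length(self) -> float:
        """Axial period of one chain segment, nm."""
        return self.residues_per_chain * self.residue_spacing


@dataclass
class LabeledCoordinates:
    """Pseudo-residue positions (nm) with lattice labels.

    Before twisting, the ribbon long axis is x, the width is y and the
    thickness is z.  One monomer is one chain segment; its residues share
    (leaflet, column, segment) and are distinguished by ``residue``.
    """

    positions: np.ndarray  # (n_points, 3) float, nm
    monomer_id: np.ndarray  # (n_points,) int, unique per (leaflet, column, segment)
    leaflet: np.ndarray  # (n_points,) int, +1 upper / -1 lower
    column: np.ndarray  # (n_points,) int, index across the width
    segment: np.ndarray  # (n_points,) int, chain index along the length
    residue: np.ndarray  # (n_points,) int, residue index within the chain
    lattice: RibbonLattice = field(default_factory=RibbonLattice)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise DomainError("positions must have shape (n_points, 3)")
        n = len(self.positions)
        for name in ("monomer_id", "leaflet", "column", "segment", "residue"):
            arr = np.asarray(getattr(self, name), dtype=int)
            if arr.shape != (n,):
                raise DomainError(f"label array {name!r} must have shape ({n},)")
            setattr(self, name, arr)

    @property
    def n_points(self) -> int:
        return len(self.positions)

    @property
    def n_monomers(self) -> int:
        return len(np.unique(self.monomer_id))

    def copy(self) -> "LabeledCoordinates":
        return LabeledCoordinates(
            self.positions.copy(),
            self.monomer_id.copy(),
            self.leaflet.copy(),
            self.column.copy(),
            self.segment.copy(),
            self.residue.copy(),
            self.lattice,
        )

    def mirrored(self) -> "LabeledCoordinates":
        """Mirror image through the z = 0 plane (flips handedness)."""
        out = self.copy()
        out.positions[:, 2] *= -1.0
        return out

    def transformed(self, rotation: np.ndarray, translation=(0.0, 0.0, 0.0)) -> "LabeledCoordinates":
        """Apply a rigid motion x → R·x + t."""
        rotation = np.asarray(rotation, dtype=float)
        out = self.copy()
        out.positions = out.positions @ rotation.T + np.asarray(translation, dtype=float)
        return out


@dataclass(frozen=True)
class TwistResult:
    """Signed global twist dihedral of a ribbon structure."""

    theta_deg: float  # cumulative end-to-end twist; positive = right-handed
    v_u: np.ndarray  # best-fit unit vector along the upper edge COM sequence
    v_l: np.ndarray  # best-fit unit vector along the lower edge COM sequence
    handedness: str  # "right" | "left" | "flat"
    contour_length: float  # nm, extent along the fitted ribbon axis
    pitch_nm: float | None  # 360·L/|θ|; None when flat


@dataclass(frozen=True)
class TrajectorySeries:
    """Per-frame twist with replicate statistics across independent runs."""

    time: np.ndarray  # (n_t,) frame times (frame index if unknown)
    theta: np.ndarray  # (n_runs, n_t) signed twist per run and frame, degrees
    mean: np.ndarray  # (n_t,) mean over runs
    sd: np.ndarray  # (n_t,) sample sd over runs (ddof=1); zeros when n_runs = 1
    n_runs: int
    single_run: bool  # True when sd is identically zero because n_runs = 1

    def to_frame(self):
        """Long-form table: one row per (run, time) plus mean/sd columns."""
        import pandas as pd

        rows = {
            "time": np.tile(self.time, self.n_runs),
            "run": np.repeat(np.arange(self.n_runs), len(self.time)),
            "theta_deg": self.theta.ravel(),
        }
        df = pd.DataFrame(rows)
        stats = pd.DataFrame(
            {"time": self.time, "mean_theta_deg": self.mean, "sd_theta_deg": self.sd}
        )
        return df.merge(stats, on="time")


def canonical_monomer_ids(
    leaflet: np.ndarray, column: np.ndarray, segment: np.ndarray
) -> np.ndarray:
    """Deterministic monomer ids from (leaflet, column, segment) labels.

    Ids are assigned in lexicographic (leaflet, column, segment) order so that
    file round trips and rebuilds agree.
    """
    keys = np.stack([np.asarray(leaflet), np.asarray(column), np.asarray(segment)])
    _, inverse = np.unique(keys.T, axis=0, return_inverse=True)
    return inverse.astype(int)


def build_ribbon(
    n_width: int,
    n_length: int | None = None,
    lattice: RibbonLattice | None = None,
    pitch_nm: float | None = None,
    handedness: str = "right",
    noise_sd: float = 0.0,
    seed: int = 0,
    length_nm: float | None = None,
) -> LabeledCoordinates:
    """Build a (possibly twisted) bilayer ribbon on the default lattice.

    Parameters
    ----------
    n_width : int
        Number of chain columns across the width (≥ 2).
    n_length : int, optional
        Number of whole chain segments along the length (≥ 2).  Mutually
        exclusive with ``length_nm``.
    lattice : RibbonLattice, optional
        Packing distances; defaults to the XRD-derived constants.
    pitch_nm : float, optional
        Axial length per full 360° turn.  ``None`` builds a flat ribbon.
    handedness : {"right", "left"}
        Sense of the twist (right-hand rule about the long axis).
    noise_sd : float
        Gaussian positional noise per coordinate, nm.
    seed : int
        Seed for the noise generator.
    length_nm : float, optional
        Target contour length; residue rows are laid down to the nearest
        lattice position, so the final chain may be partial.  Use when the
        target length is not a whole number of chain periods.

    The untwisted template places hydrophobic residues on the two backbone
    planes z = ±backbone_gap/2 and each chain's polar terminus on the outer
    surface z = ±bilayer_thickness/2; the twist then rotates each
    cross-section about x by 360°·x/pitch_nm (x measured from the ribbon
    midpoint, sign set by ``handedness``).
    """
    lattice = lattice or RibbonLattice()
    if n_width < 2:
        raise DomainError("n_width must be >= 2")
    if (n_length is None) == (length_nm is None):
        raise DomainError("specify exactly one of n_length or length_nm")
    if n_length is not None:
        if n_length < 2:
            raise DomainError("n_length must be >= 2")
        n_rows = n_length * lattice.residues_per_chain
    else:
        if length_nm <= 0:
            raise DomainError("length_nm must be > 0")
        n_rows = int(round(length_nm / lattice.residue_spacing)) + 1
        if n_rows < 2 * lattice.residues_per_chain:
            raise DomainError("length_nm too short: need at least 2 chain segments")
    if pitch_nm is not None and pitch_nm == 0:
        raise DomainError("pitch_nm must be nonzero (use None for a flat ribbon)")
    if noise_sd < 0:
        raise DomainError("noise_sd must be >= 0")
    if handedness not in ("right", "left"):
        raise DomainError(f"handedness must be 'right' or 'left', got {handedness!r}")

    rows = np.arange(n_rows)
    cols = np.arange(n_width)
    leaflets = np.array([UPPER, LOWER])

    lf, cc, rr = np.meshgrid(leaflets, cols, rows, indexing="ij")
    lf, cc, rr = lf.ravel(), cc.ravel(), rr.ravel()
    seg = rr // lattice.residues_per_chain
    res = rr % lattice.residues_per_chain

    x = rr * lattice.residue_spacing
    x = x - x.max() / 2.0  # centre so the twist is phase-symmetric
    y = (cc - (n_width - 1) / 2.0) * lattice.chain_spacing
    polar = res == lattice.residues_per_chain - 1
    z_mag = np.where(polar, lattice.bilayer_thickness / 2.0, lattice.backbone_gap / 2.0)
    z = lf * z_mag

    if pitch_nm is not None:
        sign = 1.0 if handedness == "right" else -1.0
        alpha = sign * 2.0 * np.pi * x / pitch_nm
        y, z = y * np.cos(alpha) - z * np.sin(alpha), y * np.sin(alpha) + z * np.cos(alpha)

    positions = np.column_stack([x, y, z]).astype(float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        positions = positions + rng.normal(0.0, noise_sd, size=positions.shape)

    return LabeledCoordinates(
        positions=positions,
        monomer_id=canonical_monomer_ids(lf, cc, seg),
        leaflet=lf,
        column=cc,
        segment=seg,
        residue=res,
        lattice=lattice,
    )


def _edge_coms(coords: LabeledCoordinates, column_value: int) -> np.ndarray:
    """Per-segment centres of mass of the edge monomers in one column."""
    mask = coords.column == column_value
    segs = coords.segment[mask]
    pos = coords.positions[mask]
    order = np.unique(segs)
    return np.array([pos[segs == s].mean(axis=0) for s in order])


def _fit_direction(points: np.ndarray) -> np.ndarray:
    """Principal direction of a point sequence, oriented along its ordering."""
    centred = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    v = vt[0]
    if v @ (points[-1] - points[0]) < 0:
        v = -v
    return v


def twist_dihedral(coords: LabeledCoordinates, flat_tol_deg: float = FLAT_TOL_DEG) -> TwistResult:
    """Signed global twist dihedral θ of a labelled ribbon structure.

    The two ribbon edges are the extreme column indices (both leaflets).  The
    per-segment cross-edge vectors (upper-edge COM minus lower-edge COM) are
    projected onto the plane perpendicular to the ribbon axis — the principal
    direction of the edge midpoints, oriented by increasing segment index —
    their rotation angle is unwrapped and fitted linearly in axial position,
    and θ is the fitted rotation rate times the contour length (the point
    cloud's extent along the axis).  θ > 0 means right-handed.
    """
    cols = np.unique(coords.column)
    if len(cols) < 2:
        raise InsufficientDataError("need at least 2 columns to define ribbon edges")
    upper = _edge_coms(coords, int(cols.max()))
    lower = _edge_coms(coords, int(cols.min()))
    n_seg = min(len(upper), len(lower))
    if n_seg < 2:
        raise InsufficientDataError("need at least 2 monomers along each edge")
    upper, lower = upper[:n_seg], lower[:n_seg]

    if np.allclose(upper, upper[0]) and np.allclose(lower, lower[0]):
        raise DegenerateGeometryError("all edge centres of mass coincide")

    midpoints = (upper + lower) / 2.0
    span = midpoints.max(axis=0) - midpoints.min(axis=0)
    if np.allclose(span, 0.0):
        raise DegenerateGeometryError("ribbon axis is degenerate (coincident midpoints)")
    axis = _fit_direction(midpoints)

    # Right-handed frame about the axis.
    helper = np.zeros(3)
    helper[np.argmin(np.abs(axis))] = 1.0
    e1 = np.cross(axis, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)

    w = upper - lower
    if np.allclose(w, 0.0):
        raise DegenerateGeometryError("upper and lower edges coincide")
    phi = np.unwrap(np.arctan2(w @ e2, w @ e1))
    t = midpoints @ axis
    slope = np.polyfit(t, phi, 1)[0]  # rad per nm of axial distance

    proj = coords.positions @ axis
    contour_length = float(proj.max() - proj.min())
    theta_deg = float(np.degrees(slope) * contour_length)

    if theta_deg > flat_tol_deg:
        hand = "right"
    elif theta_deg < -flat_tol_deg:
        hand = "left"
    else:
        hand = "flat"
    pitch = 360.0 * contour_length / abs(theta_deg) if hand != "flat" else None

    return TwistResult(
        theta_deg=theta_deg,
        v_u=_fit_direction(upper),
        v_l=_fit_direction(lower),
        handedness=hand,
        contour_length=contour_length,
        pitch_nm=pitch,
    )


def twist_profile(
    frames: Sequence[LabeledCoordinates] | Sequence[Sequence[LabeledCoordinates]],
    n_runs: int = 1,
    times: np.ndarray | None = None,
    flat_tol_deg: float = FLAT_TOL_DEG,
) -> TrajectorySeries:
    """Twist dihedral per frame with replicate statistics across runs.

    ``frames`` is either a nested sequence (one inner sequence per run, equal
    lengths) or a flat sequence of ``n_runs`` concatenated runs of equal
    length.  The sd across runs uses the n−1 denominator and is reported as
    zero (flagged ``single_run``) when there is only one run.
    """
    frames = list(frames)
    if not frames:
        raise InsufficientDataError("need at least one frame")
    if isinstance(frames[0], LabeledCoordinates):
        if n_runs < 1 or len(frames) % n_runs != 0:
            raise DomainError(
                f"{len(frames)} frames cannot be split into {n_runs} equal runs"
            )
        n_t = len(frames) // n_runs
        runs = [frames[r * n_t : (r + 1) * n_t] for r in range(n_runs)]
    else:
        runs = [list(r) for r in frames]
        n_runs = len(runs)
        n_t = len(runs[0])
        if any(len(r) != n_t for r in runs):
            raise DomainError("all runs must have the same number of frames")
    if n_t < 1:
        raise InsufficientDataError("need at least one frame per run")

    theta = np.array(
        [[twist_dihedral(f, flat_tol_deg).theta_deg for f in run] for run in runs]
    )
    time = np.arange(n_t, dtype=float) if times is None else np.asarray(times, dtype=float)
    if time.shape != (n_t,):
        raise DomainError(f"times must have shape ({n_t},)")
    single = n_runs == 1
    sd = np.zeros(n_t) if single else theta.std(axis=0, ddof=1)
    return TrajectorySeries(
        time=time,
        theta=theta,
        mean=theta.mean(axis=0),
        sd=sd,
        n_runs=n_runs,
        single_run=single,
    )


def pitch_from_twist(
    theta_deg: float, contour_length: float, flat_tol_deg: float = FLAT_TOL_DEG
) -> float:
    """Pitch per full helical turn: 360°·L/|θ| (e.g. θ=98°, L=23.7 nm → 87 nm)."""
    if contour_length <= 0:
        raise DomainError("contour_length must be > 0")
    if abs(theta_deg) <= flat_tol_deg:
        raise FlatRibbonError(
            f"|theta| = {abs(theta_deg):.3g}° is below the flat tolerance "
            f"({flat_tol_deg}°); no finite pitch"
        )
    return 360.0 * contour_length / abs(theta_deg)
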