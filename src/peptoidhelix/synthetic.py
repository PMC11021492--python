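"""Synthetic inputs for the pipeline: relaxation trajectories, AFM-like maps.

Three generators, all deterministic given a seed:

* :func:`simulate_twist_relaxation` — the twist dihedral of an initially flat
  ribbon relaxing exponentially to a ~98° plateau, with mean-reverting
  (Ornstein–Uhlenbeck) fluctuations, over several independent replicate runs.
* :func:`render_heightmap` — the apparent-height image of a rigid twisted
  ribbon resting on a flat substrate, blurred by a Gaussian tip and perturbed
  by additive Gaussian noise.  The per-column apparent height oscillates
  between the slab thickness (face-on) and the ribbon width (edge-on), so the
  axial height profile repeats every *half* pitch (two-fold ribbon symmetry).
* :func:`generate_population` — a cohort of such maps with per-helix widths,
  heights, pitches and handedness drawn from truncated normal distributions,
  plus a ground-truth table for estimator validation.

The ``ph7`` and ``ph4`` presets encode the measured cohort statistics:
pitch 86.4 ± 6.7 nm / 110.1 ± 20.3 nm, apparent height 5.2 ± 0.4 nm /
15.6 ± 2.4 nm, width 10.7 ± 1.7 nm, and a 50:50 handedness mix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .errors import DomainError
from .geometry import TrajectorySeries

__all__ = [
    "RelaxationParams",
    "PopulationSpec",
    "HeightMap",
    "simulate_twist_relaxation",
    "render_heightmap",
    "generate_population",
    "POPULATION_PRESETS",
    "save_heightmap",
    "load_heightmap",
]


@dataclass(frozen=True)
class RelaxationParams:
    """Parameters of the synthetic twist-relaxation trajectory.

    The deterministic part is θ(t) = θ_eq·(1 − exp(−t/τ)); with the default
    τ = 5 ns the twist has reached 98.2% of its plateau by 20 ns.  The noise
    is an exact-discretisation Ornstein–Uhlenbeck process with stationary sd
    ``sigma`` and correlation time τ, so the plateau scatter is controlled.
    """

    theta_eq: float = 98.0  # plateau twist, degrees
    tau: float = 5.0  # relaxation time, ns
    sigma: float = 4.0  # stationary fluctuation sd, degrees
    t_total: float = 100.0  # ns
    dt: float = 0.1  # ns
    n_runs: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise DomainError("tau must be > 0")
        if self.dt <= 0:
            raise DomainError("dt must be > 0")
        if self.t_total < self.dt:
            raise DomainError("t_total must be >= dt")
        if self.n_runs < 1:
            raise DomainError("n_runs must be >= 1")
        if self.sigma < 0:
            raise DomainError("sigma must be >= 0")


def simulate_twist_relaxation(params: RelaxationParams) -> TrajectorySeries:
    """Synthetic twist-dihedral trajectory θ_r(t) for ``n_runs`` replicates.

    Each run r uses an independent stream spawned from ``(seed, r)``, so the
    whole ensemble is reproducible bit-for-bit from the single seed.
    """
    n_t = int(round(params.t_total / params.dt)) + 1
    time = np.arange(n_t) * params.dt
    base = params.theta_eq * (1.0 - np.exp(-time / params.tau))

    decay = np.exp(-params.dt / params.tau)
    kick = params.sigma * np.sqrt(1.0 - decay**2)
    theta = np.empty((params.n_runs, n_t))
    for r in range(params.n_runs):
        rng = np.random.default_rng([params.seed, r])
        if params.sigma == 0:
            noise = np.zeros(n_t)
        else:
            noise = np.empty(n_t)
            noise[0] = rng.normal(0.0, params.sigma)
            shocks = rng.normal(0.0, 1.0, size=n_t - 1)
            for k in range(1, n_t):
                noise[k] = noise[k - 1] * decay + kick * shocks[k - 1]
        theta[r] = base + noise

    single = params.n_runs == 1
    sd = np.zeros(n_t) if single else theta.std(axis=0, ddof=1)
    return TrajectorySeries(
        time=time,
        theta=theta,
        mean=theta.mean(axis=0),
        sd=sd,
        n_runs=params.n_runs,
        single_run=single,
    )


@dataclass
class HeightMap:
    """Raster of apparent heights (nm) with pixel size and axis orientation."""

    grid: np.ndarray  # (n_y, n_x) heights in nm, >= 0
    pixel_size: float  # nm per pixel
    axis_angle: float = 0.0  # in-plane helix-axis orientation, degrees

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise DomainError("grid must be 2-D")
        if not np.all(np.isfinite(self.grid)):
            raise DomainError("heights must be finite")
        if self.pixel_size <= 0:
            raise DomainError("pixel_size must be > 0")

    def mirrored(self) -> "HeightMap":
        """Mirror image (flips the handedness of any helix in the map)."""
        return HeightMap(self.grid[::-1].copy(), self.pixel_size, -self.axis_angle)


def _cross_section_profile(
    y: np.ndarray, width: float, thickness: float, alpha: float
) -> np.ndarray:
    """Apparent height of a width×thickness rectangle rotated by alpha.

    The rectangle (the ribbon cross-section) is rotated about its centre and
    dropped onto the substrate so its lowest corner touches z = 0; the return
    value is the upper boundary z_top(y) − z_min for each lateral position y
    (zero outside the footprint).  The upper boundary is the upper hull of the
    four rotated corners.
    """
    c, s = np.cos(alpha), np.sin(alpha)
    v = np.array([width, -width, -width, width]) / 2.0
    w = np.array([thickness, thickness, -thickness, -thickness]) / 2.0
    cy = v * c - w * s
    cz = v * s + w * c
    z_min = cz.min()

    order = np.argsort(cy)
    cy, cz = cy[order], cz[order]
    # Upper hull of 4 convex-position points: drop any interior point below
    # the chord of its neighbours.
    keep = [0]
    for k in range(1, 4):
        while len(keep) >= 2:
            i, j = keep[-2], keep[-1]
            # cross product test: is point j below segment i->k?
            if (cy[k] - cy[i]) * (cz[j] - cz[i]) - (cz[k] - cz[i]) * (cy[j] - cy[i]) <= 0:
                keep.pop()
            else:
                break
        keep.append(k)
    hy, hz = cy[keep], cz[keep]
    z_top = np.interp(y, hy, hz, left=np.nan, right=np.nan)
    h = z_top - z_min
    return np.where(np.isnan(h), 0.0, h)


def render_heightmap(
    width: float,
    thickness: float,
    pitch: float,
    handedness: str = "right",
    length: float | None = None,
    pixel_size: float = 1.0,
    tip_sigma: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    phase_deg: float = 0.0,
    margin: float | None = None,
    height_cap: float | None = None,
    axis_angle: float = 0.0,
) -> HeightMap:
    """Render the apparent-height image of one rigid twisted ribbon.

    The helix axis runs along x (the map can be tagged with a different
    in-plane ``axis_angle``; rotation is applied by the caller or the sampler
    in :func:`generate_population`).  At axial position x the cross-section is
    rotated by ``±360°·x/pitch + phase`` (sign per handedness, right-hand rule
    about the axis with z out of the substrate).  ``height_cap`` optionally
    clips apparent heights, standing in for substrate-deformation effects that
    the rigid model does not capture.
    """
    if width <= 0 or thickness <= 0 or pitch <= 0 or pixel_size <= 0:
        raise DomainError("width, thickness, pitch and pixel_size must be > 0")
    if noise_sd < 0 or tip_sigma < 0:
        raise DomainError("noise_sd and tip_sigma must be >= 0")
    if handedness not in ("right", "left"):
        raise DomainError(f"handedness must be 'right' or 'left', got {handedness!r}")
    if length is None:
        length = 3.2 * pitch
    if margin is None:
        margin = 3.0 * tip_sigma + 4.0 * pixel_size

    half_extent = np.hypot(width, thickness) / 2.0 + margin
    n_x = max(2, int(round(length / pixel_size)))
    n_y = max(2, int(round(2 * half_extent / pixel_size)))
    x = (np.arange(n_x) + 0.5) * pixel_size

    # The tip convolution acts on the continuous surface, so the footprint
    # edges must be blurred *before* the map is sampled at pixel resolution:
    # render on a 5x-supersampled y grid, blur there, then decimate to the
    # pixel centres.  (Blurring after point-sampling would quantise the edge
    # positions to the pixel grid and erase sub-pixel width information.)
    ss = 5
    fine = pixel_size / ss
    y_fine = (np.arange(n_y * ss) + 0.5) * fine - half_extent

    sign = 1.0 if handedness == "right" else -1.0
    alphas = sign * 2.0 * np.pi * x / pitch + np.radians(phase_deg)
    grid = np.empty((n_y * ss, n_x))
    for j, a in enumerate(alphas):
        grid[:, j] = _cross_section_profile(y_fine, width, thickness, a)

    if tip_sigma > 0:
        grid = ndimage.gaussian_filter(
            grid, sigma=(tip_sigma / fine, tip_sigma / pixel_size)
        )
    grid = grid[ss // 2 :: ss, :]  # sample the blurred surface at pixel centres
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        grid = grid + rng.normal(0.0, noise_sd, size=grid.shape)
    if height_cap is not None:
        grid = np.minimum(grid, height_cap)
    grid = np.clip(grid, 0.0, None)
    return HeightMap(grid=grid, pixel_size=pixel_size, axis_angle=axis_angle)


@dataclass(frozen=True)
class PopulationSpec:
    """Specification of a synthetic helix cohort (means/sds in nm)."""

    n_helices: int = 50
    width_mean: float = 10.7
    width_sd: float = 1.7
    height_mean: float = 5.2
    height_sd: float = 0.4
    pitch_mean: float = 86.4
    pitch_sd: float = 6.7
    handedness_fraction_right: float = 0.5
    pixel_size: float = 1.0
    noise_sd: float = 0.1
    tip_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_helices < 1:
            raise DomainError("n_helices must be >= 1")
        for name in ("width_mean", "height_mean", "pitch_mean", "pixel_size"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be > 0")
        for name in ("width_sd", "height_sd", "pitch_sd", "noise_sd", "tip_sigma"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")
        if not 0.0 <= self.handedness_fraction_right <= 1.0:
            raise DomainError("handedness_fraction_right must be in [0, 1]")


#: Cohort presets matching the measured population statistics at the two
#: assembly pH conditions: narrow single ribbons at pH 7 (pitch 86.4 ± 6.7 nm,
#: height 5.2 ± 0.4 nm, width 10.7 ± 1.7 nm); thicker multilayer stacks with a
#: longer pitch at pH 4 (pitch 110.1 ± 20.3 nm, height 15.6 ± 2.4 nm).  The
#: pH 4 widths were reported only qualitatively ("much larger"), so the preset
#: uses twice the pH 7 width; this also keeps width > height, without which a
#: resting rigid cross-section's two dimensions are not separately
#: identifiable from a height map (the map is invariant under swapping them
#: with a quarter-turn phase shift).
POPULATION_PRESETS: dict[str, PopulationSpec] = {
    "ph7": PopulationSpec(),
    "ph4": PopulationSpec(
        width_mean=21.4,
        width_sd=3.4,
        height_mean=15.6,
        height_sd=2.4,
        pitch_mean=110.1,
        pitch_sd=20.3,
    ),
}


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Normal(mean, sd) truncated at zero (degenerate to the mean if sd=0)."""
    if sd == 0:
        return np.full(size, mean)
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def generate_population(
    spec: PopulationSpec, with_rotation: bool = False
) -> tuple[list[HeightMap], pd.DataFrame]:
    """Draw a helix cohort and render one height map per helix.

    Per-helix widths, heights and pitches are drawn from zero-truncated
    normals with the spec's means and sds; handedness is Bernoulli in the
    right-handed fraction.  The drawn height is rendered as the slab
    thickness of the rigid ribbon (the face-on apparent height).  With
    ``with_rotation`` each map is additionally tagged and rendered at a random
    in-plane axis orientation.  Returns the maps and a ground-truth table
    (one row per helix) for estimator validation.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_helices
    widths = _truncated_normal(rng, spec.width_mean, spec.width_sd, n)
    heights = _truncated_normal(rng, spec.height_mean, spec.height_sd, n)
    pitches = _truncated_normal(rng, spec.pitch_mean, spec.pitch_sd, n)
    right = rng.random(n) < spec.handedness_fraction_right
    phases = rng.uniform(0.0, 360.0, size=n)
    angles = rng.uniform(-60.0, 60.0, size=n) if with_rotation else np.zeros(n)
    map_seeds = rng.integers(0, 2**31 - 1, size=n)

    maps = []
    for k in range(n):
        hm = render_heightmap(
            width=float(widths[k]),
            thickness=float(heights[k]),
            pitch=float(pitches[k]),
            handedness="right" if right[k] else "left",
            pixel_size=spec.pixel_size,
            tip_sigma=spec.tip_sigma,
            noise_sd=spec.noise_sd,
            seed=int(map_seeds[k]),
            phase_deg=float(phases[k]),
        )
        if with_rotation and angles[k] != 0.0:
            from skimage.transform import rotate as sk_rotate

            hm = HeightMap(
                np.clip(
                    sk_rotate(hm.grid, angles[k], resize=True, order=1, preserve_range=True),
                    0.0,
                    None,
                ),
                hm.pixel_size,
                axis_angle=float(angles[k]),
            )
        maps.append(hm)

    truth = pd.DataFrame(
        {
            "helix_id": np.arange(n),
            "width_nm": widths,
            "height_nm": heights,
            "pitch_nm": pitches,
            "handedness": np.where(right, "right", "left"),
            "phase_deg": phases,
            "axis_angle_deg": angles,
            "map_seed": map_seeds,
        }
    )
    return maps, truth


def save_heightmap(hm: HeightMap, path: str | Path, seed: int | None = None) -> None:
    """Write a height map as a plain-text matrix (nm) plus a JSON sidecar."""
    path = Path(path)
    np.savetxt(path, hm.grid, fmt="%.4f", header="apparent height (nm); rows = y, cols = x")
    meta = {"pixel_size": hm.pixel_size, "axis_angle": hm.axis_angle}
    if seed is not None:
        meta["seed"] = seed
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def load_heightmap(path: str | Path) -> HeightMap:
    """Read a height map written by :func:`save_heightmap`."""
    path = Path(path)
    grid = np.loadtxt(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {"pixel_size": 1.0}
    return HeightMap(
        grid=grid,
        pixel_size=float(meta.get("pixel_size", 1.0)),
        axis_angle=float(meta.get("axis_angle", 0.0)),
    )
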