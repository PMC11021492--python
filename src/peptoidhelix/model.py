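"""Phenomenological thermodynamic model of twisted-ribbon width selection.

A twisted bilayer ribbon of amphiphiles, N monomer columns across its width,
trades two free-energy contributions per monomer (in units of the dispersion
energy scale ε):

* an interfacial gain ``-κ (1 - 1/N)`` from burying hydrophobic faces between
  adjacent columns — edge columns keep one face exposed, hence the 1/N edge
  correction — which favours wide ribbons;
* a twist-shear penalty ``(φ²/24)(N² - 1)`` on the dispersion stacking: under a
  uniform twist the shear between neighbouring columns grows linearly with the
  distance from the centreline, and averaging the quadratic elastic cost over
  the width gives the (N² - 1) factor.  This favours narrow ribbons.

The balance is controlled by the single dimensionless parameter
κ = γ·l·δ/ε (interfacial tension γ, monomer length l, inter-column spacing δ,
dispersion energy ε).  Solution pH enters through the protonation state of the
polar head group: the protonated acid is more hydrophobic, raises γ and hence
κ, and shifts the preferred width upward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError

__all__ = [
    "ModelParams",
    "PhMap",
    "WidthDistribution",
    "ModeWidth",
    "free_energy_per_monomer",
    "width_distribution",
    "mode_width",
    "kappa_from_ph",
]

#: Default twist shear angle per inter-column spacing (radians).  Calibrated so
#: that κ = 1 puts the continuous optimum near 23 columns, i.e. a physical
#: width of 23 × 0.46 nm ≈ 10.6 nm, commensurate with the measured 10.7 nm.
DEFAULT_PHI = 0.0314

#: Default inverse-temperature weight (cooperative segment size, monomers).
DEFAULT_BETA_EPS = 50.0

#: Default inter-column spacing δ in nm (the 4.6 Å chain-packing distance).
DEFAULT_DELTA = 0.46


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the width-selection free energy.

    Attributes
    ----------
    kappa : float
        Dimensionless interfacial/dispersion balance κ = γlδ/ε, ≥ 0.
    phi : float
        Twist shear angle per inter-column spacing, radians, > 0.
    beta_eps : float
        Depth of the dispersion energy in thermal units (β·ε), > 0.
    n_max : int
        Largest width N evaluated, ≥ 2.
    delta : float
        Inter-column spacing in nm converting N to physical width D = N·δ.
    """

    kappa: float
    phi: float = DEFAULT_PHI
    beta_eps: float = DEFAULT_BETA_EPS
    n_max: int = 60
    delta: float = DEFAULT_DELTA

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise DomainError(f"kappa must be >= 0, got {self.kappa}")
        if self.phi <= 0:
            raise DomainError(f"phi must be > 0, got {self.phi}")
        if self.beta_eps <= 0:
            raise DomainError(f"beta_eps must be > 0, got {self.beta_eps}")
        if int(self.n_max) != self.n_max or self.n_max < 2:
            raise DomainError(f"n_max must be an integer >= 2, got {self.n_max}")
        if self.delta <= 0:
            raise DomainError(f"delta must be > 0, got {self.delta}")


@dataclass(frozen=True)
class PhMap:
    """Mapping from solution pH to the balance parameter κ.

    The polar head group (a carboxylic acid here) is protonated with fraction
    f = 1 / (1 + 10^(pH − pKa)); the effective interfacial tension interpolates
    between the fully protonated (more hydrophobic) and fully deprotonated
    values, and κ = γ·l·δ/ε.

    The default apparent pKa is 5.5 rather than the aqueous ~3.5: inside the
    supramolecular stack the dissociation equilibrium is substantially shifted
    (water exclusion, intramolecular electrostatics), which is how partial
    protonation persists up to neutral pH.
    """

    pka_app: float = 5.5
    gamma_ha: float = 15.0  # interfacial tension, protonated form (ε / nm²)
    gamma_a: float = 0.15  # interfacial tension, deprotonated form (ε / nm²)
    l: float = 1.45  # characteristic monomer length, nm (5 × 0.29 nm)
    delta: float = DEFAULT_DELTA  # inter-layer spacing, nm
    epsilon: float = 1.0  # dispersion energy scale, thermal units

    def __post_init__(self) -> None:
        if not self.gamma_ha > self.gamma_a >= 0:
            raise DomainError(
                "require gamma_ha > gamma_a >= 0 (protonated form is the more "
                f"hydrophobic), got gamma_ha={self.gamma_ha}, gamma_a={self.gamma_a}"
            )
        for name in ("l", "delta", "epsilon"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be > 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class WidthDistribution:
    """Relative width probabilities P̃(N), scaled to unit maximum."""

    n_values: np.ndarray
    p_scaled: np.ndarray
    mode_n: int
    mode_d: float  # nm
    params: ModelParams = field(repr=False)


@dataclass(frozen=True)
class ModeWidth:
    """Most probable width: integer mode, physical width, continuous optimum."""

    mode_n: int
    mode_d: float  # nm
    n_star_continuous: float  # NaN when kappa = 0 (no interior optimum)


def free_energy_per_monomer(n, params: ModelParams):
    """Free energy per monomer e(N) of a ribbon N columns wide, in units of ε.

    e(N) = −κ(1 − 1/N) + (φ²/24)(N² − 1).  e(1) = 0 by construction (a single
    column buries no interface and carries no shear), and e is strictly convex
    for φ > 0, so the width distribution is unimodal.

    Accepts scalar or array ``n`` (need not be integer; the continuous
    extension is what the closed-form optimum differentiates).
    """
    n_arr = np.asarray(n, dtype=float)
    if np.any(n_arr < 1):
        raise DomainError("width n must be >= 1")
    e = -params.kappa * (1.0 - 1.0 / n_arr) + (params.phi**2 / 24.0) * (n_arr**2 - 1.0)
    return e if isinstance(n, np.ndarray) else float(e)


def width_distribution(params: ModelParams) -> WidthDistribution:
    """Relative probability of each width N = 1..n_max, scaled to unit maximum.

    P̃(N) ∝ exp(−βε·e(N)); the curve is shifted by its minimum energy before
    exponentiating so the maximum is exactly 1.0 in floating point.  Ties in
    the argmax resolve to the smallest N.
    """
    n_values = np.arange(1, params.n_max + 1)
    e = free_energy_per_monomer(n_values.astype(float), params)
    p = np.exp(-params.beta_eps * (e - e.min()))
    p_scaled = p / p.max()
    mode_n = int(n_values[np.argmax(p_scaled)])  # np.argmax takes first of ties
    return WidthDistribution(
        n_values=n_values,
        p_scaled=p_scaled,
        mode_n=mode_n,
        mode_d=mode_n * params.delta,
        params=params,
    )


def mode_width(params: ModelParams) -> ModeWidth:
    """Most probable ribbon width and its closed-form continuous companion.

    Setting e'(N) = 0 gives N* = (12κ/φ²)^(1/3); the integer mode is whichever
    of floor/ceil(N*) has the lower free energy (clipped to [1, n_max]).  For
    κ = 0 there is no interior optimum: the mode is N = 1 and the continuous
    optimum is reported as NaN.
    """
    if params.kappa == 0:
        return ModeWidth(mode_n=1, mode_d=params.delta, n_star_continuous=math.nan)
    n_star = (12.0 * params.kappa / params.phi**2) ** (1.0 / 3.0)
    lo = max(1, min(params.n_max, math.floor(n_star)))
    hi = max(1, min(params.n_max, math.ceil(n_star)))
    candidates = sorted({lo, hi})
    energies = [free_energy_per_monomer(c, params) for c in candidates]
    mode_n = candidates[int(np.argmin(energies))]
    return ModeWidth(mode_n=mode_n, mode_d=mode_n * params.delta, n_star_continuous=n_star)


def protonated_fraction(ph: float, pka_app: float) -> float:
    """Henderson–Hasselbalch fraction of the acid in the protonated form."""
    return 1.0 / (1.0 + 10.0 ** (ph - pka_app))


def kappa_from_ph(ph, ph_map: PhMap | None = None):
    """Map solution pH to the balance parameter κ.

    κ(pH) = γ(pH)·l·δ/ε with γ interpolated between the protonated and
    deprotonated interfacial tensions by the Henderson–Hasselbalch fraction.
    Monotonically non-increasing in pH: low pH (protonated, hydrophobic) gives
    large κ and hence wide ribbons.
    """
    if ph_map is None:
        ph_map = PhMap()
    ph_arr = np.asarray(ph, dtype=float)
    f = 1.0 / (1.0 + 10.0 ** (ph_arr - ph_map.pka_app))
    gamma = f * ph_map.gamma_ha + (1.0 - f) * ph_map.gamma_a
    kappa = gamma * ph_map.l * ph_map.delta / ph_map.epsilon
    return kappa if isinstance(ph, np.ndarray) else float(kappa)
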