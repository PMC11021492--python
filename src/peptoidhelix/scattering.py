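"""Lamellar d-spacing bookkeeping for ribbon XRD peaks.

Converts scattering vector q (Å⁻¹) to real-space spacing d = 2π/q (Å) and
assigns observed peaks to the four packing distances of the bilayer ribbon
lattice: the bilayer thickness (2.46 nm), the inter-backbone distance inside
the bilayer (1.36 nm), the inter-chain packing distance (4.6 Å) and the
residue repeat along the backbone (2.9 Å).  First-order features only; no
harmonic indexing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DomainError
from .geometry import RibbonLattice

__all__ = ["PeakAssignment", "d_from_q", "q_from_d", "reference_spacings", "assign_peaks"]

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class PeakAssignment:
    """One scattering peak: q (Å⁻¹), spacing d (Å), lattice label, rel. error."""

    q: float
    d_angstrom: float
    label: str
    relative_error: float

    @property
    def d_nm(self) -> float:
        return self.d_angstrom / 10.0


def d_from_q(q):
    """Real-space spacing d = 2π/q; q in Å⁻¹ gives d in Å."""
    q_arr = np.asarray(q, dtype=float)
    if np.any(q_arr <= 0):
        raise DomainError("q must be > 0")
    d = 2.0 * np.pi / q_arr
    return d if isinstance(q, np.ndarray) else float(d)


def q_from_d(d):
    """Scattering vector q = 2π/d; exact inverse of :func:`d_from_q`."""
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr <= 0):
        raise DomainError("d must be > 0")
    q = 2.0 * np.pi / d_arr
    return q if isinstance(d, np.ndarray) else float(q)


def reference_spacings(lattice: RibbonLattice | None = None) -> dict[str, float]:
    """Reference lattice spacings in Å, keyed by feature label."""
    if lattice is None:
        lattice = RibbonLattice()
    return {
        "bilayer_thickness": lattice.bilayer_thickness * 10.0,
        "inter_backbone": lattice.backbone_gap * 10.0,
        "inter_chain": lattice.chain_spacing * 10.0,
        "residue_repeat": lattice.residue_spacing * 10.0,
    }


def assign_peaks(
    q_list: Sequence[float],
    lattice: RibbonLattice | None = None,
    rel_tol: float = 0.05,
) -> list[PeakAssignment]:
    """Assign each peak to the nearest reference spacing within ``rel_tol``.

    Assignment is one-to-many (two peaks may share a label; harmonics are not
    modelled) and independent of input order.  A peak whose nearest reference
    lies further than ``rel_tol`` in relative spacing is labelled
    ``"unassigned"`` but still reports its distance to that nearest reference,
    so tightening the tolerance can only ever unassign peaks.
    """
    q_arr = np.asarray(list(q_list), dtype=float)
    if q_arr.size == 0:
        raise DomainError("q_list must contain at least one peak")
    if np.any(q_arr <= 0):
        raise DomainError("all q must be > 0")
    if rel_tol < 0:
        raise DomainError("rel_tol must be >= 0")

    refs = reference_spacings(lattice)
    labels = list(refs)
    ref_d = np.array([refs[k] for k in labels])

    out = []
    for q in q_arr:
        d = d_from_q(float(q))
        rel_err = np.abs(d - ref_d) / ref_d
        j = int(np.argmin(rel_err))
        err = float(rel_err[j])
        label = labels[j] if err <= rel_tol else UNASSIGNED
        out.append(PeakAssignment(q=float(q), d_angstrom=d, label=label, relative_error=err))
    return out
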