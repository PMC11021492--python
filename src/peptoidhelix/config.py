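"""Pipeline configuration: one seed, one file, every stage parameter.

The configuration is a flat dataclass with nested override mappings for the
physical parameter groups (pH map, lattice, relaxation, population presets).
It round-trips through YAML unchanged, rejects unknown keys with a
:class:`~peptoidhelix.errors.ConfigError` listing every offending key, and is
the single source of randomness for :func:`peptoidhelix.pipeline.run_pipeline`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .errors import ConfigError
from .model import DEFAULT_BETA_EPS, DEFAULT_DELTA, DEFAULT_PHI

__all__ = ["PipelineConfig", "load_config", "save_config"]


def _default_populations() -> dict[str, dict[str, Any]]:
    return {"ph7": {}, "ph4": {}}


def _default_peaks() -> list[float]:
    # q = 2π/d for the four reference spacings (24.6, 13.6, 4.6, 2.9 Å)
    return [0.2554, 0.4620, 1.3659, 2.1666]


@dataclass
class PipelineConfig:
    """Every knob of the end-to-end pipeline; see field comments for units."""

    seed: int = 0
    out_dir: str = "artifacts"
    verbosity: int = 1

    # width-model stage
    kappas: list[float] = field(default_factory=lambda: [0.1, 1.0, 10.0])
    phi: float = DEFAULT_PHI  # rad per inter-column spacing
    beta_eps: float = DEFAULT_BETA_EPS
    n_max: int = 60
    delta: float = DEFAULT_DELTA  # nm
    ph_values: list[float] = field(default_factory=lambda: [float(x) / 2 for x in range(29)])
    ph_map: dict[str, float] = field(default_factory=dict)  # PhMap overrides

    # geometry stage
    lattice: dict[str, float] = field(default_factory=dict)  # RibbonLattice overrides
    ribbon_n_width: int = 23
    ribbon_length_nm: float = 23.7
    ribbon_pitch_nm: float = 87.0
    ribbon_handedness: str = "right"
    ribbon_noise_sd: float = 0.0  # nm

    # synthetic stages
    relaxation: dict[str, float] = field(default_factory=dict)  # RelaxationParams overrides
    populations: dict[str, dict[str, Any]] = field(default_factory=_default_populations)

    # scattering stage
    peaks_q: list[float] = field(default_factory=_default_peaks)  # Å⁻¹
    peak_rel_tol: float = 0.05

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        problems: dict[str, str] = {}
        known = {f.name: f for f in dataclasses.fields(cls)}
        for key in data:
            if key not in known:
                problems[key] = "unknown key"
        cfg_kwargs = {k: v for k, v in data.items() if k in known}
        if problems:
            raise ConfigError(problems)
        cfg = cls(**cfg_kwargs)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        """Raise :class:`ConfigError` listing every invalid field."""
        problems: dict[str, str] = {}
        if int(self.seed) != self.seed:
            problems["seed"] = "must be an integer"
        if not self.kappas:
            problems["kappas"] = "must list at least one kappa"
        elif any(k < 0 for k in self.kappas):
            problems["kappas"] = "kappa values must be >= 0"
        if self.phi <= 0:
            problems["phi"] = "must be > 0"
        if self.beta_eps <= 0:
            problems["beta_eps"] = "must be > 0"
        if self.n_max < 2:
            problems["n_max"] = "must be >= 2"
        if self.delta <= 0:
            problems["delta"] = "must be > 0"
        if self.ribbon_n_width < 2:
            problems["ribbon_n_width"] = "must be >= 2"
        if self.ribbon_length_nm <= 0:
            problems["ribbon_length_nm"] = "must be > 0"
        if self.ribbon_pitch_nm == 0:
            problems["ribbon_pitch_nm"] = "must be nonzero"
        if self.ribbon_handedness not in ("right", "left"):
            problems["ribbon_handedness"] = "must be 'right' or 'left'"
        if self.ribbon_noise_sd < 0:
            problems["ribbon_noise_sd"] = "must be >= 0"
        if not self.peaks_q:
            problems["peaks_q"] = "must list at least one q value"
        elif any(q <= 0 for q in self.peaks_q):
            problems["peaks_q"] = "q values must be > 0"
        if self.peak_rel_tol < 0:
            problems["peak_rel_tol"] = "must be >= 0"
        for name in self.populations:
            if name not in ("ph7", "ph4"):
                problems[f"populations.{name}"] = "unknown preset (use ph7/ph4)"
        if problems:
            raise ConfigError(problems)


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML (or JSON — a YAML subset) configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError({"<root>": "configuration must be a mapping"})
    return PipelineConfig.from_dict(data)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    """Write the configuration as YAML; ``load_config`` restores it exactly."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
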