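"""End-to-end pipeline: model curves → ribbons → trajectories → populations
→ measurements → peak assignments, with a deterministic manifest.

Every stage derives its seed from the single configuration seed, writes
plain-text artifacts (CSV, XYZ, text matrices, JSON) under the output
directory, and registers each file in ``manifest.json`` with its SHA-256 hash
and generating parameters, so two runs of the same configuration produce
byte-identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import coordio, measure, scattering
from .config import PipelineConfig
from .geometry import RibbonLattice, build_ribbon, twist_dihedral
from .model import ModelParams, PhMap, kappa_from_ph, width_distribution
from .synthetic import (
    POPULATION_PRESETS,
    RelaxationParams,
    generate_population,
    render_heightmap,
    save_heightmap,
    simulate_twist_relaxation,
)

__all__ = ["run_pipeline", "make_fixtures"]

logger = logging.getLogger("peptoidhelix")


def _stage_seed(seed: int, stage_index: int) -> int:
    """Deterministic per-stage seed derived from the single pipeline seed."""
    return int((int(seed) * 1000003 + 7919 * stage_index) % (2**31 - 1))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> Path:
    """Run every stage and return the artifact directory.

    Artifact classes: model curves, κ(pH) table, a built twisted ribbon with
    its twist measurement, a synthetic relaxation trajectory, height-map
    populations with ground truth, per-helix measurements with population
    summaries, and scattering peak assignments — plus ``manifest.json``.
    """
    config.validate()
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": int(config.seed), "stages": {}}

    def register(stage: str, path: Path, **params) -> None:
        entry = manifest["stages"].setdefault(stage, {"params": params, "outputs": {}})
        entry["outputs"][path.name] = _sha256(path)
        if config.verbosity:
            logger.info("%s: wrote %s (%s)", stage, path.name, entry["outputs"][path.name][:12])

    lattice = RibbonLattice(**config.lattice)

    # 1. width-model probability curves, one block per kappa
    rows = []
    for kappa in config.kappas:
        params = ModelParams(
            kappa=kappa, phi=config.phi, beta_eps=config.beta_eps,
            n_max=config.n_max, delta=config.delta,
        )
        dist = width_distribution(params)
        rows.append(pd.DataFrame({
            "kappa": kappa,
            "N": dist.n_values,
            "D_nm": dist.n_values * config.delta,
            "P_scaled": dist.p_scaled,
        }))
    curves_path = out / "model_curves.csv"
    pd.concat(rows, ignore_index=True).to_csv(curves_path, index=False)
    register("model_curves", curves_path, kappas=list(config.kappas), phi=config.phi)

    # 2. pH → kappa mapping
    ph_map = PhMap(**config.ph_map)
    kappa_path = out / "kappa_vs_ph.csv"
    pd.DataFrame({
        "ph": config.ph_values,
        "kappa": [kappa_from_ph(p, ph_map) for p in config.ph_values],
    }).to_csv(kappa_path, index=False)
    register("kappa_vs_ph", kappa_path, **dataclasses.asdict(ph_map))

    # 3. built ribbon and its twist dihedral
    ribbon = build_ribbon(
        n_width=config.ribbon_n_width,
        length_nm=config.ribbon_length_nm,
        lattice=lattice,
        pitch_nm=config.ribbon_pitch_nm,
        handedness=config.ribbon_handedness,
        noise_sd=config.ribbon_noise_sd,
        seed=_stage_seed(config.seed, 3),
    )
    ribbon_path = out / "ribbon.xyz"
    coordio.write_xyz(ribbon, ribbon_path)
    twist = twist_dihedral(ribbon)
    twist_path = out / "twist.csv"
    pd.DataFrame([{
        "theta_deg": twist.theta_deg,
        "handedness": twist.handedness,
        "contour_length_nm": twist.contour_length,
        "pitch_nm": twist.pitch_nm,
    }]).to_csv(twist_path, index=False)
    register("ribbon", ribbon_path, n_width=config.ribbon_n_width,
             length_nm=config.ribbon_length_nm, pitch_nm=config.ribbon_pitch_nm,
             handedness=config.ribbon_handedness)
    register("ribbon", twist_path)

    # 4. synthetic twist relaxation
    relax = RelaxationParams(**{"seed": _stage_seed(config.seed, 4), **config.relaxation})
    series = simulate_twist_relaxation(relax)
    relax_path = out / "relaxation.csv"
    series.to_frame().to_csv(relax_path, index=False)
    register("relaxation", relax_path, **dataclasses.asdict(relax))

    # 5/6. populations, measurements, summaries
    for i, (name, overrides) in enumerate(sorted(config.populations.items())):
        spec = replace(
            POPULATION_PRESETS[name],
            **{"seed": _stage_seed(config.seed, 5 + i), **overrides},
        )
        maps, truth = generate_population(spec)
        pop_dir = out / f"population_{name}"
        pop_dir.mkdir(exist_ok=True)
        truth_path = pop_dir / "truth.csv"
        truth.to_csv(truth_path, index=False)
        register(f"population_{name}", truth_path, **dataclasses.asdict(spec))
        for k, hm in enumerate(maps):
            map_path = pop_dir / f"map_{k:03d}.txt"
            save_heightmap(hm, map_path, seed=int(truth.map_seed[k]))
            register(f"population_{name}", map_path)
            register(f"population_{name}", map_path.with_suffix(".txt.json"))

        measurements = [measure.measure_heightmap(hm) for hm in maps]
        meas_path = out / f"measurements_{name}.csv"
        measure.measurements_to_frame(measurements).to_csv(meas_path, index=False)
        summary = measure.summarize_population(measurements)
        summary_path = out / f"summary_{name}.json"
        summary_path.write_text(json.dumps(
            {**dataclasses.asdict(summary), "formatted": summary.formatted()}, indent=1,
        ))
        register(f"measurements_{name}", meas_path)
        register(f"measurements_{name}", summary_path)

    # 7. scattering peak assignment
    assignments = scattering.assign_peaks(config.peaks_q, lattice, config.peak_rel_tol)
    peaks_path = out / "peaks_assigned.csv"
    pd.DataFrame([{
        "q_invA": a.q, "d_A": a.d_angstrom, "label": a.label,
        "relative_error": a.relative_error,
    } for a in assignments]).to_csv(peaks_path, index=False)
    register("peaks", peaks_path, rel_tol=config.peak_rel_tol)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out


def make_fixtures(out_dir: str | Path, seed: int = 0) -> Path:
    """Write the small reference fixture set used by tests and examples.

    Contents: one ideal twisted-ribbon XYZ whose twist dihedral is +98°
    (pitch 87 nm over a 23.7 nm contour), one 4-run relaxation CSV, one
    reference height map per handedness (noise-free), and one scattering peak
    CSV whose four q values match the four lattice spacings exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    ribbon = build_ribbon(n_width=23, length_nm=23.7, pitch_nm=87.0, handedness="right")
    coordio.write_xyz(ribbon, out / "ideal_ribbon.xyz")

    series = simulate_twist_relaxation(
        RelaxationParams(t_total=50.0, dt=0.5, seed=_stage_seed(seed, 1))
    )
    series.to_frame().to_csv(out / "relaxation.csv", index=False)

    for hand in ("right", "left"):
        hm = render_heightmap(
            width=10.7, thickness=5.2, pitch=86.4, handedness=hand,
            noise_sd=0.0, seed=_stage_seed(seed, 2),
        )
        save_heightmap(hm, out / f"reference_{hand}.txt", seed=seed)

    refs = scattering.reference_spacings()
    pd.DataFrame({"q_invA": [2.0 * np.pi / d for d in refs.values()]}).to_csv(
        out / "peaks.csv", index=False
    )
    return out
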