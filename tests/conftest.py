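import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def ideal_ribbon():
    """Noise-free right-handed ribbon: pitch 87 nm over a 23.7 nm contour."""
    from peptoidhelix.geometry import build_ribbon

    return build_ribbon(n_width=23, length_nm=23.7, pitch_nm=87.0, handedness="right")


@pytest.fixture(scope="session")
def reference_map():
    """Noise-free right-handed height map at the measured helix geometry."""
    from peptoidhelix.synthetic import render_heightmap

    return render_heightmap(
        width=10.7, thickness=5.2, pitch=86.4, handedness="right", noise_sd=0.0
    )


def twisted_plane(pitch_nm: float, length_nm: float, half_width_nm: float, n_seg: int = 60,
                  handedness: str = "right"):
    """Analytically parameterised twisted plane (two columns, no lattice).

    The two edges trace exact helices y = ±c·cos(kx), z = ±c·sin(kx); the
    closed-form end-to-end rotation is 360°·L/P.
    """
    from peptoidhelix.geometry import LabeledCoordinates, canonical_monomer_ids

    sign = 1.0 if handedness == "right" else -1.0
    x = np.linspace(-length_nm / 2, length_nm / 2, n_seg)
    k = sign * 2 * np.pi / pitch_nm
    upper = np.c_[x, half_width_nm * np.cos(k * x), half_width_nm * np.sin(k * x)]
    lower = np.c_[x, -half_width_nm * np.cos(k * x), -half_width_nm * np.sin(k * x)]
    positions = np.vstack([upper, lower])
    column = np.r_[np.ones(n_seg, dtype=int), np.zeros(n_seg, dtype=int)]
    segment = np.r_[np.arange(n_seg), np.arange(n_seg)]
    leaflet = np.r_[np.ones(n_seg, dtype=int), -np.ones(n_seg, dtype=int)]
    residue = np.zeros(2 * n_seg, dtype=int)
    return LabeledCoordinates(
        positions=positions,
        monomer_id=canonical_monomer_ids(leaflet, column, segment),
        leaflet=leaflet,
        column=column,
        segment=segment,
        residue=residue,
    )
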