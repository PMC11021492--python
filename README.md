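# peptoidhelix

Thermodynamic width selection, twist order parameter and morphometrics for
amphiphilic peptoid nanohelices.

Short diblock-like peptoids — four hydrophobic N-phenylmethyl glycine (Npm)
units with one pH-titratable diglycolic-acid head group — self-assemble into
twisted bilayer ribbons: nanohelices ~10.7 nm wide and 2.46 nm thick with a
helical pitch near 87 nm, formed in both hands with equal probability. This
package is for researchers modelling that system (and twisted amphiphile
ribbons generally): it implements the phenomenological model that explains
why ribbon width grows as solution pH drops, the geometric order parameter
that quantifies ribbon twist in simulation output, and the estimators that
turn AFM-like height images into pitch/width/height/handedness statistics —
together with a seeded synthetic-data generator so every estimator is
validated by parameter recovery.

## The model

A ribbon N monomer columns wide (column spacing δ) has free energy per
monomer, in units of the dispersion energy ε:

    e(N) = −κ (1 − 1/N) + (φ²/24)(N² − 1),        κ = γ l δ / ε

The interfacial term (tension γ, monomer length l) favours wide ribbons; the
twist-shear penalty on dispersion stacking (shear angle φ per column)
favours narrow ones. Boltzmann weights P̃(N) ∝ exp(−βε·e(N)), scaled to unit
maximum, give the relative width probabilities; the optimum is
N* = (12κ/φ²)^(1/3). Solution pH controls κ through the head-group
protonation equilibrium: low pH → protonated, more hydrophobic, higher γ and
κ → wider ribbons.

The twist of an explicit ribbon structure is measured by the twist dihedral
θ, defined through the monomers on the two long edges via
v_u·v_l = |v_u||v_l| cos θ: the cross-edge vector is tracked along the
contour and θ is its total rotation about the ribbon axis (positive =
right-handed). Pitch per full turn is 360°·L/|θ|. Diffraction peaks convert
as d = 2π/q and are assigned to the bilayer lattice spacings (2.46 nm /
1.36 nm / 4.6 Å / 2.9 Å).

## Worked example

```python
from peptoidhelix import (ModelParams, mode_width,
                          build_ribbon, twist_dihedral, d_from_q)

for kappa in (0.1, 1.0, 10.0):
    m = mode_width(ModelParams(kappa=kappa))
    print(f"kappa={kappa:5}: mode_n={m.mode_n:2d}  mode_d={m.mode_d:.2f} nm")

ribbon = build_ribbon(n_width=23, length_nm=23.7, pitch_nm=87.0, handedness="right")
r = twist_dihedral(ribbon)
print(f"theta={r.theta_deg:.2f} deg  handedness={r.handedness}  pitch={r.pitch_nm:.1f} nm")
print(f"d(q=1.36/A) = {d_from_q(1.36):.2f} A")
```

prints

```
kappa=  0.1: mode_n=11  mode_d=5.06 nm
kappa=  1.0: mode_n=23  mode_d=10.58 nm
kappa= 10.0: mode_n=50  mode_d=23.00 nm
theta=98.40 deg  handedness=right  pitch=87.0 nm
d(q=1.36/A) = 4.62 A
```

Raising κ from 0.1 to 10 moves the most probable width from ~5 nm to
~23 nm — the pH→width trend; at κ = 1 the preferred width (10.6 nm) matches
the measured 10.7 ± 1.7 nm. The ribbon built with one turn per 87 nm over a
23.7 nm contour measures a 98° twist dihedral, i.e. the order parameter
recovers the built twist exactly and the 98°/87 nm pair is self-consistent.
The q = 1.36 Å⁻¹ diffraction peak is the 4.6 Å chain-packing distance.

The same pipeline runs from the shell — generate a synthetic cohort at the
pH 7 statistics and measure it back:

```sh
peptoidhelix simulate population --preset ph7 --n 50 --seed 7 --out-dir pop/
peptoidhelix measure --in pop/ --truth pop/truth.csv --out summary.csv
```

```
pitch: 87.7 ± 6.7 nm (n = 50)
width: 10.6 ± 1.8 nm (n = 50)
height: 5.2 ± 0.4 nm (n = 50)
handedness: right fraction = 0.48 (n = 50)
```

i.e. the estimators recover the generated cohort (pitch 86.4 ± 6.7 nm,
width 10.7 ± 1.7 nm, height 5.2 ± 0.4 nm, racemic) within sampling error.
`peptoidhelix run` executes every stage (model curves, κ(pH), ribbon +
twist, relaxation trajectory, both population presets, measurements,
peak assignment) into an artifact directory with a deterministic
SHA-256 manifest; `peptoidhelix make-fixtures` writes the small reference
set used by the tests.

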