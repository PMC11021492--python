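# Methods

`peptoidhelix` models and measures the self-assembly of short amphiphilic
peptoids (four hydrophobic N-phenylmethyl glycine units capped by one
pH-titratable diglycolic-acid head group) into twisted bilayer ribbons —
nanohelices roughly 10 nm wide, a few nm thick and microns long, with a
helical pitch near 90 nm and no preferred handedness. The package has four
scientific layers: a thermodynamic width-selection model, an explicit ribbon
geometry with a twist order parameter, a synthetic-data generator that
emulates the observable record (twist-relaxation trajectories and AFM-like
height images), and morphometric estimators validated by parameter recovery
against that generator.

## 1. Width-selection thermodynamics

A ribbon cross-section contains N peptoid columns spaced δ apart. The free
energy per monomer, in units of the inter-column dispersion energy ε, is

    e(N) = −κ (1 − 1/N) + (φ²/24)(N² − 1),

with κ = γ l δ / ε the dimensionless ratio of interfacial to dispersion
energies (γ interfacial tension, l monomer length). The first term is the
hydrophobic gain of burying column faces — edge columns keep one face
exposed, giving the 1/N edge correction that favours wide ribbons. The
second is the elastic cost of shearing the dispersion stacking under a
uniform twist: the shear between neighbours grows linearly with distance
from the centreline, and the mean quadratic cost over the width gives
(N² − 1). e(1) = 0 identically and e is strictly convex for φ > 0, so the
relative-probability curves P̃(N) ∝ exp(−βε·e(N)) (rescaled to unit maximum)
are unimodal with continuous optimum N* = (12κ/φ²)^(1/3).

Parameter defaults and rationale:

| parameter | default | meaning / why |
|---|---|---|
| φ | 0.0314 rad | twist shear per column spacing; calibrated so κ = 1 puts N* ≈ 23, i.e. 23 × 0.46 nm ≈ 10.6 nm, matching the measured 10.7 nm ribbon width |
| βε | 50 | cooperative segment size in monomers; a presentation parameter — only the unit-maximum scaling and the mode ordering are scientifically meaningful |
| δ | 0.46 nm | inter-column (chain-packing) spacing from diffraction |
| n_max | 60 | largest width evaluated |

Physical width is reported as D = N·δ (the across-width column count times
the chain-packing spacing); ties in the discrete argmax resolve to the
smallest N, and the distribution is evaluated on integers only.

The pH dependence enters through the head-group protonation equilibrium
(Henderson–Hasselbalch): f = 1/(1 + 10^(pH − pKa_app)), γ(pH) = f·γ_HA +
(1 − f)·γ_A, κ = γ l δ/ε. The apparent pKa defaults to 5.5 rather than the
aqueous ≈3.5 because the dissociation equilibrium inside a densely packed,
water-excluding assembly is shifted upward — this is how partial protonation
(and hence ribbon formation) persists at neutral pH. The default tension
endpoints give κ ≈ 10 fully protonated and κ ≈ 0.1 fully deprotonated,
spanning the regime where the mode moves from ~5 to ~23 nm; all values are
configuration-overridable. Width selection here is achiral: no term in e(N)
distinguishes the two hands, consistent with the observed racemic mixtures.
κ, γ, φ are never fitted to images; the model is forward-only.

## 2. Ribbon geometry and the twist order parameter

The coordinate builder places one pseudo-point per residue on a rectangular
bilayer lattice fixed by the diffraction spacings: 0.29 nm residue repeat
along the chain axis, 0.46 nm between parallel chains across the width,
backbone planes at ±0.68 nm (1.36 nm apart), polar termini at ±1.23 nm
(2.46 nm outer thickness). Chains run along the ribbon long axis; N columns
across the width therefore means a physical width of N × 0.46 nm. A uniform
twist rotates each cross-section about the long axis by 360°·x/pitch, with x
measured from the ribbon midpoint and the sign set by the requested
handedness (right-hand rule). When a target contour length is not a whole
number of 1.45 nm chain periods, `length_nm` lays residue rows to the
nearest lattice position and the final chain may be partial.

**Twist dihedral θ.** The monomers in the two extreme columns define the
ribbon edges. For each chain segment the vector from the lower-edge to the
upper-edge centre of mass is projected onto the plane perpendicular to the
ribbon axis (the principal direction of the edge midpoints, oriented by
increasing segment index); the rotation angle of that cross-edge vector is
unwrapped along the axis, fitted linearly in axial position, and θ is the
fitted rotation rate times the contour length. For an ideal uniformly
twisted ribbon this equals 360°·L/pitch exactly, for every ribbon width.

That width-independence is why the estimator is *not* the naive angle
between the two best-fit 3-D edge lines: the fitted edge lines of a twisted
ribbon of half-width c with twist rate k are skew lines whose mutual angle
is approximately 2·atan(c·k·C/S) — strongly width-dependent (≈37° for a
10 nm-wide ribbon twisted 98° end-to-end) — so that angle is not an order
parameter for the twist. The relation v_u·v_l = |v_u||v_l|·cos θ holds for
the projected cross-edge vectors at the two ends of the ribbon, which is
what the unwrapped-phase fit measures robustly. The sign convention
(right-handed = positive, from the rotation sense of the cross-edge vector
about the oriented axis) is mirror-antisymmetric by construction; a simpler
triple product of the two edge-line directions with the axis is identically
zero by the ribbon's two-fold symmetry and cannot carry the sign.

θ is reported cumulatively (not wrapped): the phase is unwrapped
segment-to-segment, which is unambiguous while the twist between adjacent
segments stays below half a turn — far beyond any geometry built here.
Pitch per full turn is 360°·L/|θ|; below a 1° flat tolerance the structure
is classified flat and has no finite pitch. Trajectory analysis reports
per-frame θ with mean and n−1 standard deviation across replicate runs
(zero, flagged, for a single run).

## 3. Synthetic data

**Twist relaxation.** θ_r(t) = θ_eq(1 − e^(−t/τ)) plus exact-discretisation
Ornstein–Uhlenbeck noise (stationary sd σ, correlation time τ), for n_runs
independent replicates seeded from (seed, run). Defaults θ_eq = 98°,
τ = 5 ns (so the twist is at 98.2% of plateau by 20 ns), σ = 4°,
t_total = 100 ns, dt = 0.1 ns, 4 runs. Mean-reverting noise keeps the
plateau scatter controlled, so the time constant is recoverable by an
exponential fit and the final-window mean has a computable standard error
(for an OU average over a window T ≫ τ, var ≈ 2σ²τ/T per run).

**Height maps.** A rigid W × T rectangular cross-section is rotated by
360°·x/pitch and rested on the substrate per cross-section (lowest corner at
z = 0); the apparent height is the upper hull of the rotated rectangle, so
the axial maximum-height profile oscillates between T (face-on) and W
(edge-on) with period pitch/2 — the two-fold symmetry that makes the
apparent-height period *half* the pitch. The surface is rendered on a
5×-supersampled lateral grid, convolved with a Gaussian tip (σ_tip, default
1 nm), decimated to pixel centres (default 1 nm/px), and perturbed with
additive Gaussian noise (default 0.1 nm). Blurring before sampling matters:
the tip convolves the continuous surface, and sampling first would quantise
footprint edges to the pixel grid and destroy sub-pixel width information.
An optional apparent-height cap stands in for substrate-deformation effects
(the measured 5.2 nm helix height lies between the 2.46 nm bilayer thickness
and the 10.7 nm width, implying compliance this rigid model does not
capture); by default no cap is applied and validation uses generator truth,
not experimental heights, as ground truth.

**Populations.** Per-helix width, height and pitch are drawn from
zero-truncated normals, handedness from a Bernoulli(right fraction), twist
phase and map seed per helix; the drawn height is rendered as the slab
thickness. Presets encode the two assembly conditions: `ph7` — pitch
86.4 ± 6.7 nm, height 5.2 ± 0.4 nm, width 10.7 ± 1.7 nm, 50:50 handedness;
`ph4` — pitch 110.1 ± 20.3 nm, height 15.6 ± 2.4 nm, width 21.4 ± 3.4 nm,
50:50. The pH 4 width was reported only qualitatively ("much larger"
multilayer stacks), so the preset doubles the pH 7 value; this also keeps
width > height, without which the two dimensions of a resting rigid
cross-section are not separately identifiable from a height map (the image
is invariant under swapping them with a quarter-turn phase shift).

What the generator does **not** emulate: scanner drift and line noise,
non-Gaussian tip shape and tip–sample dilation, substrate deformation,
stain granularity, overlapping or curved helices, finite helix ends.
Passing recovery tests therefore demonstrates estimator correctness under
the rigid-ribbon imaging model, not performance on raw experimental
micrographs.

## 4. Morphometric estimators

All estimators share one path: deskew (footprint PCA orientation, bilinear
rotation when the axis is off by > 0.5°), background segmentation
(threshold from the border frame — median plus trimmed spread — since the
borders are substrate by construction; plain Otsu can split high-twist from
face-on regions *within* a strongly modulated footprint), then the axial
maximum-height profile over footprint columns.

**Pitch = 2 × profile period.** The profile repeats every half turn, so the
estimator doubles the measured period; reporting the raw period would
silently halve the pitch. The period comes from the dominant autocorrelation
peak, refined as the mean spacing of sub-pixel face-on *minima*. Minima are
used because the profile maxima split into a double hump around each edge-on
passage (h(α) = W|sin α| + T|cos α| peaks at α = atan(W/T), either side of
90°), making maxima spacings alternate. Three cross-section regimes are
distinguished: ordinary (W clearly > T, multiplier 2); squarish, where
edge-on dips alternate with face-on minima and are separated by their
alternating depths (multiplier 2 on the deep class); and degenerate square
(W ≈ T), recognised by a profile max/min ratio near √2 with a single hump
between minima, where all four quarter-turn passages are equivalent and the
multiplier is 4. The reported sd is over individual (doubled) spacings and
n_periods counts them; population summaries report both helix-level and
total period-level counts, since a quoted "n" can mean either.

**Width and height** are read near the face-on passages and inverted
through the rigid-ribbon model. At twist angle α from face-on, the
half-maximum footprint extent is W·cos α + (T/2)·|sin α| — the tilted
cross-section ends in a full-height cliff at one footprint extreme and a
ramp of lateral width T·|sin α| at the other, and the half-maximum point
sits mid-ramp — while the on-axis apparent height is
T·(cos α/2 + 1/(2 cos α)) + (W/2)·|sin α|. Extents are localised by the
centroid of the edge-gradient lobe (the gradient extremum of a symmetric
blur sits exactly at the unblurred edge, realising the half-maximum
convention without threshold bias); on-axis heights are medians of the
central footprint rows, sampled at 3 px ≤ |Δx| with |α| ≤ 0.6 rad to stay
outside the tip-blur core of the V-shaped minimum and clear of the
corner-crossing breakdown at tan α = W/T. W and T are solved by alternating
the two inversions (4 iterations, well past convergence). Raw per-column
readouts without this inversion carry 2–6% biases (blur lift at the V
minimum, off-angle extent growth) — larger than the 1% noise-free recovery
this package holds itself to. For an untwisted stripe every column is
face-on and the estimators reduce to plain extent and central-median height.

**Handedness** is the sign of the ridge drift: as the cross-section
rotates, the per-column height maximum sweeps laterally in a sawtooth whose
steady drift direction is set by the hand (right-handed = toward smaller y
in the generator's frame, with z out of the substrate). The classifier
refines the ridge row per column to sub-pixel precision, discards sawtooth
jump-backs (steps ≥ 2 px), and takes the majority sign of the remaining
steps; confidence is the net majority fraction |n⁻ − n⁺|/(n⁻ + n⁺) ∈ [0, 1],
with labels below 0.02 reported indeterminate. Mirroring the map reverses
every step, so label antisymmetry is exact with identical confidence. A
structure-tensor cross-term readout was evaluated first and rejected: its
global sign inverts as the cross-section aspect ratio approaches 1, where
two stripe families cancel. The sign chain from the 3-D convention to image
space is frozen by a generated reference pair (one map per hand) in the
fixture set.

## 5. Numerical choices and conventions

- Flat tolerance 1° for handedness/pitch decisions; argmax ties to the
  smallest N; sample standard deviations use the n−1 denominator.
- Units: nm everywhere except scattering (Å, Å⁻¹, d = 2π/q); height-map
  files are plain-text matrices in nm with JSON sidecars.
- Scattering assignment is first-order nearest-spacing bookkeeping within a
  5% relative tolerance (no harmonic indexing); tightening the tolerance can
  only unassign.
- All randomness flows from one seed: pipeline stages use
  seed·1000003 + 7919·stage (mod 2³¹−1); population helices use child seeds
  drawn once from the cohort seed; relaxation runs use (seed, run) spawn
  keys. Reruns are bit-identical, and the pipeline manifest records a
  SHA-256 per artifact to make that testable.
- Problem sizes: recovery suites use cohorts of 10–50 maps (each ≈3.2
  pitches long at 1 nm/px) and a 3×4×3 one-at-a-time grid spanning 2× around
  the reference geometry; the racemic handedness check uses 200 maps. These
  sizes put sampling error well below the tolerances they are tested
  against.

## 6. Known limitations

- Near-square cross-sections (|W − T| below the noise floor, ≈0.3 nm at
  preset noise) have a genuinely four-fold-symmetric height profile; the
  quarter-period regime is detected and handled, but the crossover region
  can still misjudge the multiplier for individual maps.
- Slabs thinner than ≈3 px (≈3 nm at the default pixel size) approach the
  blur width and bias the width/height inversion by a few percent.
- The rigid resting model cannot represent cohorts with height > width
  (identifiability), nor apparent heights between the slab thickness and
  the width as produced by substrate deformation.
- Estimator validation is against this package's own generator; agreement
  with real micrographs depends on how well the rigid-ribbon imaging model
  holds.
- The twist builder assumes the below-half-turn-per-segment regime; it does
  not model writhe, supercoiling or variable twist along the contour.
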