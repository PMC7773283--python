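# Methods

## Coordinate, sign and unit conventions

The axial coordinate z runs in millimetres from the foramen magnum
(z = 0) caudally to the thecal-sac termination (z = L_sas), on a uniform
grid (default spacing 1 mm; non-uniform inputs are linearly resampled
with a logged warning). Caudally directed CSF flow is negative, so the
systolic peak of a cardiac-gated waveform is the most negative flow
value and the diastolic peak the most positive. All internal physics is
done in mm, s and mm²/s, so every dimensionless number is formed without
hidden conversion factors; reported velocities are cm/s
(`U [cm/s] = 100 · Q [mL/s] / A [mm²]`), volumes mL, surface areas cm².

## Geometry

The SAS cross-section is the annulus between dura and cord,
`A_sas = A_d − A_c`, wetted by both boundaries, `P_sas = P_c + P_d`. An
implanted catheter is treated as a solid circular obstacle: over its
in-SAS path it removes `(π/4)·OD(z)²` of area and adds `π·OD(z)` of
wetted perimeter. Segments of piecewise-constant OD are laid from the
catheter tip toward the dural entry point; catheter length beyond the
entry lies outside the SAS and contributes nothing. The default segment
stack (100 mm of OD 0.99 mm, then 240 mm of OD 1.98 mm, then 15 mm of
OD 1.93 mm, tip first) matches a commercial NHP intrathecal catheter;
with it, the proximal 15 mm segment only enters the sums when the
in-SAS path exceeds 340 mm. The adjustment is exactly conservative:
subtracting the footprint restores the original profiles bit for bit.

Volumes and surface areas are axial trapezoidal integrals of the area
and perimeter profiles. Real studies compute them from 3-D
segmentations; the axial integral is the stated surrogate here and is
exact for the piecewise-linear profiles the package manipulates. Nerve
roots are excluded from all areas and perimeters (they are below MRI
resolution in the source data this pipeline targets).

To compare axial distributions across animals of different spine
length, each profile is rescaled by `L_mean / L_sas` and linearly
resampled onto a common grid, leaving values at matching fractional
positions unchanged.

## Flow processing

Between-scan heart-rate variability is removed by affinely rescaling
each waveform's time axis to a common reference period (default
T_ref = 0.53 s, the cohort-average cardiac cycle). Only time is
rescaled: flow values are untouched, so extrema are preserved exactly
and stroke volume scales with the period as physics requires.

The flow surface Q(z, t) is a tensor-product B-spline (cubic in each
direction, linear in z when only two levels exist) with one basis
function per data site and a second-difference roughness penalty in
each direction. The single penalty weight is chosen by generalized
cross-validation over a log-spaced grid (26 points, 10⁻⁶–10⁴) by
default, may be fixed numerically, or dropped entirely, in which case
the surface interpolates the samples to machine precision. No installed
library provides a 2-D smoothing spline with GCV selection, so this
~80-line standard P-spline construction is implemented here directly.

Peaks are global extrema over the cycle per axial position (systolic =
minimum under the caudal-negative convention), stroke volume is the
trapezoidal integral of |Q| over one periodically closed cycle, and the
pulse wave velocity is the inverse OLS slope of the systolic-peak
arrival time against z (arrival regressed on position, slope inverted,
converted to m/s, positive for caudal propagation). Arrival times are
refined by parabolic interpolation around the discrete minimum, and the
regression runs on the measured slice locations when the field records
them — between those anchors the spline introduces phase distortion
that would otherwise bias the slope by about 1 %. A flat arrival
profile yields an infinite-PWV flag rather than an error. A constructed
arrival line `t(z) = 0.10 + z/1150` (z in mm) recovers exactly
1.15 m/s.

## Hydrodynamic characterization

With ν = 0.693 mm²/s (CSF at body temperature; numerically equal to the
dynamic viscosity in mPa·s at density 1 g/mL) and ω = 2π/T_ref:

- `Re = |Ū_sys| D_h / ν` — laminar below ~2300;
- `δ = √(2ν/ω)` ≈ 0.342 mm and `Re_δ = |Ū_sys| δ / ν` — conditional
  turbulence in oscillatory flow above ~550;
- `α = (D_h/2) √(ω/ν)` — Womersley number;
- `Re_NR = |Ū_sys| D_NR / ν`, `K = |Ū_sys| T / D_NR`,
  `β = Re_NR / K = D_NR² / (νT)`, and Hall's critical
  `K_cr = 5.778 β^(−1/4)(1 + 0.205 β^(−1/4))` for Honji-type
  instability around cylinders.

All numbers use |Ū_sys|: the thresholds concern flow speed, not
direction. D_NR defaults to a single constant 0.25 mm (mid-range of
anatomical nerve-root diameters, 0.2–0.3 mm) and may be given an axial
profile. Note an internal inconsistency in published summary values for
this system: a reported β of 2.79 with K_cr = 22.32 is incompatible
both with β = D_NR²/(νT) at any anatomical D_NR (which gives β ≤ 0.25)
and with the K_cr formula itself (K_cr(2.79) ≈ 5.18). The formulas are
implemented verbatim; those two scalars are not reproduced by design.

## Hagen–Poiseuille flow reduction

Treating the SAS as a series of short laminar conduits at fixed driving
pressure, resistance per unit length scales as D_h⁻⁴ and

    reduction = 1 − Σ_z D_h(z)⁻⁴ / Σ_z D_hw(z)⁻⁴ ,

with equal-weight sums over the uniform grid (a Δz-weighted variant is
available for non-uniform grids) and D_hw the with-catheter profile.
For a uniform conduit the sums collapse to `1 − (D_hw/D_h)⁴` exactly,
which anchors the unit tests. Sums run over grid points where both
diameters are positive and finite. The estimator ignores the annular
shape of the lumen (the D⁻⁴ law is the circular-pipe result), unsteady
inertia and wall compliance; it is a resistance *proxy*, and its virtue
is that it needs only the geometry.

## Mixed-effects comparison battery

Each parameter is measured along the spine, so per-animal measurements
form a curve. For one pairwise comparison (two group × time-point
cells) the model is

    y = β0 + β1 x1 + β2 x1² + β3 x2 + β4 age + β5 weight
        + z0 + z1 x1 + z2 x1² + ε ,

with x1 the normalized axial location rescaled to [0, 1] (for
conditioning of the quadratic term), x2 a 0/1 cell indicator, and
(z0, z1, z2) per-animal random effects with unstructured 3×3
covariance. Estimation is REML via statsmodels' MixedLM with design
matrices built exactly as above; inference on β3 is a Wald z test. Each
of the 7 comparisons (4 time-point pairs within group, 3 group pairs
within time point) is refit on its own two-cell subset. A singular
random-effect covariance triggers a flagged refit with diagonal
covariance; non-convergent fits are reported as missing cells, never
silently dropped — with only 4 animals per group some non-convergence
is expected and surfaced in the run manifest. The full battery is
13 parameters × 7 comparisons = 91 p-values with Bonferroni threshold
α/91 (5.49·10⁻⁴ at α = 0.05) and stars at α·{0.05, 0.01, 0.005,
0.001}/91.

Operating characteristics are verified by simulation from the model's
own generating process: with 20 subjects per cell, 11 axial points per
curve, random-effect SDs (1, 0.5, 0.5), residual SD 1 and a null group
effect, the empirical type-I error over 500 datasets lies within
[0.03, 0.07]; the 11-point curve length is the smallest that cleanly
identifies the quadratic random effect while keeping 500 REML fits
cheap. A nonzero β3 is recovered within 3 SE in essentially all fits.

## Synthetic cohort generator

The generator emulates the structure of a two-group (cervical/lumbar
implantation), three-time-point NHP study:

- **Geometry.** Smooth monotone-taper templates (monotone cubic splines
  through five control points) for A_c, A_d, P_c, P_d, evaluated at
  fractional axial position and rescaled so the cohort-mean along-spine
  averages hit configurable targets (defaults 15.43 / 39.65 mm² and
  13.88 / 22.09 mm, the published NHP group means, giving ~7 mL SAS
  volumes over a 300 ± 15 mm spine). Per-subject unit-mean lognormal
  factors (σ = 0.08) scale areas and perimeters jointly, preserving
  A_d > A_c.
- **Flow.** `Q(z, t) = −q0 · g(z/L) · s((t − z/PWV) mod T)` with a
  caudally decaying amplitude template g peaking just below the foramen
  magnum, a two-harmonic pulse s (second-harmonic weight 0.3) whose
  systolic lobe peaks ~100 ms into the cycle, true PWV 1.15 m/s,
  q0 = 0.35 mL/s (cervical systolic peaks 0.2–0.6 mL/s), per-subject
  heart period N(0.53, 0.05²) s, 32 samples per cycle at six levels
  (fractions 0, 0.08, 0.2, 0.45, 0.7, 0.88 of L_sas), and additive
  Gaussian noise (SD 0.01 mL/s).
- **Catheter effect.** Implantation adds the catheter footprint to each
  subject's geometry (cervical tip at 0.20·L_sas, lumbar at 0.72·L_sas,
  entry at 0.95·L_sas) and scales the flow amplitude by
  `1 − reduction`, where the reduction is the Hagen–Poiseuille
  prediction from that subject's *own* geometry — so the generated
  effect is, by construction, exactly the quantity the estimator
  recovers. Attenuation is uniform along z by default; a z-modulation
  hook exists but is off. Ground truth (scale factors, q0, T, PWV,
  attenuation) is recorded with every dataset, and generation is a pure
  function of (config, seed).

What the generator does **not** emulate: respiratory modulation,
retrospective-gating artefacts, vertebral-level anatomy, segmentation
error structure (noise is i.i.d. Gaussian/lognormal, not spatially
correlated), dural compliance, or any z-dependence of the flow
attenuation beyond the optional hook. Passing recovery tests therefore
demonstrates correctness of the analysis chain under its own
assumptions, not robustness to every artefact of real PC-MRI data.

## Numerical choices and degenerate inputs

- Grid uniformity tolerance 10⁻⁹ relative; summary-table round trips
  preserve values to ≤10⁻¹² relative.
- Trapezoidal integration throughout (exact for linear profiles); the
  stroke-volume integral closes the cycle periodically before
  integrating, giving ≤0.33 % error for a sinusoid at 32 samples.
- GCV failures fall back across the penalty grid; an all-singular grid
  raises rather than returning a bad surface.
- A catheter that locally exhausts the SAS (A_sas ≤ 0) is an error
  naming the offending z; a zero-length catheter path is a valid empty
  footprint and yields exactly zero flow reduction.
- Degenerate PWV fits (flat arrival profile) return +inf with a flag.
- With fewer than 2 subjects per cell, or a constant comparison
  indicator, the mixed model refuses to fit rather than returning an
  inestimable effect.

## Problem sizes

Default study conditions are 4 animals per group, 1 mm axial grids
(~300 points), 32-sample cycles at 6 levels, and the full 91-cell
battery; the simulation studies use 500 replicate datasets (type-I
error), 200 replicates (PWV under arrival jitter) and 25 replicates
(effect recovery). These sizes were chosen so every validation runs on
one CPU in minutes while keeping Monte-Carlo standard errors around
0.01 on rejection rates.

## Known limitations

- The flow-reduction estimator shares the printed formula's equal-weight
  sums; on a uniform grid this equals the Δz-weighted version, but the
  estimate does depend mildly on grid spacing near catheter ends
  (halving dz moves smooth-profile estimates by <0.1 %).
- Wald z inference on β3 ignores small-sample degrees-of-freedom
  corrections; at 4 animals per group p-values are approximate and the
  battery's value there is structural (effect signs and magnitudes),
  not exact error control.
- The hydraulic-diameter description collapses each cross-section to
  one number; eccentric cord position and the annulus shape are not
  represented.
- Published pooled hydrodynamic means from real cohorts cannot be
  reproduced from synthetic data and are not targeted; only the
  aggregation arithmetic over published cell means is checked exactly.
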