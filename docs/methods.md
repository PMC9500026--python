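# Methods

This note documents the models implemented in `optofluidics`, the defaults
and why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical choices that matter.

## Electrolysis micropump

Water electrolysis at the interdigitated electrodes,
2 H₂O → O₂ + 2 H₂, produces gas at

    ṅ = 3 i / (4 F)          [mol/s]

for electrode current *i* (three gas molecules per four electrons;
F = 96485 C/mol). The gas pressurizes the pump chamber; the isothermal
rate form of the ideal gas law couples pressure *P* and membrane-displaced
volume *V*:

    d/dt [ P (V + V₀) ] = ṅ R T,

and the quasi-static force balance across the membrane and the square
delivery channel closes the system:

    P = (32 μ L / a⁴) V̇ + f(V) + P₀.

`f(V)` is the membrane's pressure–volume law. Three laws are provided:

* **linear** (default): `f(V) = 64 E h³ V / (3 π R₀⁶)`. The coefficient is
  fixed by requiring its nondimensional form to equal the
  `64 h²/(3 π R₀²)` group of the closed-form solution, so both solution
  paths describe the same membrane.
* **spherical cap**: large-deflection clamped circular membrane, with the
  displaced volume the spherical cap of the apex deflection. A stiffer-
  than-linear alternative for validating law sensitivity.
* **tabulated**: monotone (V, P) pairs (e.g. from a finite-element
  characterization), PCHIP-interpolated so monotonicity is preserved.

### Two solution paths

`integrate_pump_ode` integrates the dimensional system with classical RK4
on a fixed grid aligned to every PWM switching edge. Because the gas moles
are known in closed form from the cumulative charge, the right-hand side
is smooth inside every step and gas-mole conservation is exact to rounding;
the integrator is deterministic (no randomness anywhere in this module).
Step-size default is period/40 (the integrator refuses anything coarser
than period/20) and peak flows are stable well below 0.5% under halving.

`solve_volume_closed_form` / `flow_rate_closed_form` implement the
nondimensional closed form: the quasi-steady implicit relation

    t* = (V* + V₀*) G(V*) + V* P₀*,

with `V* = V/R₀³`, `P₀* = P₀R₀/(Eh)`, `G(V*) = f(V* R₀³) R₀/(Eh)`, minus a
start-up transient of amplitude `M*/(V₀*(g + P₀*/V₀*)²)` decaying at rate
`(g + P₀*/V₀*)/M*` per unit t*, where `g = 64h²/(3πR₀²)` and
`M* = (24 μL/a⁴)(iRT R₀²)/(F h² E²)` is the normalized viscous resistance.
The nondimensional time scale is fixed by dimensional analysis so the
quasi-steady integral of the gas law reduces to the implicit relation:

    t = τ t*,   τ = 4 F E h R₀² / (3 i R T).

With this τ, the transient's decay rate redimensionalizes *exactly* to the
linearized ODE rate `a⁴ (f′(0) + P₀/V₀) / (32 μL)` — the apparent 24-vs-32
coefficient difference between the two equation paths is the 3/4
stoichiometric factor folded into the time scale, not an inconsistency.

**Accuracy relationship.** The closed form is the exact solution of the
*linearized* dynamics and the leading-order solution in M* beyond that
(the exact nondimensional balance carries an extra `M*(V*+V₀*) dV*/dt*`
term). Its peak-flow deviation from the ODE therefore grows with M*, i.e.
with viscosity × current, and with the gas-term nonlinearity V/V₀ at the
peak. The test suite verifies 1% agreement on randomized parameter sets in
the small-M* regime and verifies that the deviation shrinks proportionally
as M* is reduced; `scripts/acceptance.py` reports the measured deviation
at the printed device parameters across 0.1–1 mA, where it is several
percent to ~15% because M* there is not small. The ODE path is the ground
truth throughout.

### Defaults (SI)

| parameter | default | rationale |
|---|---|---|
| viscosity μ | 0.89×10⁻³ Pa·s | water at ~25 °C (aqueous drug solutions) |
| channel a, L | 30 μm, 7 mm | device channel geometry |
| membrane R₀, E, h | 1.2 mm, 4 MPa, 150 μm | SIS membrane properties |
| P₀, T | 101.3 kPa, 300 K | ambient conditions |
| reservoir | 500 nL | drug reservoir volume |
| V₀ | 5% of the 4.71 μL chamber | initial gas headspace is not a measured quantity; a small headspace fraction of the cylinder (h=1 mm, ⌀=2.45 mm) chamber is assumed and configurable |

The PWM drive is handled two ways, both exposed: exact on/off switching in
the ODE, and the duty-cycle-averaged "effective current" (duty × peak; an
RMS convention would be wrong here because gas generation is linear in
current) in the closed form.

### Reservoir exhaustion and delivery

Delivered volume is the time integral of positive channel flow, capped at
the reservoir volume; once the membrane has displaced the full reservoir,
flow stops. The closed form clamps its quasi-steady branch at the same
travel limit (a strict mode raises a diagnostic error instead). Without a
valve the flow may reverse during relaxation; the delivered-volume
integral counts only forward flow and is monotone by construction.

## Check valve

The flapper valve is reduced to an ideal rectifying series element with a
sharp forward cracking pressure (default 7.2 kPa) and complete reverse
blocking up to a reverse rating (default 45 kPa; beyond it the element
still blocks but warns, since that regime is uncharacterized). When open,
the flow solves the series balance with an optional extra open resistance
(default 0), so just above threshold the flow equals the unvalved flow
driven by the excess pressure. No opening hysteresis is modeled — the
data parameterizing the element are two pressures, not a loop.

## Square-duct flow and micro-PTV

The analytic laminar profile of a square duct (classical Fourier series
over odd harmonics, no-slip walls) provides both the synthetic ground
truth and the basis for converting observed midplane velocities into a
volumetric flow rate. The series is normalized to unit cross-sectional
mean using the analytic term-wise integrals; with 50 terms the
centerline-to-mean ratio evaluates to 2.0963.

Pipeline stages and their numerical choices:

* **Detection**: temporal-median background subtraction, fixed threshold
  (default: median + 5 robust sigmas), intensity-weighted centroids of
  connected regions (sub-pixel).
* **Linking**: minimum total squared displacement via the Hungarian
  algorithm on the standard augmented cost matrix; a hard gate `max_disp`
  forbids implausible matches and each unmatched detection costs
  `max_disp²` (birth/death). The recommended gate is 1.5× the expected
  per-frame displacement at peak flow. The assignment is verified against
  exhaustive enumeration for all instances with ≤ 6 particles.
* **Gap closing**: track ends re-joined to later starts across 1–3 missing
  frames within `max_disp × (gap+1)`; ambiguities resolved by minimum
  cost, exact ties by earliest start frame then smallest id. Positions in
  the gap are left unfilled — the spline spans them.
* **Smoothing**: least-squares B-splines of order 4 (cubic) with interior
  knots every 5 samples; velocities are the analytic spline derivatives.
  Tracks shorter than order+1 points pass through unsmoothed (flagged)
  with finite-difference velocities.
* **Eulerian field**: cell averages on a default 10 μm × 1 μm grid over
  the 500 × 30 μm field of view; empty cells are NaN with count 0, never
  zero-filled.
* **Flow rate**: count-weighted linear least squares of observed midplane
  velocities against the unit-flow duct profile — linear in Q, so
  doubling velocities doubles the estimate. Coverage below 50% of cells
  flags low confidence. A per-frame variant of the same fit gives the
  time-resolved flow for peak detection.

Coordinates: origin at the channel corner, x streamwise, y across the
channel, micrometres; frame k is at time k/frame_rate (default 640 fps,
0.64 μm/px).

## Rotational-behavior statistic

Keypoints (snout, both ears, both hind legs, tail base) below the
likelihood cutoff (default 0.6) are masked. One frame per 0.5 s bin (the
first at/after each bin start) gives a body vector from the back centroid
(legs + tail base, surviving members only) to the head centroid (snout +
ears). The per-bin rotation is

    θ = degrees( atan2(x₁y₂ − y₁x₂, x₁x₂ + y₁y₂) )

between consecutive valid vectors, kept *signed* in (−180°, 180°] so that
direction is explicit — cumulative rotation, left/right totals and their
ratio are only well defined with signed angles (an unsigned 0–2π wrap
loses the turning direction). Since pose CSVs use image coordinates with
y growing downward, the default `y_down=True` flips the sign so positive
θ is a left turn as seen in the video; a flag restores mathematical
handedness. Bins with no valid head or back are excluded and the
cumulative sum carries through unchanged. The left/right ratio is +inf
when no rightward rotation occurred. Per-bin rotations of ≥ 180° alias by
construction and the synthetic generator refuses to produce them.

## qNMR and photolysis

Per-proton peak integrals are proportional to concentration, so with the
maleic-acid internal standard (2 μl of 20 mM into 0.6 ml → 0.0667 mM):

    C_sample = C_ref · (I_sample/n_sample) / (I_ref/n_ref).

Proton counts per characteristic peak are configuration inputs. Photolysis
of the caged compound is modeled first order: caged = (C₀−r₀)e^(−kt),
released = r₀ + (C₀−r₀)(1−e^(−kt)), with k in 1/min and an optional t=0
released offset r₀ (off by default) for ambient-light exposure during
handling. The fit is joint over both species with shared k and C₀;
uncertainty on k comes from a residual bootstrap (seed-controlled,
95% percentile interval).

Protocol coupling: the caged pool grows at each phase's delivered rate
(including delivery from residual pressure during LED phases) and converts
at rate k only while an LED epoch is active, scaled by the LED duty cycle
(PWM illumination delivers proportionally less average power). Every
inter-event interval is integrated in closed form (linear source plus
exponential decay), so caged + released equals delivered to rounding.
Tissue clearance and diffusion of the released compound are not modeled;
exposure is reported as cumulative release.

## Synthetic-data generators

One global seed fans out through independent `SeedSequence` substreams per
scenario, so adding a scenario never perturbs another's draws, and fixed
seeds give byte-identical outputs.

* **Flow profiles**: pump-model output plus optional additive Gaussian
  noise; the truth record stores the noiseless peak and total.
* **Tracer movies**: 640 fps, 0.64 μm/px frames of Gaussian spots
  (σ = 1 px) on a constant background with Poisson noise; each tracer
  keeps a fixed cross-channel position (laminar flow) and advects with
  the local midplane duct velocity; tracers leaving the field re-enter
  under a fresh id. Not emulated: depth-of-field effects and depth motion
  (the analysis is midplane-2D), real background structure, particle
  aggregation and wall accumulation — so a passing round trip validates
  the tracking and reconstruction chain, not robustness to those imaging
  pathologies.
* **Pose tracks**: a rigid six-keypoint mouse template (snout 3 cm ahead
  of center, ears ±1 cm at +1 cm, legs ±1 cm at −2 cm, tail base −3 cm;
  plausible adult-mouse proportions, a convention rather than a claim)
  rotated at the commanded ω(t), with Gaussian keypoint noise and
  dropouts replaced by uniform garbage positions tagged with likelihood
  < 0.5. A one-second stationary tail is appended so binned
  quantification covers the full commanded rotation. Not emulated:
  body-shape deformation, occlusions, arena walls, multiple animals.
* **NMR series**: per-proton integrals proportional to the first-order
  concentrations with multiplicative Gaussian noise; tube concentrations
  follow the preparation (10 μl of 10 mM caged stock to 0.6 ml
  → 0.1667 mM; defaults for the illumination series are 0/1/5/10/30 min).
  No lineshape, phasing or baseline effects — peak integrals are taken as
  given, since spectral processing is out of scope.

Every generator returns a machine-readable truth record sufficient to
compute expected pipeline outputs without re-running the generator.

## Problem sizes

Default study sizes were chosen to exercise every pathway at full fidelity
while remaining desk-scale: 120 s PWM protocols at 4 Hz (≈20k integrator
steps), 400-frame tracer movies with 20 tracers, 12 s pose tracks at
25 fps, five-point photolysis series with 200–300 bootstrap replicates.

## Known limitations

* The closed-form pump solution degrades outside the small-M* regime (see
  above); the ODE is authoritative.
* The valve is quasi-static: no flap inertia, hysteresis, or partial
  opening.
* PTV is midplane-2D; out-of-plane shear biases are not represented.
* The rotation statistic cannot recover per-bin rotations ≥ 180° and
  treats the animal as rigid between binned frames.
* Released-compound pharmacokinetics (diffusion, uptake, clearance) are
  outside the model; release curves are chemistry-only.
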