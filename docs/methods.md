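# Methods

`nactwin` models the growth of a primary breast lesion and its response to
neoadjuvant chemotherapy (NAC) as a reaction–diffusion system on a
voxelized region of interest (ROI), and calibrates two patient-specific
"virtual biomarkers" — the biological conversion rate r_c and the
aggregated pharmacodynamic efficiency ε_PD — from exactly two volume
measurements: the baseline lesion volume V(0) at diagnosis and the
residual volume ΔV_s at the end of therapy.

## Model

The tumor is a single solid phase described by a dimensionless cell
density φ_c(x, t) ∈ [0, K] with the carrying capacity normalized to
K = 1 (any other K rescales the field without changing volume fits).  Up
to three drug species φ_dj are transported alongside it:

    ∂φ_c/∂t  = ∇·(D_c ∇φ_c)  − r_c φ_c ln(φ_c/K) − Σ_j ε_PDj φ_dj
    ∂φ_dj/∂t = ∇·(D_dj ∇φ_dj) + f_j(t) m_d − ε_PKj φ_dj

with zero-flux conditions on the ROI boundary for every species.  The
lesion volume is the volume integral V*(t) = ∫ φ_c dx, reported in cm³ —
the only observable validated against clinical measurements.  Disease
time is split at diagnosis (t = 0): Phase I is free growth from an
unknown onset t_i < 0; Phase II is therapy over [0, Δt_s] (Δt_s = 168
days for the standard regimen: epirubicin/cyclophosphamide every 21 days
× 4, then weekly taxane-based therapy × 12).

The drug kill term is linear in the drug concentration and independent
of φ_c, with the update clamped so φ_c never drops below zero; a
mass-action variant (kill ∝ φ_dj·φ_c) is available via
`SolverOptions(mass_action_kill=True)` for sensitivity analysis.

### Parameters

| symbol | meaning | unit | default / fixture values |
|---|---|---|---|
| r_c | biological conversion (proliferation) rate | 1/s | fitted; plausibility band 4e-7 – 6e-6 |
| K | carrying capacity of the tissue matrix | – | 1 (normalized) |
| D_c | tumor effective diffusivity | m²/s | 1e-13 |
| D_dj | drug effective diffusivity | m²/s | 1e-5 |
| ε_PDj | pharmacodynamic efficiency (kill per unit drug) | 1/s | fitted (aggregated); range 1e-7 – 4e-4 |
| ε_PKj | first-order clearance | 1/h | 2 (EC), 50 (taxane/antibody) |
| m_d | normalized dose rate during infusion | 1/s | 1/(1 h) in pulsed mode |
| φ_ci | seed density at onset | – | 0.01 |

Constructors accept clinical units (days, hours, millimetres); all
internal computation is in SI seconds and converted exactly once.

## Geometry

Patient-specific segmented geometries are not part of this package; the
ROI is a sphere (ellipsoids supported) of volume 10× the baseline lesion,
voxelized at a spacing chosen to give ≈ 6000 ROI voxels (≈ 1.3–3 mm for
the fixture volume scale).  Only the volume integral is validated, and
the volume functional is exact on the voxel grid by construction.  The
initial condition is a uniform ball of density φ_ci = 0.01 whose region
volume is 0.5 cm³, giving an integrated seed volume V_i* = 5e-3 cm³
("small enough" for disease onset; results are insensitive to the seed
because stage-1 calibration absorbs it into t_i).  NIfTI masks and
closed STL surfaces can be imported in place of the synthetic ellipsoid;
STL surfaces are voxelized by parity ray casting over voxel-center
columns.

## Numerics

Space: 7-point finite-volume Laplacian over masked voxels; links exist
only between ROI voxels, which implements the mirrored-ghost zero-flux
condition and makes the scheme conservative to solver precision (mass
drift < 1e-10 relative over 100 steps with reactions disabled — tested).

Time: first-order operator splitting per macro step with exact
sub-process maps, arranged Strang-style for the growth term:

1. half-step Gompertz growth (closed-form map),
2. backward-Euler diffusion for every species (sparse LU, factors cached
   per (D·dt)),
3. exact drug kinetics over the step (piecewise-exponential solution of
   dφ_d/dt = a − ε_PK φ_d) together with the exact exposure integral
   ∫φ_d dt, whose product with ε_PD is the kill decrement,
4. half-step Gompertz growth; clamp φ_c to [0, K], φ_d to ≥ 0.

The Gompertz logarithm is floored: for φ_c < 1e-12·K the growth rate is
linear in φ_c with coefficient r_c·|ln 1e-12|.  Besides giving the
x ln x limit a finite value, this bounds the amplification rate at the
leading edge of the lattice invasion front, which is what makes the
front speed converge linearly under time-step refinement.  Default macro
step: 0.25 day (0.5 h inside infusion windows in pulsed-exposure mode).
Halving the step from 1/8 to 1/16 day changes V*(0) and ΔV_s* by < 0.5%
(tested); at the 0.25-day default the residual discretization bias in
V* is ≈ 0.6% per halving — thirty-fold below the 20% clinical margin,
and calibrated results absorb it by construction because fitting and
prediction share the discretization.

Drug transport: D_dj = 1e-5 m²/s homogenizes a centimetre ROI within
seconds, 10⁸ times faster than the tumor spreads, so the default drug
model treats each drug as spatially uniform and solves its ODE exactly
(`drug_model="well_mixed"`); the full PDE drug model is retained and
agrees with the reduction to < 1% in spatial mean (tested).

### Drug exposure model

With the published clearance constants, a literal 1-hour infusion is a
near-impulse of exposure (total ∫φ_d dt = dose/ε_PK, delivered within
minutes to hours).  For fast-growing tumors (r_c of a few 1e-6/s, inter-
dose regrowth e-foldings r_c·T ≈ 3–10) the regrowth between doses then
provably outruns any per-pulse kill, and the end-of-therapy volume
becomes an all-or-nothing function of ε_PD — partial responses such as a
16 → 3.3 cm³ reduction are unrepresentable for any ε_PD.  Since the
clinical cohort consists of partial responders, the default exposure
model (`exposure="block"`) sustains each drug at a fixed dimensionless
concentration over its dosing block (first dose to one interval past the
last), turning Phase II into a continuous competition between kill and
regrowth; the literal pulse train remains available
(`exposure="pulsed"`), and the pharmacokinetic clearance checks use it.

The sustained concentration is 0.02 dose units.  The product m_d·ε_PD is
not identifiable from volume data, so this scale is a convention fixed
once: at 0.02, the slowest patient's published (r_c, ε_PD) pair
accumulates an order-unity integrated kill over Phase II (a partial
response, as reported for that case), and stasis-level ε_PD for the whole
published r_c band falls inside the published ε_PD range.

## Calibration

Stage 1 (onset / growth).  Phase I is autonomous, so one free-growth run
records V* as a monotone function of elapsed growth time; the onset t_i
follows by inverting that curve at V(0) (linear interpolation between
macro steps, bracket reaching growth age r_c·t = 4.5).  A single baseline
volume cannot identify r_c and t_i jointly; the degeneracy is broken by a
clinical prior: either r_c is supplied directly (replay mode — the
published per-patient rates) or it is searched on a log grid over a
Ki67-indexed third of the plausibility band (≤ 15% → lower third,
15–30% → middle, > 30% → upper), each candidate resolved by the onset
fit, ties broken by the shortest growth history.  Band mode guarantees a
baseline reproduction inside the band, not a unique rate.

Stage 2 (efficiency).  With the growth parameters held, one aggregated
ε_PD applied to every drug channel is searched so that the modeled
residual volume matches ΔV_s.  The objective is continuous and
non-increasing in ε_PD (comparison principle — tested), so a
deterministic bisection on the signed volume residual over log ε_PD
converges; stopping rule: |residual| ≤ 1e-3 cm³, bracket collapse below
2e-3 in ln ε (0.2% in the parameter), or 50 iterations.  The residual
floor in practice is set by voxel quantization of the volume (one voxel
≈ 0.02–0.03 cm³ at the default resolution).

Classification follows the clinical margin rule: a case is a true
positive when |V* − V|/V ≤ 20% at both timepoints.  Cohort precision and
sensitivity count each out-of-margin case as one false positive and one
false negative (the symmetric reading that reproduces 100%/100% on an
all-TP cohort); specificity is undefined without negative cases and
reported as null.

## Virtual cohort

The synthetic generator draws r_c log-uniformly over the published
band.  Two priors make the cohort resemble the study conditions rather
than a blind parameter sweep:

- Onset: t_i = −τ/r_c with growth age τ ~ U(1.8, 2.8).  The volume
  history collapses onto a single curve in τ (the lattice front advances
  ∝ r_c), and this window places every virtual baseline in the
  clinically observed 1–16 cm³ span.  A common calendar window (e.g.
  years) would let every tumor fill the ROI before diagnosis and destroy
  identifiability.
- Efficiency: the kill-to-growth ratio ρ = ε_PD·c_block·e/r_c is drawn
  log-uniformly in (0.15, 0.6) and ε_PD clipped into the published
  range.  ρ < 1 keeps the response measurable but incomplete — the
  regime of all three clinical cases.  Complete responders (ΔV_s* = 0)
  carry no information about ε_PD beyond a lower bound, and
  non-responders none at all, so recovery there is ill-posed by
  construction, not by implementation.

Ki67 is back-assigned from the r_c tertile so band-mode calibration is
exercisable.  Observations are the simulated V*(0) and ΔV_s* times
(1 + e), e ~ N(0, σ) with σ = 5% by default — an explicit stand-in for
contrast-enhanced MRI volumetry error, for which no published model is
available.  The generator emulates only volumes; it does not emulate
image intensities, segmentation error structure, spatial heterogeneity,
or inter-scan registration, so passing recovery tests demonstrate the
calibration machinery is correct and well-conditioned under the stated
noise model, not that the biomarkers are recoverable from real images.

Recovery studies refit r_c with the onset held at its generating value
and ε_PD with the growth stage held, mirroring the structure of the
self-consistency checks; the studies run on a fixed 26 mm spherical ROI
at 3 mm spacing with a 0.5-day step — generation and refit share the
discretization, so recovery error measures the calibration itself.

## Problem sizes

Default fixture grids ≈ 6000 ROI voxels (1.3–3 mm spacing depending on
lesion scale); virtual-cohort grids ≈ 2800 voxels; macro step 0.25 day
(0.5 day in the cohort studies).  These sizes keep a full three-case
replay calibration around two minutes and a 20-patient recovery study a
few minutes on one core, while staying ≥ 30× inside the clinical margin
on discretization bias.

## Known limitations

- The computed volumes of the original study depend on patient-specific
  segmented meshes that are not available; this package reproduces the
  margin-rule classification and the calibration machinery on synthetic
  geometry, not the exact printed V* values, and its fitted ε_PD values
  are comparable only under this package's exposure normalization.
- The lattice invasion front is grid-limited (the continuum front width
  √(D_c/r_c·|ln floor|) ≈ 0.05–0.1 mm is far below any practical voxel
  size), so absolute front speeds are discretization properties;
  calibrated quantities are insensitive because fit and prediction share
  the grid.
- Single-compartment pharmacokinetics with the published clearance
  constants; no drug-resistance dynamics, immune or stromal effects, no
  spatial heterogeneity of perfusion, no post-therapy (relapse-phase)
  dynamics.
- Precision/sensitivity are degenerate metrics on an all-positive
  three-case cohort; they are reported for completeness, not as evidence
  of discriminative power.
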