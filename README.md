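# nactwin

Reaction–diffusion modelling of breast-tumor growth under neoadjuvant
chemotherapy (NAC), with two-stage calibration of patient-specific
**virtual biomarkers** from routine imaging volumetry.  The package is
aimed at mathematical-oncology researchers who want a tested, fully
synthetic-data-capable implementation of the volume-dynamics +
calibration pipeline: simulate a lesion from its (unknown) onset through
a chemotherapy regimen, fit the model to two clinical volume
measurements, and study how reliably the fitted biomarkers can be
recovered.

## Model

A dimensionless tumor cell density φ_c and up to three drug
concentrations φ_dj evolve on a voxelized region of interest Ω₀ with
zero-flux boundaries:

    ∂φ_c/∂t  = ∇·(D_c ∇φ_c)  − r_c φ_c ln(φ_c/K) − Σⱼ ε_PDj φ_dj
    ∂φ_dj/∂t = ∇·(D_dj ∇φ_dj) + f_j(t)·m_d − ε_PKj φ_dj

Growth is Gompertzian (self-limiting toward the carrying capacity
K = 1); each drug is delivered by the regimen indicator f_j(t), cleared
at first order (ε_PK), and kills tumor at rate ε_PD per unit
concentration.  The observable is the lesion volume
V*(t) = ∫ φ_c dx (cm³).  Disease time is split at diagnosis (t = 0):
Phase I is free growth from an onset t_i < 0, Phase II is therapy over
0 ≤ t ≤ Δt_s (168 days for the standard EC ×4 → weekly taxane ×12
regimen).

Calibration is two-stage, per patient:

1. **Stage 1** — fit the onset t_i (and, lacking a clinical prior, the
   conversion rate r_c on a Ki67-indexed band) so that V*(0) matches the
   measured baseline volume V(0);
2. **Stage 2** — keep the growth parameters and fit one aggregated ε_PD
   across all drug channels so that the end-of-therapy volume ΔV_s*
   matches the measured residual volume ΔV_s.

A case counts as a true positive when model and measurement agree within
the 20% clinical error margin at both timepoints.  The fitted pair
(r_c, ε_PD) are the virtual biomarkers: proliferative aggressiveness and
chemosensitivity.

The three clinical cases ship as bundled fixtures (measured volumes,
receptor/Ki67 status, regimens, published per-patient parameters), and a
virtual-patient generator draws cohorts with known ground truth for
recovery studies.  See `docs/methods.md` for the numerical scheme, the
drug-exposure model, and every default with its rationale.

## Worked example

Calibrate the three bundled cases (also available as
`python analysis/02_calibrate_patients.py`, or `nactwin cohort` on the
command line):

```python
from nactwin.replication import replay_calibrations
from nactwin.report import summary_table

results = replay_calibrations()
print(summary_table(results).to_string(index=False))
```

prints

```
 patient  V(0)_cm3  V*(0)_cm3  AD(0)_cm3  dVs_cm3  dVs*_cm3  AD(dts)_cm3 label
patient1       4.2      4.200     -0.000     0.18     0.183        0.003    TP
patient2      16.0     15.958     -0.042     3.30     3.207       -0.093    TP
patient3       1.4      1.395     -0.005     1.40     1.400        0.000    TP
```

Each row compares a measured volume (V, ΔV_s, from contrast-enhanced
MRI) with its calibrated model prediction (V*, ΔV_s*); AD is the signed
difference predicted − observed.  All three cases sit well inside the
20% margin at both timepoints (largest relative deviation ≈ 3%), so the
cohort classifies 3/3 true positive — precision and sensitivity 100%,
specificity undefined because the cohort has no negative cases.  The
fitted onsets and biomarkers are on the result objects, e.g.
`results[0].t_i_days` ≈ −80 d and `results[0].eps_pd` ≈ 5.2e-6/s for the
slow-growing case.

The numbered scripts under `analysis/` walk the full study: forward
simulation of a published parameter row (`01`), the calibration table
above (`02`), stage-wise self-recovery of the published biomarkers
(`03`), and a 20-virtual-patient recovery study at 0% and 5%
observation noise (`04`); outputs land under `results/analysis/`.

## Layout

```
src/nactwin/       domain.py      ROI grids, seeding, volume functional, NIfTI/STL I/O
                   kinetics.py    growth/kill/clearance terms, regimens, parameters
                   solver.py      operator-split PDE integrator, well-mixed drug model
                   calibration.py two-stage fitting, margin rule, cohort metrics
                   cohort.py      bundled clinical fixtures, virtual-patient generator
                   recovery.py    parameter-recovery studies
                   replication.py study-level analyses shared by scripts and tests
                   report.py, cli.py   structured outputs and the `nactwin` CLI
analysis/          numbered narrative drivers (01–04)
scripts/           acceptance.py
tests/             pytest suite (unit, property, acceptance)
```
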