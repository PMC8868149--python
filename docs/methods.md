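# Methods

## Study design emulated

Eighteen pigs in three weight bands (53–57, 73–77, 93–97 kg; n = 6 each)
receive 20 mg/kg cefuroxime as a 10-min intravenous infusion at 0 and
480 min. Microdialysis catheters sit in a surgical deadspace (glenohumeral
cavity after humeral-head excision; 30-mm membrane) and in cancellous bone
(10-mm membrane), perfused at 2 µL/min with saline carrying 5 µg/mL
meropenem as the internal calibrator. Dialysate vials are collected every
30 min for the first 4 h of each dosing interval and every 60 min for the
second 4 h (12 vials per interval, 24 per catheter); a free-drug plasma
sample is drawn at the midpoint of every collection interval. All times are
minutes from the start of the first infusion; collection intervals are
half-open [t_start, t_end).

## Recovery calibration

Relative recovery per vial is RR% = 100·(1 − C_dial,cal/C_perf). The
catheter's recovery is the arithmetic mean of per-vial values — one
time-constant number per catheter, matching how a single per-catheter
recovery is conventionally reported. Calibrator measurements below the
calibrator LOQ (0.050 µg/mL) are excluded from the mean; if nothing usable
remains, or the mean is non-positive (catheter failure), the catheter
receives the mean of the measured recoveries of the same compartment
elsewhere in the cohort, flagged `imputed`. Individual vials whose
calibrator reading exceeds the perfusate concentration (possible under
assay noise at low recovery) enter the mean as negative per-vial values
rather than being censored, which keeps the estimator unbiased; only the
catheter-level mean is judged.

## Profiles and the dose boundary

Dialysate vials are interval averages. After recovery correction each is
placed at its interval midpoint: the study's own plasma reference is drawn
mid-interval, so this placement time-aligns all three channels. Profiles
are anchored at (0, 0) (drug-naïve animals) and keep one absolute clock;
the second interval is not re-anchored.

Dose times are slope discontinuities of the true curve, so windowed metrics
never interpolate across them. Each dosing-interval window [start, end]
uses the points inside it; a boundary concentration with no exact sample is
carried by extrapolating the *preceding* segment — log-down for AUC,
linear (clipped at zero) for the PD metrics. Concretely, the interval-1
window ends at 480 min with the washout extension of its last two vials,
and interval 2 *starts* at that same carried concentration: residual drug
carries across the dose (a deadspace still above the MIC at 480 min gets a
time-to-threshold of 0), while the post-dose rise cannot bleed backwards
into interval-1 metrics. The window tail beyond the last observation
midpoint (930–960 min) is covered the same way. Drug values below the LOQ
(0.01 µg/mL) are set to 0 when they follow the last quantifiable vial and
treated as missing otherwise.

## Non-compartmental metrics

AUC uses linear trapezoids on rising, flat or zero-touching segments and
logarithmic trapezoids on positive declines (exact for mono-exponential
decline; the log form is evaluated via `log1p` so near-flat declines lose
no precision, and window boundaries inherit the parent segment's rule,
which makes AUC exactly additive across sub-windows). C_max is the maximum
observed concentration in the interval and T_max the earliest time
attaining it, reported on the interval's own clock. λ_eq is the negative
OLS slope of ln C on t over all points strictly after T_max within the
interval with positive concentration — a deterministic, auditable window —
with a minimum of 3 points (configurable); a non-negative slope or too few
points yields "undefined" with a reason code, never an exception.
T_½ = ln 2/λ_eq. Penetration is AUC_tissue/AUC_plasma per interval.

fT>MIC uses the piecewise-linear interpolant on *both* rising and falling
segments, with crossings solved exactly per segment. This is deliberately
different from the AUC's log-down rule: time-above-threshold is
conventionally read by linear interpolation, and the asymmetry is
documented rather than harmonised. %fT>MIC is aggregated as the mean of
per-subject percentages.

## Cohort summary

Group means carry t-distribution CIs (mean ± t_{n−1,0.975}·sd/√n; undefined
at n = 1). Interval and compartment contrasts are paired two-sided t-tests
on within-subject differences — every compartment and interval is measured
in every subject. This deliberately replaces a mixed-model ANOVA with
small-sample degrees-of-freedom correction; the substitution is recorded in
the output metadata of every run. Identical pairs return p = 1.

## Simulator

The kinetic model is linear and deterministic per subject:

* **Plasma**: two compartments (V_c, V_p, clearance CL, intercompartmental
  clearance Q) with zero-order infusion into the central compartment.
* **Bone**: a small satellite with first-order uptake k_in and efflux
  k_out; the equilibrium tissue/plasma ratio is k_in/k_out (< 1).
* **Deadspace**: a satellite of volume V_d (scaled to the humeral-head
  volume, ~14–22 mL across 55–95 kg) exchanging through a clearance that
  decays as CL_d(t) = CL_d0·e^(−t/τ_c) — the simplest mechanism producing
  the observed consolidation pattern (later, lower second-interval peak,
  much longer elimination, preserved exposure) — with partition coefficient
  P_d > 1 for retention in the haematoma. All exchange fluxes are mass-
  conserving, so total drug amount is non-increasing whenever no infusion
  runs and elimination occurs only from plasma.

The system is integrated with an explicit high-order Runge–Kutta scheme
(DOP853, rtol 1e-10) piecewise between infusion on/off times, with running
∫C dt states so interval averages and true AUCs are solver-accurate; the
solver reproduces the matrix-exponential solution on constant-coefficient
segments to ≤ 1e-8 relative. Ground truth lives on a 0.1-min grid: AUC from
the integral states, C_max/T_max from the grid, fT>MIC by exact crossing
refinement, and terminal T½ as the dense-grid log-OLS slope over the same
post-T_max window the estimator uses — the estimand is the window
log-slope, so noise-free comparisons isolate sampling sparsity rather than
window choice.

Measurements: plasma point samples at interval midpoints; dialysate drug
as true interval average × RR/100; calibrator as C_perf·(1 − RR/100); all
multiplied by unit-mean lognormal noise with CV `noise_cv` (default 0.10,
within the assay's reported 3–17% imprecision range). Between-subject
variability: lognormal CV 0.20 on clearances and 0.10 on volumes; catheter
recoveries drawn per catheter from normal(62, 15) (deadspace) and
normal(34, 10) (bone), truncated to [5, 95]%. Weights are uniform within
±2 kg of each band centre; plasma volumes and clearances scale linearly
with weight (dose is per-kg, so plasma and bone are weight-invariant up to
the small unscaled satellite uptake), while the deadspace volume follows
the humeral-head size and its exchange clearance does not scale — heavier
animals have slower-turning deadspaces.

### Calibrated defaults (75-kg reference)

| parameter | value | rationale |
|---|---|---|
| CL | 550 mL/min | noise-free pipeline plasma AUC ≈ 2477 min·µg/mL |
| V_c / V_p | 12.6 / 17.5 L | plasma C_max ≈ 48.5 µg/mL at the 15-min midpoint |
| Q | 900 mL/min | distribution fast enough that the post-peak decline is near log-linear, consistent with a single reported plasma half-life (T½ ≈ 47 min) |
| bone k_in / k_out | 0.0095 / 0.0135 min⁻¹ | bone penetration ≈ 0.75, T½ ≈ 70 min |
| CL_d0 | 0.515 mL/min | deadspace T_max ≈ 45 min, first-interval T½ ≈ 94 min |
| τ_c | 300 min | second-interval deadspace T_max/T½ lengthen (105 min / 459 min) and the cavity dips below 4 µg/mL shortly before the second dose |
| P_d | 1.23 | deadspace/plasma AUC ratio ≈ 1.60 in interval 1 |

These defaults were fixed once against the reported headline values and
qualitative orderings; they are study conditions, not fitting targets.

## What passing tests do and do not show

The generator emulates the study's design and the statistical structure the
analysis assumes — linear kinetics, a single time-constant recovery per
catheter, multiplicative assay noise. It does not emulate calibrator
degradation late in the 16-h sampling, drift in recovery over time,
nonlinear protein binding (free drug is the modelled quantity throughout),
surgical-bleeding dynamics, or any model misspecification. Recovery of
ground truth by the pipeline therefore validates the *estimators under the
stated assumptions*, not the assumptions themselves.

Known, quantified estimator biases under this design (noise-free, measured
against dense-grid truth at the calibrated defaults):

* **Plasma AUC is under-read by ~9%**: the infusion ends at 10 min but the
  first plasma draw is at 15 min, so the anchored linear rise misses the
  unsampled infusion peak. The published plasma AUC is defined by the same
  sparse design, so this is a property of the design, not an error of the
  implementation relative to it.
* **Dialysate AUC is under-read by ~2.4–2.8% in segments containing the
  sharp early rise** (30-min interval averages straddling the
  infusion-driven concave climb); the slow second-interval deadspace is
  recovered within 1%.
* **The deadspace first-interval fT>MIC is over-read by ~5–6 min**: its
  down-crossing of 4 µg/mL falls in the 60-min-sampling region, where the
  linear chord through midpoint-placed averages crosses late. Crossings in
  the 30-min region (plasma, bone) are recovered within ~1 min.
* Plasma terminal T½ is recovered within ~1.4%; cohort-mean fT>MIC under
  10% assay noise is recovered within 10% in ≥95% of 200 replicates.

## Numerical and degenerate-input conventions

Flat or zero-touching segments integrate linearly (the log form is
undefined there); ties in C_max break to the earliest time; windows
starting before the first profile point raise; empty groups raise while
missing per-subject metrics are flagged and excluded pairwise; reruns with
the same seed and configuration are byte-identical. Problem sizes
throughout (18 subjects, 200 replicates, 1000-profile oracle sweeps,
0.1-min truth grids) are the package's default desk-scale choices.
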