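# Methods

## Structural and statistical model

Meropenem concentrations are described by a one-compartment disposition model
with zero-order (infusion) input and first-order elimination. All regimens of
interest are repeated infusions sampled at steady state, so the package works
with the analytic steady-state solution obtained by geometric accumulation of
the single-dose profile over dosing intervals; explicit superposition of
doses is retained only as a brute-force oracle in the test suite. During the
infusion the steady-state curve rises monotonically from the trough; after
the end of infusion it decays monotonically, so the time above any threshold
has at most one up-crossing and one down-crossing per interval and fT>MIC is
computed exactly from closed-form crossing times (no time grid).

Between-subject variability is log-normal on clearance and central volume
with a full 2×2 covariance (ωCL, ωVc, correlation ρ), matching an exponential
IIV model. Renal function enters clearance as a power of Cockcroft–Gault
creatinine clearance normalized to 47.7 mL/min, the reference used by the
final model. Residual error may be additive, proportional or combined.
A two-compartment structure (biexponential disposition, IIV still on CL and
Vc) is provided purely as a structural-comparison hook.

Default parameters are the published final estimates: CL 6.472 L/h,
Vc 26.69 L, CRCL exponent 0.3834, ωCL 0.494, ωVc 0.8199, ρ 0.94. The
published residual-error report is internally inconsistent (the table's
"additional error" 17.4 mg/L, a text statement of a proportional model, and a
bootstrap median of 4.64 mg/L cannot all describe one model); the package
defaults to an additive σ of 4.64 mg/L — the bootstrap median, which is the
only value consistent with the magnitude of the observed concentrations — and
exposes all three error kinds by configuration, privileging none.

## Estimation

The marginal likelihood of the mixed-effects model is approximated by the
Laplace method, the same family of approximations as FOCE-type estimators in
commercial tools: for each subject the joint negative log-density is
minimized over (ηCL, ηVc) by a damped Newton iteration (finite-difference
gradient and Hessian, eigenvalue-floored for positive definiteness, step
backtracking), run vectorized across all subjects; −2 log L sums
2·h(η̂) + log det H(η̂) − 2 log 2π over subjects. The outer problem is solved
by L-BFGS-B on transformed parameters: log fixed effects, raw covariate
coefficients, the Cholesky factor of Ω (log-diagonal), log residual SDs.
The Cholesky parameterization keeps Ω positive semi-definite throughout.
Conditional modes are warm-started between outer iterations. The unit tests
pin the approximation against an 80-node adaptive Gauss–Hermite quadrature
oracle (agreement within 0.1 in −2LL on small problems).

Observations flagged below the 0.5 mg/L quantification limit are excluded
from the likelihood (M1 handling); values above 80 mg/L are retained but
carry a dilution flag. Relative standard errors come from a central
finite-difference Hessian of the objective at the optimum, mapped to the
natural scale by the delta method.

### Covariate search

Stepwise covariate modeling uses the study's thresholds: a candidate enters
when it lowers the objective by more than 3.84 (α = 0.05, 1 df) and survives
backward elimination only if its removal raises the objective by more than
10.83 (α = 0.001). Continuous covariates enter as power functions normalized
to the dataset median; binary covariates as proportional shifts (1 + θ·flag).
Ties in forward selection resolve to the larger drop, then to fewer added
parameters. A pre-screen removes one member of any covariate pair with
Pearson |r| ≥ 0.6 (the member with the smaller single-covariate objective
drop). The selection-recovery harness in the acceptance tests runs 20 seeds
of a 120-subject design with the CRCL effect planted at its published value
plus two log-normal decoy covariates, searching on clearance; 120 subjects
keep the planted signal (ΔOFV ≈ 50) far above the backward threshold while
holding the whole harness to a few minutes of CPU.

### Bootstrap and diagnostics

The nonparametric bootstrap resamples subjects with replacement to the
original cohort size, re-identifies duplicates, refits from the final
estimates, and summarizes converged replicates by the median and 2.5/97.5
percentiles; runs with more than 20% non-convergence are flagged unreliable.
CWRES use the FOCE linearization about the conditional modes: the model-
implied covariance G Ω Gᵀ + R (G = ∂f/∂η at η̂, R the residual variance at
the individual prediction) decorrelates the residual y − (f(η̂) − G η̂) via
its Cholesky factor; a singular covariance falls back to weighted residuals
with a warning. The pcVPC bins observations at the design's nominal sampling
times (the sampling is discrete, so nearest-time binning is exact), corrects
each observation by median-bin-PRED/own-PRED, and compares observed 5th/50th/
95th percentiles with 90% confidence bands formed from the same percentiles
of model-simulated replicates of the original design.

## Synthetic cohort

No patient-level data are distributed, so the cohort generator emulates the
study design: 44 adults (70% male) on 1.0 g q8h infused over 2 h (2.5 h
available by configuration), sampled at steady state at −0.5 h pre-dose
(encoded as τ − 0.5 within the interval) and at the end of infusion, 4 h and
6 h, with three of the four times drawn per subject (the real study's 135
samples from 44 patients ≈ 3 per patient). Age, weight and CRCL come from
truncated normal distributions matching the reported means, SDs and ranges
(age 68.5 ± 14.8 in [20, 91] years; weight 56.7 ± 9.04 in [40, 81] kg; CRCL
54.3 ± 29.6 in [11.9, 136] mL/min); 15.91% of subjects carry a hemodialysis
flag. CRCL is drawn directly from its reported distribution rather than
reconstructed from age/weight/creatinine — the study does not report the
joint distribution, and inventing one would fabricate correlation structure.
As a consequence age and weight are *independent* decoy covariates in the
synthetic data, which the real cohort's covariates are not: passing selection
tests show the thresholds' operating characteristics, not freedom from
real-world confounding. The cohort summary reports a mean CRCL of 54.3
mL/min while the tabulated value (and the model reference) is 47.7; the
generator defaults to the 54.3 distribution and offers the 47.7 variant as a
preset, while the model reference stays 47.7 throughout. Negative
concentrations from additive noise are redrawn rather than truncated, keeping
the error model unbiased near the quantification limit. Mid-course dose
adjustments and dialysis sessions are not simulated.

## Monte Carlo PTA

For each renal stratum, 500 virtual subjects are drawn once per seed: CRCL
uniform within the stratum (the "<10" band uses [5, 10) mL/min and the top
band is capped at 140, matching the recommendation grid) and (ηCL, ηVc) from
Ω. Residual error is excluded — attainment concerns true exposure — with a
flag to include it. The same subjects are reused across all 18 regimens,
4 MICs and 4 targets (common random numbers), so PTA is monotone in MIC,
dose and target stringency cell-by-cell, not just in expectation. The within-
stratum covariate distribution is not stated by the study and is the largest
reproduction risk; it is isolated behind a switch (uniform, fixed midpoint,
fixed boundary). "100% fT" targets are evaluated as a trough criterion with
a 1e−9 tolerance, since no numerical tolerance is published. Total
concentrations proxy free drug (protein binding ≈ 2%); a free fraction of
0.98 is available by configuration. The recommendation table marks a cell
"All"/"None" or the minimal attaining regimen under the ordering: total
daily dose, then per-dose amount, then infusion duration; "(2 h)" marks cells
where only the prolonged infusion attains. Steady-state troughs are also
checked against literature toxicity thresholds (64.2 mg/L neurotoxicity,
44.45 mg/L nephrotoxicity) as a safety flag.

## Problem sizes and numerical choices

Defaults follow the study: 500 Monte Carlo subjects per scenario, 500
bootstrap replicates, 1,000 pcVPC simulations. The test suite scales some
harnesses to keep a full run in minutes on one CPU: parameter recovery uses
five 500-subject refits, the selection harness 20 seeds at 120 subjects,
CWRES calibration a 300-subject evaluation, and the pcVPC self-consistency
check three 44-subject cohorts at 300 simulations — sizes chosen so each
check retains clear statistical margin. Inner Newton iterations stop at a
gradient of 1e−7 with a finite-difference step of 1e−4 in η; the outer
optimizer runs to an L-BFGS-B ftol of 1e−9 (1e−6 in the covariate-search
harnesses, where only objective differences of order 3.84 matter).
Degenerate inputs are handled explicitly: infeasible covariate multipliers
and non-finite inner solutions contribute a large penalty and a warning
naming the subjects; Ω is floored at an SD of 1e−6.

## Known limitations

The estimator is a Laplace approximation, not the vendor-exact FOCE-ELS, so
objective values differ slightly from commercial output (differences are
bounded by the quadrature-oracle tests). The synthetic cohort cannot
reproduce the real study's fitted RSEs, its OFV, or real-data diagnostics —
those depend on the raw concentrations — so the validation suite substitutes
operating-characteristic checks on simulated data. One CRCL value per
subject is used (no within-course renal drift), interoccasion variability is
not modelled, and dialysis enters only as a binary covariate candidate, not
as a kinetic event.
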