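# Methods

## The analysis problem

A selective CDK9 inhibitor given as a 30-minute weekly intravenous infusion
(30 mg) suppresses transcription of short-lived oncogenic mRNAs. The
package models three linked layers of a phase-I style analysis: (i)
model-free (noncompartmental) summaries of each patient's plasma
concentration–time profile, (ii) a pooled structural PK model of the whole
cohort, and (iii) a mechanism-based PD model linking plasma concentration
to MYC/MCL1 mRNA in whole blood, expressed as percent of the pre-dose
baseline.

## One-compartment IV-infusion model

Drug amount A obeys dA/dt = R0·1(t ≤ Tinf) − k·A with R0 = dose/Tinf and
k = CL/V; concentration is C = A/V. The closed form is

    C(t) = (R0/CL)(1 − e^{−kt})                    0 ≤ t ≤ Tinf
    C(t) = C(Tinf) e^{−k(t−Tinf)}                  t > Tinf

Units: dose mg (converted ×1000 to µg), time h, C µg/L, CL L/h, V L. The
model is linear, so doubling the dose doubles C(t) everywhere and
AUC0–∞ = dose/CL exactly; both are asserted in the test suite.

### Naive-pooled fitting

All subjects' post-dose observations are concatenated and one (CL, V) pair
is estimated by `scipy.optimize.least_squares` on log-transformed
parameters (positivity by construction), convergence tolerances 1e-10 on
the relative change of objective and parameters, at most 2000 residual
evaluations (500 iterations' worth). Starting values come from NCA of the
pooled mean curve (per-time-point averages), falling back to a
terminal-slope heuristic. Precision is reported as asymptotic CV% from the
Jacobian-based covariance of the log-parameters: to first order the SE of
log θ is the CV of θ.

**Weighting.** Two schemes are available: uniform (default) and
proportional (residuals (y−ŷ)/ŷ, i.e. weights 1/ŷ²). Proportional
weighting is the textbook choice when residual error scales with the
concentration — and with residual error only, it is nearly unbiased here
(−5 % on CL at a 20 % log-normal CV, the small offset coming from the
skew of the log-normal). Under between-subject variability, however, naive
pooling misattributes the spread of individual elimination rates to
residual noise: at late times the pooled relative residuals are dominated
by slow eliminators, and proportional weighting then underestimates CL
severely (measured −27 % on the default synthetic cohort with 30 % BSV,
versus +2 % for uniform weighting over 50 replicates). Uniform weighting —
which effectively emphasises the informative early, high-concentration
samples — is therefore the default for pooled fits; proportional remains
available for data without appreciable between-subject spread.

## Noncompartmental analysis

* **AUC/AUMC**: interval-wise trapezoids. Default method is
  linear-up/log-down (industry convention): the logarithmic trapezoid
  (C1−C2)/k with k = ln(C1/C2)/Δt is used when both endpoints are positive
  and declining, linear otherwise. A pure linear method is available.
* **λz**: log-linear regression on terminal points. Best-fit selection
  evaluates every tail of ≥ 3 positive concentrations strictly after tmax
  and keeps the largest adjusted R² (ties → more points, implemented by
  scanning longest-first and requiring strict improvement). A numerically
  zero or negative slope is a failure: λz-dependent quantities (AUC0–∞, t½,
  CL, MRT, Vss) are reported as NaN while Cmax/tmax/AUC0–t remain, the way
  a clinical table prints "—".
* **Derived**: AUC0–∞ = AUC0–t + Clast/λz;
  AUMC0–∞ = AUMC0–t + Clast·tlast/λz + Clast/λz²; CL = dose/AUC0–∞;
  MRT = AUMC0–∞/AUC0–∞ − Tinf/2 (the −Tinf/2 term removes the mean input
  time of a zero-order infusion; a bolus mode skips it); Vss = CL·MRT.
* **Missing/BLQ**: zero concentrations are treated as missing by default
  (dropped), with a documented `blq="zero"` flag to keep them; AUC0–t runs
  to the last positive concentration by default (`auc_cut` switches to the
  last observation). tmax ties break to the earliest time.

On noise-free analytic infusion curves with dense sampling the NCA
recovers CL within 2 % and Vss within 5 %, converging as the grid is
refined (tested).

## Indirect-response (turnover) PD model

The biomarker is produced at zero-order rate k_in (%·h⁻¹) and lost at
first-order rate k_out; drug inhibits production through a Hill term:

    dPD/dt = k_in (1 − Cⁿ/(IC50ⁿ + Cⁿ)) − k_out · PD,     PD(0) = 100

At homeostasis k_in = k_out·PD_initial with PD_initial = 100 %, so k_out is
not a free parameter: k_out = k_in/100. Maximum inhibition is complete
(Imax = 1), consistent with a pure Hill inhibition term. The form used is
the standard type-I inhibitory indirect-response model; it is the unique
standard turnover variant consistent with production-side inhibition, the
homeostasis substitution and the parameter set (k_in, IC50, n), and this
assumption is deliberately explicit here because the source presentation
of the equation is typographically ambiguous.

Consequences used as test oracles: C ≡ 0 holds PD at 100; constant C gives
PD_ss = 100(1 − Cⁿ/(IC50ⁿ+Cⁿ)) (so C = IC50 → 50 %); larger exposure gives
pointwise lower PD; and the nadir always lags the concentration peak.

**Integration.** LSODA (`scipy.integrate.solve_ivp`) with rtol 1e-8,
atol 1e-10. The driving concentration is supplied analytically — no
interpolation error — and integration is restarted at known kinks/jumps
(end of infusion, edges of washout pulses) so the adaptive solver never
steps across a discontinuity.

**Fitting.** Sequential PK→PD: the pooled one-compartment fit's typical
curve drives a pooled least-squares fit of (k_in, IC50, n) on the log
scale, baseline fixed at exactly 100 (the homeostasis substitution), with
unweighted residuals by default (PD is already scale-normalised;
proportional weighting optional). Starting values: k_in = 100·ln 2
(a ~1 h transcript half-life), IC50 = model concentration at the
observation nearest half of the maximal observed inhibition, n = 1.
Pre-dose observations are fitted against the baseline value. CV% as in the
PK fit. IC50 is estimated in total-plasma µg/L and reported additionally
as unbound nmol/L (× fu_plasma, / MW × 1000) when binding constants are
supplied — single-dose fits per occasion; accumulation from earlier weekly
doses is neglected (half-life ≈ 5.6 h versus a 168-h dosing interval).

## Binding constants and molecular weight

fu_plasma = 0.0665 and fu_media = 0.666 are the measured unbound fractions
in human plasma and culture media. The molecular weight used for
mass↔molar conversion, 404.4 g/mol, is a package calibration: the cohort's
multiple-dose Cmax extremes (410 and 894 µg/L) times fu 6.65 % must land on
the reported unbound exposure range 67.5–147 nmol/L, and
410 × 0.0665/404.4 × 1000 = 67.4, 894 × 0.0665/404.4 × 1000 = 147.0 —
no other value in the plausible range reconciles both ends. Raw products
are always carried unrounded; rounding (half-up, to the printed significant
figures) is display-only. The same convention explains the reported
166.5 → 167 nmol/L (250 × 0.666) and 116.375 → 117 nmol/L (1750 × 0.0665)
arithmetic.

## Cohort tables

The observed 15-patient table is packaged as a CSV fixture with two
exclusion flags per row: an implausible single concentration sample
(metadata only — it affected upstream NCA input, not the printed values)
and a dose reduction from 30 to 22.5 mg, which removes that subject's
multiple-dose row from multiple-dose summaries while keeping the
single-dose row. Summaries are arithmetic means and n−1 sample SDs of the
non-missing, non-excluded values; each column keeps its own n. The n−1
convention is what reproduces the table's printed SD row. One printed cell
(single-dose Cmax mean 709) differs by one unit in the last digit from the
mean of the printed per-subject values (708.47) — the published mean was
evidently computed from unrounded source values; the package reports the
value its inputs imply and does not force agreement.

## Synthetic-data generator

The generator emulates the study design: n = 15 subjects, 30 mg/0.5 h
infusions, rich plasma sampling to 24 h, biomarker sampling pre-dose and
1–24 h post-dose, and the in-vitro washout grid (−4, 0, 1, 2, 4, 8, 12,
16, 24, 48 h).

* **PK**: individual (CL_i, V_i) are log-normal around typical values
  CL = 10.3 L/h, V = 67.1 L (the cohort NCA means) with 30 % CV each — a
  typical phase-I between-subject magnitude, chosen because the study
  itself pools and estimates none. Residual error is proportional
  log-normal with 20 % CV (σ² = ln(1+CV²), median-preserving).
* **PD**: each subject's own true concentration curve drives the turnover
  model; additive Gaussian noise (SD 5 percentage points) is applied
  post-dose, truncated at 0, and the pre-dose sample is pinned to 100 %.
  Additive-on-% noise because PD is bounded and scale-normalised.
* **Truth values**: k_in = 140 %·h⁻¹ for both transcripts (k_out ≈ 1.4/h,
  a ~30-minute mRNA half-life — the fast turnover that makes these
  transcripts CDK9-sensitive), IC50 121.6 µg/L (MYC) and 395.3 µg/L (MCL1)
  total plasma, ≈ 20 and ≈ 65 nmol/L unbound, Hill n 1.5 and 1.0. These
  place the noiseless nadir 2–3 h post-dose with ~80 % (MYC) and ~45 %
  (MCL1) maximal suppression, matching the clinical scale of the effect.
* **Washout panels**: the nominal media concentration is reduced to its
  unbound level (× fu_media) and expressed as the plasma-equivalent total
  concentration (to µg/L, ÷ fu_plasma) so a single IC50 calibration drives
  both in-vivo and in-vitro scenarios.
* **Determinism**: all draws flow through `numpy.random.default_rng`
  (PCG64) seeded as `[seed, stream]` with a distinct stream per generator
  stage; a fixed seed is bit-reproducible across platforms.

What the generator does **not** emulate: assay limits of quantification
and BLQ censoring, dropout/missing visits, dose accumulation, circadian or
occasion-to-occasion variability in the biomarker, and correlation between
CL and V. Passing recovery tests therefore demonstrate estimator
correctness under the stated statistical model, not robustness to every
feature of real clinical data.

## Problem sizes and numerical choices

Recovery experiments use 50 seeded replicates of the default 15-subject
cohort for bias assessment; Monte-Carlo noise-calibration checks use 1000
subjects. The ODE tolerance pair (1e-8, 1e-10) keeps simulated PD within
~1e-6 of analytic steady states; tests of mathematical bounds and
monotonicity therefore allow slack at that scale. Optimizer tolerances
1e-10 make noise-free fits exact fixed points to < 1e-6 relative.

## Known limitations

* Naive pooling is a deliberate simplification: it estimates a typical
  curve, not between-subject distributions, and its finite-sample estimates
  inherit a small negative volume bias (~−7 % at 30 % BSV) from the
  nonlinear averaging of individual curves.
* The Hill coefficient is weakly identified from sparse pooled biomarker
  sampling (downward bias ~−12 % at the default design, wide CVs); fix it
  (`fix_hill=1`) when the data cannot support it.
* Sequential PK→PD propagates no PK uncertainty into PD CVs.
* The λz best-fit rule can select short noisy tails on very sparse data;
  manual index selection is provided.
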