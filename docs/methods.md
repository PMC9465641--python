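# Methods

## Structural model and closed-form evaluation

Disposition is a linear two-compartment model with first-order
elimination and zero-order infusion input. Writing k10 = CL/V,
k12 = CL2/V, k21 = CL2/V2, the macro rate constants are the roots of
λ² − (k10+k12+k21)λ + k10·k21, and the central concentration after one
infusion of rate R over duration T is

    C(t) = (R/V)·[A·φ(α) + B·φ(β)],   φ(λ) = (1−e^{−λs})·e^{−λu}/λ,

with s the infused time, u the time since infusion end, A = (α−k21)/(α−β)
and B = (k21−β)/(α−β). Multiple doses superpose. AUC over any interval is
the analytic integral of the same expression (no quadrature anywhere in
the pipeline); AUC(0, ∞) of a dose equals dose/CL and is returned through
that identity when the upper limit is infinite.

Numerical care:

- `(1−e^{−x})/x`-type factors use `expm1` with series fallbacks below
  10⁻⁸, so the one-compartment limit CL2 → 0 (where β → 0) is exact.
- When α−β is small relative to 1/t, the A/B form cancels
  catastrophically; the kernel then switches to divided differences of
  exponentials (`sinch`-based), which have a finite repeated-root limit.
  For strictly positive micro constants an exact double root is actually
  impossible (the discriminant equals (k10+k12−k21)² + 4·k12·k21 −
  4·k10·k12 … reducing to zero only when k10·k12 = 0), but the guarded
  branch keeps near-degenerate parameter sets accurate to ~10⁻¹⁰, which a
  dedicated test checks against a stiff ODE integration.
- The whole kernel is vectorized over an arbitrary leading batch shape;
  the estimator exploits this by pushing entire finite-difference
  stencils through single kernel calls.

Against an independently written stiff-ODE oracle (LSODA, rtol 10⁻¹²,
atol 10⁻¹⁶, integration segmented at the infusion-end discontinuity) the
closed form agrees to better than 10⁻⁶ relative error over thousands of
randomized parameter/dose cases, and to ~10⁻¹² against a matrix-exponential
evaluation.

## Covariate model

Typical values are modified by power functions of continuous covariates
normalised at reference values, and exponential functions of categorical
covariates. For a general fit the references default to the dataset
medians of the covariates in the model; for the validation protocols they
are fixed at CrCL 57.5 ml/min and ALT 37 U/L — the published reference
points — so that recovered estimates are directly comparable to the
reported equations. The final model carries CrCL on CL and ALT on V2;
inter-individual variability sits on V and CL only (V2 and CL2 carry
none).

## Estimation

The marginal likelihood integrates the random effects per subject with a
Laplace approximation:

    −2LL_i = 2·g_i(η̂) + log det G_i − d·log 2π,

where g_i is the negative log joint density, η̂ its minimiser and G_i its
Hessian at η̂. Residual variance is Var(y|η) = σ_add² + σ_prop²·f²
(proportional by default), i.e. the interaction form: the variance moves
with the conditional prediction.

- Inner problem: damped Newton, vectorized across subjects. The gradient
  and the exact Hessian of g are assembled by the chain rule from
  analytic derivatives of the per-observation log density in f (verified
  symbolically) and central finite differences of f in η (step 10⁻⁴, one
  batched kernel call per iteration for the full stencil including cross
  terms). Where the exact Hessian is not positive definite the
  Gauss-Newton curvature (always PD) substitutes, both for the step and,
  at a non-PD putative mode, for the Laplace determinant. Steps are
  clipped to an infinity-norm of 2 per iteration and η to ±40;
  backtracking halves rejected steps. Convergence at gradient
  infinity-norm < 10⁻⁸. Each subject warm-starts from its cached mode
  (or η = 0 if that is better), which makes the outer objective smooth
  and cheap: near convergence a full objective evaluation costs about
  four kernel calls.
- With all ω² = 0 the objective reduces exactly to the fixed-effects
  likelihood. A test checks the Laplace value against an independent
  one-dimensional mode search + second-difference curvature at 10⁻⁶, and
  against exact quadrature at the few-percent level the approximation
  warrants.
- Outer problem: L-BFGS-B on log-transformed typical values, variances
  and error SDs (positivity by construction; covariate exponents are
  unconstrained), finite-difference gradients, with up to five restarts —
  a restart resets the quasi-Newton memory and reliably escapes stalled
  line searches; iteration stops when a restart improves the objective by
  less than 10⁻³. Default initial estimates are crude dose/AUC-style
  heuristics computed from the data, not the generating values.
- Standard errors come from the central finite-difference Hessian of the
  −2LL objective (cov = 2·H⁻¹), delta-method-transformed back from the
  log scale; CV% = 100·SE/estimate. Shrinkage is 1 − SD(η̂)/ω in percent.
  AIC = −2LL + 2p and BIC = −2LL + p·log(n_obs) hold by definition.

## Covariate selection, bootstrap, pcVPC

Stepwise covariate modelling adds, each forward round, the candidate with
the largest OFV drop above 3.84 (ties: fewest added parameters, then
lexicographic), then removes backward any covariate whose deletion costs
at most 6.63. The default candidate map screens the continuous
covariates on CL and V2 (power form) and sex on CL (exponential form);
candidates missing for any subject are skipped with a warning. Null
calibration of the forward step against the nominal χ²₁ rate, and its
power to recover a true CrCL effect at n = 100, are exercised in the
validation suite.

The bootstrap resamples subjects with replacement, refits from the point
estimates, and reports medians with 2.5/97.5 percentile intervals; failed
replicates are counted and excluded, and more than 50% failures aborts.
A `resampler` hook lets callers force specific index draws (the identity
resample is used as a test fixture).

The prediction-corrected VPC bins observations by time after the most
recent dose (quantile bins, sparse bins merged below 3 observations),
scales observed and simulated values by bin-median population prediction
over point population prediction, and overlays observed 5th/50th/95th
percentiles on their 80% simulation intervals.

## Synthetic-study generator

The generator emulates the study design the analysis targets: ~20
critically ill adults; CrCL 6.5–193.8 ml/min and ALT 7–495 U/L (split
log-uniform: half the mass log-uniform on each side of the cohort median,
pinning the sample median at 48.8 ml/min / 37.5 U/L while covering the
full skewed range); weight 45–65 kg, age 18–92 y, 40% female; daily doses
of 1.0/1.5/2.0 MU (10/70/20%) as 2–3 infusions of 1–2 h with a 1.0 MU
loading dose in ~20% of patients; plasma samples after 72 h of therapy
split trough/peak/random at the cohort's 38/27/33 observed counts
(troughs 5 min before a dose, peaks 5 min after an infusion ends — TDM
practice); a rich within-interval template (7 samples) in 6 patients and
sparse sampling (4) elsewhere, which makes the default 20-patient study
yield exactly 98 samples; and a single 12-h urine collection in 6
patients whose amount is generated as CL_R,true × model AUC with CL_R/CL
log-uniform over 2–32%. Outcome labels are assigned to a 16-of-20-style
evaluable subset through a logistic link on fAUC/MIC. The generating
parameters default to the final-model estimates, and the hidden truth
(per-patient η, realized parameters, CL_R, MIC) is returned separately.

What the generator does **not** emulate: continuous renal replacement
therapy, time-varying covariates or renal function, correlated assay
error, inter-occasion variability, and the co-medication structure of the
cohort. Passing tests therefore demonstrate the pipeline's correctness
and calibration under the stated design, not robustness to those
real-data features.

An enriched design (the parameter-recovery protocol) puts 200 virtual
patients on 0.75 MU q12h (2-h infusions, 6 doses over 72 h) with 8
samples across the 60–72 h interval, including 0.5–3.5 h post-infusion
points so the distribution phase identifies V2 and CL2; covariates are
log-uniform across the cohort ranges. Problem sizes in the validation
suite (200×8 for recovery over 10 seeds; 50 subjects for the AIC
direction check; 100/40 subjects for SCM power/null calibration) were
chosen as the smallest designs at which the corresponding property is
statistically clean.

## Dosing simulation

The Monte Carlo dosing study evaluates 12 regimens ({no load, 1.0, 1.5 MU
load} × {0.5 MU q12h, 0.5 MU q8h, 0.75 MU q12h, 1.0 MU q12h}, 2-h
infusions) across CrCL ∈ {10, 50, 80, 120} ml/min and MIC ∈
{0.5, 1, 2} mg/L with 1000 replicates. Choices:

- One set of (ηV, ηCL) replicates is shared by every grid cell (common
  random numbers), so dose/renal-function/MIC contrasts are exact per
  replicate and the attainment surfaces are monotone by construction.
- Exposure is the noise-free model quantity: residual (assay) error is
  not added, since fAUC/MIC and Css,avg are model summaries, not
  observations.
- The daily AUC is AUC(0–24) on day 1 and AUC(48–72) on day 3; Css
  metrics are evaluated on the dosing interval ending at 72 h (pre-dose
  minimum, end-of-infusion maximum, interval AUC/τ). Because the terminal
  half-life of the typical subject is ~48 h, day-3 exposure is still
  short of steady state; the infinite-time value (daily dose / 24·CL) is
  exposed separately (`css_avg_ss`), and large-replicate attainment on it
  converges to the closed-form log-normal tail probability, which the
  suite checks against the normal CDF.
- ALT is fixed at 37 U/L: V2 does not affect steady-state AUC, only the
  transient day-1 metrics, where this is an explicit assumption.
- Parameter uncertainty is not resampled — only inter-individual
  variability is, reflecting replicate-level simulation from fixed final
  estimates.

## Renal excretion

Renal clearance is non-compartmental: amount recovered in urine divided
by the plasma AUC over the collection window, with the AUC taken as the
linear trapezoid over observed quantifiable samples (window edges
interpolated; a window not covered by sampling within 1.5 h raises an
error naming the gap). A model-based AUC can be substituted for
sensitivity analysis. The dose attributed to a window prorates each dose
by the overlap of its dosing interval with the window, which reduces to
"the one dose given at the interval start" for an aligned 12-h
collection. Urinary recovery is amount/dose in percent; the renal
fraction is CL_R/CL in percent, with values above 100% returned with a
warning rather than rejected (they indicate inconsistent inputs, not a
programming error). With 13 samples per 12-h interval the trapezoid
recovers a known CL_R within 2%.

## Exposure–outcome analysis

ROC curves and areas are computed with scikit-learn; the area equals the
Mann–Whitney statistic over (positive, negative) pairs with ties counted
half, which the suite verifies exhaustively on small inputs. Group
contrasts of exposure metrics between valid and invalid outcomes use the
two-sided Mann–Whitney test (the comparison's test statistic was an open
choice; a rank test matches the skewed, small-sample setting). Patients
on empirical therapy (no causative-pathogen MIC) are excluded from
AUC/MIC-based analyses only.

## Known limitations

- The Laplace objective is an approximation; its small-sample bias is
  visible as a few-percent offset against exact quadrature on toy cases
  and is part of why variance parameters carry wider validation bands
  (25%) than fixed effects (10%).
- Samples below the quantification limit (0.034 mg/L colistin A +
  0.059 mg/L colistin B summed) are flagged and excluded from fitting
  with a logged warning; a censored-likelihood (M3-style) treatment is
  out of scope.
- Observed attainment tables published for this drug exceed what the
  final model's own steady-state tail admits in several cells, so the
  dosing-simulation outputs are validated by their internal properties
  (monotonicity, loading-dose dominance, analytic-tail convergence)
  rather than against any external table.
- One- and two-compartment structures only; no nonlinear elimination, no
  Ω off-diagonals, no inter-occasion variability, no CRRT terms.
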