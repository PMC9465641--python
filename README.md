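# colipk

Population pharmacokinetics of intravenous colistin sulfate in critically
ill patients: a tested, reusable pipeline covering the full analysis chain
— two-compartment covariate modelling, nonlinear mixed-effects estimation,
stepwise covariate selection, bootstrap and visual-predictive-check
diagnostics, urinary-excretion analysis, Monte Carlo dose optimization and
exposure–outcome ROC analysis — driven by a synthetic-study generator so
that every stage can be exercised and validated without patient data.

It is intended for pharmacometricians and infectious-disease researchers
who want to reproduce, probe or extend dose-optimization conclusions for
colistin sulfate (the active sulfate salt of polymyxin E, dosed in million
units; 10,000 IU = 0.44 mg).

## The model

Disposition is linear and two-compartmental (central volume `V`,
peripheral volume `V2`, clearance `CL`, inter-compartmental clearance
`CL2`) with zero-order infusion input, evaluated in closed form through
the macro-exponential constants. The covariate model ties clearance to
renal function and the peripheral volume to liver function:

```
V   (L)   = tvV  · exp(ηV)
V2  (L)   = tvV2 · (ALT / 37)^dV2dALT
CL  (L/h) = tvCL · (CrCL / 57.5)^dCLdCrCL · exp(ηCL)
CL2 (L/h) = tvCL2
```

with log-normal inter-individual variability `η ~ N(0, ω²)` on `V` and
`CL` and proportional residual error `y = f·(1 + ε)`, `ε ~ N(0, σ²)`.
The population likelihood integrates the random effects by a Laplace
(FOCE-class) approximation around each subject's empirical-Bayes mode;
covariate selection uses forward inclusion at ΔOFV > 3.84 and backward
elimination at ΔOFV > 6.63 (χ²₁ at p = 0.05 / 0.01).

Dose optimization simulates inter-individual variability for each regimen
× renal-function × MIC cell and reports the probability of attaining
fAUC/MIC ≥ 20 (unbound fraction f = 0.49, target PTA ≥ 90%) and of
average steady-state concentrations above 2 mg/L (efficacy) and 4 mg/L
(toxicity).

## Worked example

```python
import numpy as np
from colipk import (PopPKModel, StudyDesign, SimulationScenario,
                    final_model_spec, generate_study, run_scenario)

# a virtual 20-patient study with the cohort's design
records, truth = generate_study(StudyDesign(n_patients=20, seed=7))

# fit the final covariate model
model = PopPKModel(records, final_model_spec())
result = model.fit()
print(result.summary())

# dose-optimization grid from the fitted parameters
grid, css = run_scenario(result.population_params,
                         SimulationScenario(n_replicates=1000, seed=1))
print(css.table[css.table.crcl == 80.0].to_string(index=False))
```

prints

```
Population PK fit
==========================================================
subjects: 20   observations: 98   converged: True
-2LL: 99.14   AIC: 117.14   BIC: 140.40
----------------------------------------------------------
Parameter         Estimate       CV%   Shrink%
tvV                  14.08      9.55        NA
tvV2                 62.69      53.9        NA
tvCL                 1.887      17.6        NA
tvCL2                1.608      27.4        NA
dCLdCRCL            0.4303      28.3        NA
dV2dALT             0.5312      31.9        NA
omega2_V            0.0699      80.1      30.5
omega2_CL           0.1633      55.3      2.88
sigma_prop          0.2036      9.27        NA
            regimen  crcl  prob_over_2  prob_over_4
         0.5MU q12h  80.0          0.0          0.0
          0.5MU q8h  80.0          2.1          0.0
        0.75MU q12h  80.0          2.1          0.0
           1MU q12h  80.0         21.7          0.0
   1MU + 0.5MU q12h  80.0          0.0          0.0
    1MU + 0.5MU q8h  80.0          3.6          0.0
  1MU + 0.75MU q12h  80.0          2.7          0.0
     1MU + 1MU q12h  80.0         21.7          0.0
 1.5MU + 0.5MU q12h  80.0          0.0          0.0
  1.5MU + 0.5MU q8h  80.0          5.2          0.0
1.5MU + 0.75MU q12h  80.0          3.9          0.0
   1.5MU + 1MU q12h  80.0         23.6          0.0
```

The summary table is the fitted population model: typical values, the
covariate exponents, the inter-individual variances with their
empirical-Bayes shrinkage, and the proportional residual SD, each with a
relative standard error (CV%). On this 20-patient replicate the estimates
scatter around the generating values, as expected at the cohort's sample
size. The attainment table shows, for patients with creatinine clearance
80 ml/min, the probability that the day-3 average concentration exceeds
the 2 mg/L efficacy and 4 mg/L toxicity references: at normal renal
function none of the label-range regimens reaches high efficacy-target
attainment, the motivation for renal-function-guided dosing.

A command-line interface exposes the same stages
(`colipk generate | fit | scm | bootstrap | vpc | renal | pta | roc`); each
run writes its outputs plus a JSON manifest recording inputs and seed.

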