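# acetapop

Population pharmacodynamics of serum bicarbonate response to acetazolamide
in mechanically ventilated COPD patients.

Acetazolamide (ACET) is given to ventilated COPD patients during weaning to
correct metabolic alkalosis, which depresses ventilatory drive.  How much
the serum bicarbonate (HCO₃⁻) actually falls depends on the dose *and* on
the patient: illness severity, serum chloride and co-prescribed drugs all
modulate the response.  `acetapop` implements the population
pharmacodynamic analysis of that response for pharmacometricians and
intensivists who want to simulate, refit or stress-test the model:

- **Structural model** — one-compartment ACET kinetics (iv bolus, half-life
  fixed at 0.25 day) driving an indirect-response turnover model in which
  the drug stimulates bicarbonate elimination:

  dB/dt = k_in − E(t)·k_out·B,  E(t) = 1 + Emax·A(t)/(A(t)+A50),
  Bicar₀ = k_in/k_out

- **Covariate submodel** — Bicar₀ scales with (SAPS II/50)^β₁,
  (chloride/100)^β₂ and a glucocorticoid multiplier; furosemide attenuates
  k_out through an Imax term with potency Fur₅₀.  Log-normal
  between-subject variability on Bicar₀ and k_out; proportional residual
  error.
- **Estimation** — nonlinear mixed-effects maximum likelihood (adaptive
  Gauss–Hermite / Laplace), standard errors from the observed information,
  AIC/BIC, likelihood-ratio covariate scan, η shrinkage.
- **Diagnostics** — normalized prediction distribution errors (NPDE) from
  500 Monte-Carlo replicates with a decorrelation step, plus mean/variance/
  normality calibration tests and goodness-of-fit predictions.
- **Synthetic studies** — a generator that emulates the original study
  design (68 patients, ~3 samples each within 24 h of a dose, realistic
  covariate distributions) for recovery experiments, in NONMEM-like CSV.
- **Dosing simulation** — typical-subject trajectories for dose menus ×
  covariate scenarios and 24-h dose–response tables.

See `docs/methods.md` for the model, the numerical methods and their
assumptions.

## Worked example

Simulate a study under the published final-model estimates and refit it:

```python
import numpy as np
from acetapop import (PopulationParameters, StudyDesign, generate_study,
                      BicarbonateTurnoverModel)

truth = PopulationParameters()          # published estimates as truth
ds = generate_study(StudyDesign(n_subjects=500), truth,
                    np.random.default_rng(20210914))
results = BicarbonateTurnoverModel(ds).fit()
print(results.summary())
```

```
Population pharmacodynamic model of bicarbonate response
  subjects: 500   observations: 1586
  log-likelihood: -3783.55   AIC: 7587.1   BIC: 7640.8
  converged: True

Parameter                             Estimate    (%rse)
Half-life, day                            0.25   (fixed)
Bicar0, mmol/L                           35.28       (1)
  x SAPS II effect (SAPS II/50)^b      -0.1091      (15)
  x corticosteroid effect                1.081       (1)
  x chloride effect (Cl/100)^b          -1.302       (6)
kout, 1/day                             0.4093       (6)
Fur50, mg/day                            147.9      (22)
A50, mg                                  115.7       (4)
Emax                                         1   (fixed)
Residual (proportional SD)             0.03812       (3)

BSV (SD of log eta)                   Estimate    (%rse)   [shrinkage]
omega Bicar0                            0.1027       (4)        [0.05]
omega kout                              0.7837       (4)        [0.19]
```

The fit recovers the generating values: a typical baseline of ~35.3 mmol/L
(truth 35.5), an elimination rate of ~0.41/day (truth 0.395) and a
half-maximal ACET amount A50 of ~116 mg (truth 117), with the covariate
exponents and variance components inside their sampling uncertainty.
Fur₅₀ is the loosest parameter (22 %rse) because simulated furosemide
doses lie well below it.

Model checking and dosing questions hang off the same objects:

```python
npde = results.compute_npde(K=500, rng=np.random.default_rng(1))
print(npde.p_mean, npde.p_variance, npde.p_normality)  # ~U(0,1) if correct

from acetapop import dose_response_24h
print(dose_response_24h(truth, [125, 250, 500, 1000]))
#     dose  delta_24h
#    125.0  -2.482
#    250.0  -3.768
#    500.0  -5.206
#   1000.0  -6.587        (mmol/L change 24 h after a single bolus)
```

Only the 500 mg-and-above boluses clear a 5 mmol/L decrease within 24
hours at reference covariates, and high chloride or furosemide blunt the
response further — the quantitative form of the dosing guidance the model
supports.

## Command line

```bash
acetapop simulate --n 68 --seed 7 --out data.csv
acetapop fit --data data.csv --out fit.json
acetapop npde --data data.csv --K 500 --seed 3 --out npde.csv
acetapop scenarios --out scenarios.csv --summary-out summary.csv
```

Every output gets a `.meta.json` sidecar recording the seed and the full
parameter set used.

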