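# Methods

## The model

`acetapop` models the serum-bicarbonate response of invasively ventilated
COPD patients to acetazolamide (ACET), a carbonic-anhydrase inhibitor given
during weaning to correct metabolic alkalosis.

**Kinetics.** The drug amount in the body A(t) (mg) follows a
one-compartment model with first-order elimination,
dA/dt = −k_elim·A, with boluses superposed at the dose times.  The
elimination half-life is fixed at 0.25 day (six hours), so
k_elim = ln 2 / 0.25 ≈ 2.77 day⁻¹.  A first-order absorption (Bateman)
variant is available for enteral dosing, but because ACET bioavailability
is excellent the iv-bolus model is used for all subjects by default; the
degenerate case k_a = k_elim is handled by the analytic t·e^(−kt) limit
rather than an error.  Amounts stay in mg — no volume of distribution is
introduced, because the potency parameter A50 is itself expressed in mg of
dose.

**Dynamics.** Serum bicarbonate B(t) (mmol/L) follows an indirect-response
(turnover) model in which the drug stimulates the loss term:

    dB/dt = k_in − E(t)·k_out·B,      E(t) = 1 + Emax·A(t) / (A(t) + A50),

with baseline Bicar0 = k_in/k_out (subjects start at equilibrium).  Emax is
fixed at 1 (it is not jointly identifiable with A50 from bicarbonate data
at clinical doses), which bounds every trajectory in
[Bicar0/2, Bicar0] and caps the achievable decrease at half the baseline.

**Covariates and variability.** Individual parameters are

    Bicar0_i = TV(Bicar0)·(SAPSII_i/50)^β_saps·(Cl_i/100)^β_cl·θ_cort^[steroids]·e^(η1_i)
    kout_i   = TV(kout)·(1 − Furo_i/(Furo_i + Fur50))·e^(η2_i)

with η ~ N(0, ω²) (log-normal between-subject variability, diagonal Ω — two
ω values are reported, no correlation is modelled) and proportional
residual error y = f·(1 + ε), ε ~ N(0, σ²).  σ = 0.04 is interpreted as the
SD of the proportional term (4 % CV); reading it as a variance would imply a
20 % CV, inconsistent with the precision of the data the model describes.
The covariate exponents default to the estimate-precision values (−0.112,
−1.18) rather than their two-digit roundings.  Subjects without furosemide
have dose 0, which leaves k_out unchanged by construction.

Default parameter values (the published final-model estimates, used as
simulation truth everywhere):

| parameter | value | units |
|---|---|---|
| TV(Bicar0) | 35.5 | mmol/L |
| β_saps | −0.112 | – |
| β_chloride | −1.18 | – |
| θ_cort | 1.092 | – |
| TV(kout) | 0.395 | day⁻¹ |
| Fur50 | 187 | mg/day |
| A50 | 117 | mg |
| Emax | 1 (fixed) | – |
| half-life | 0.25 (fixed) | day |
| ω(Bicar0), ω(kout) | 0.101, 0.792 | log-scale SD |
| σ (proportional) | 0.04 | – |

## Trajectory computation

Because the turnover ODE is linear and non-autonomous, three routes exist:

1. `solve_bicarbonate` — LSODA with rtol 1e−10 and the dose times inserted
   as integration breakpoints (A(t) is discontinuous at boluses).
2. `oracle_bicarbonate` — the integrating-factor solution
   B(t) = e^(−kout·H(t))·(Bicar0 + k_in ∫₀ᵗ e^(kout·H(s)) ds) with
   H(t) = ∫₀ᵗ E(s) ds computed in closed form piecewise between doses
   (∫ A/(A+A50) dt has an analytic antiderivative for exponentially
   decaying A) and the outer integral by adaptive quadrature.  This is the
   independent verification oracle.
3. `_engine.ProfileEngine` — the same integrating-factor form with a fixed
   composite 10-node Gauss–Legendre rule per inter-dose segment, fully
   vectorised over subjects and parameter draws.  B is linear in Bicar0 and
   analytic in kout, so the engine also returns exact first and second
   derivatives with respect to kout.  This route backs the likelihood and
   all Monte-Carlo simulation; the test suite requires 1e−6 mmol/L
   three-way agreement on randomized regimens.

## Estimation

The marginal likelihood integrates the two η's per subject against their
normal prior.  Per subject and candidate θ:

1. **Grid scan.** h(η) = conditional log-likelihood + log prior is scanned
   on a fixed 25×9 grid spanning ±4.5 prior SDs.  The surface can be
   multimodal in η_kout with one to six observations, and a history-free
   scan makes the likelihood a *pure function of θ* — essential because the
   outer optimiser differentiates it by finite differences.
2. **Newton polish.** Damped Newton (analytic gradient and Hessian,
   backtracking, step-norm cap) from the grid argmax to gradient
   tolerance 1e−8.
3. **Adaptive Gauss–Hermite.** The quadrature grid is centred at the mode
   and scaled by the Cholesky factor of the inverse negative Hessian,
   ordered so that η_kout varies only with the outer node index; the
   expensive kout-dependent trajectory factor is then computed once per
   outer node and reused across the inner (Bicar0) nodes, which enter
   linearly.  One node per dimension reproduces the Laplace approximation
   exactly.  Curvatures are floored at a quarter of the prior precision so
   a flat or saddle Hessian still yields a usable quadrature scale.

Defaults: 5 nodes/dimension during optimisation (speed), 20 in
`log_marginal_likelihood` (accuracy; agrees with brute-force 2-D Simpson
integration to better than 1e−4 on 3-subject instances).  Fixed effects,
ω's and σ are maximised jointly with L-BFGS-B under a log transform for the
positive parameters (exponents untransformed), Emax and k_elim held fixed.
Standard errors come from the central-difference observed information at
the optimum (relative step 1e−3); AIC = −2LL + 2p and BIC = −2LL + p·ln n
with n = number of observations (a deliberate convention choice — reference
software differs here).  Initial values are data-driven and scale-free:
mean pre-dose observation for TV(Bicar0), 0.5/day for TV(kout), half the
median administered dose for A50, 0.1 for ω and σ, null values for the
covariate effects.  The optimiser never returns a point worse than its
start (enforced).  Shrinkage is 1 − sd(η̂)/ω with η̂ the conditional modes.

A stochastic-EM (SAEM-type) algorithm is *not* implemented: the estimator
contract here is the marginal likelihood itself, checked against
brute-force integration, plus the parameter-recovery experiments; `laplace`
and `agh` are the available `FitSettings.algorithm` values.

## Synthetic study generator

`generate_study` emulates the design of the source study (68 patients, 207
observations): 250 or 500 mg per administration (one amount per subject,
equiprobable), twice daily for 3 days; one pre-dose observation of the
equilibrium baseline at t = 0 plus further samples drawn up to 24 h after a
randomly chosen dose; the per-subject observation count is drawn from
(0.12, 0.22, 0.28, 0.18, 0.12, 0.08) on {1..6} (median 3, range 1–6).
Covariate distributions are matched to the published population summaries —
only medians and ranges are available, so the shapes are modelling choices,
fixed once:

- SAPS II: log-normal, median 47, log-SD 0.30, truncated to [20, 95];
- chloride: normal, mean 96, SD 7 mmol/L, truncated to [69, 108]
  (SD ≈ printed range / 4.7, the expected normal range at n = 68);
- glucocorticoids: Bernoulli(0.147); furosemide: Bernoulli(0.471) with dose
  Uniform(20, 160) mg/day.

Treatment duration (3 days) follows the reported 72-hour reversal horizon
of alkalosis treatment.  The generator emulates neither dropout nor
missing-data mechanisms, and real ICU covariates are correlated in ways
these independent draws are not; passing recovery tests therefore
demonstrates correctness of the estimation machinery under the stated
model, not robustness to real-data violations of it.  Generated datasets
carry the realized individual parameters as provenance columns for
recovery experiments.

## Diagnostics

NPDE uses K = 500 Monte-Carlo replicates of each subject's observation
vector at the observed design.  Observed and simulated vectors are
decorrelated with the simulation mean and the *symmetric* square-root of
the simulation covariance (eigendecomposition; Cholesky would be an
acceptable alternative — the symmetric root is used because it treats the
observation ordering symmetrically); near-singular covariances are
ridge-stabilized with a warning.  The NPDE is Φ⁻¹ of the mid-ranked
proportion of decorrelated simulations below the decorrelated observation,
with probabilities clipped to [1/(2K), 1 − 1/(2K)] to keep the quantiles
finite at extreme ranks.  Calibration tests: Wilcoxon signed-rank for mean
zero; a two-sided χ² test of the sample variance against 1 on n−1 df (the
"variance test" is underspecified in the field; the χ² form is the
single-sample analogue of an F test against a known variance);
Shapiro–Wilk for normality.

## Dosing simulation

Scenario trajectories are deterministic typical-subject simulations (zero
η, no residual noise) on an hourly grid, default horizon 5 days.  The
24-hour dose–response table administers each total daily dose as a single
bolus at t = 0 and reports B(24 h) − baseline.  The headline report
evaluates, per covariate scenario, which menu dose achieves a > 5 mmol/L
decrease within the horizon; "high" and "low" chloride default to the
population extremes (108 and 69 mmol/L) since no canonical values exist,
and the corticosteroid scenario toggles only the baseline multiplier (the
model's single steroid pathway).  Note that over a multi-day horizon at
kout ≈ 0.4/day even small sustained doses eventually produce large
decreases; the dose menu discriminates most clearly at 24–48 h horizons.

## Problem sizes and numerical choices

The package's own verification experiments use: 500 subjects for the
parameter-recovery study (the headline experiment of
`scripts/acceptance.py`); 200 subjects × K = 500 for the NPDE calibration
check plus 200 replicate studies of 20 subjects at K = 300 for the
test-level calibration; 20 replicate studies of 60 subjects for the
chloride-retention power check; brute-force likelihood grids of 201×201
Simpson points spanning ±6 prior SDs.  These sizes were chosen so each
experiment's Monte-Carlo error is small relative to the tolerance it
checks.  The recovery experiment's sampling SDs at n = 500 (from the
observed information) are roughly 0.6 % for TV(Bicar0), 6 % for the
chloride exponent, 15 % for the SAPS II exponent and 22 % for Fur50 —
Fur50 is weakly identified because the simulated furosemide doses
(20–160 mg/day) sit well below it, so its recovered value scatters more
than the other fixed effects.

## Known limitations

- No renal/CSF/red-cell physiology, pH or PaCO₂ modelling; bicarbonate is
  the sole response.
- Covariates outside the final model (protein, creatinine, potassium,
  weight, ventilation mode, β₂-agonists, fluid load) have no effect
  pathway.
- The ω's are diagonal; an η correlation, if present, is absorbed into the
  marginal ω's.
- The likelihood treats the pre-dose sample as an observation of the
  equilibrium baseline; designs violating the steady-state assumption at
  t = 0 are outside the model.
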