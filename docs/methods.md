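# Methods

## Scope

`prucapop` re-creates a pediatric population-pharmacokinetic analysis of
prucalopride, a 5-HT₄ agonist dosed orally once daily for functional
constipation, as a reusable, fully seeded pipeline.  Because the underlying
clinical datasets are not public, the package pairs the model with a
synthetic-trial generator that emulates the two study designs the analysis
rests on; every statistical claim the package makes is demonstrated on data
it can generate itself.

## Structural model

Plasma kinetics follow a two-compartment disposition model with first-order
oral absorption from a depot, parameterised by clearance CL (L/h), central
and peripheral volumes V2 and V3 (L), intercompartmental clearance Q (L/h),
and a *switched* dual absorption: the depot drains at rate Ka1 = 0.792 h⁻¹
until MTIME = 0.734 h after each dose and at Ka2 = 3.87 h⁻¹ afterwards, with
relative bioavailability F1 = 0.858.  Absorption parameters and F1 are fixed
quantities carried over from the adult model of the same drug and are never
estimated here.

The model is linear, so the implementation is the exact closed form: the
standard three-exponential depot solution on each absorption phase, joined at
the switch by propagating the depot/central/peripheral state, and superposed
over doses.  An alternative would be numerical integration with a breakpoint
at the switch; the closed form was chosen as the implementation because
population estimation evaluates the model ~10⁵ times per fit and the analytic
solution is both exact and orders of magnitude faster.  The stiff-ODE
integration (LSODA, rtol 1e-11) is retained in the test suite as the
independent oracle; the two agree to ~1e-10 relative.

The MTIME switch is applied per dose (time after *that* dose), since the
cutoff was estimated from single-dose adult data; whether the original
software applied it per dose or only to the first dose of a regimen is not
documented, and this choice is flagged rather than asserted.  There is no
absorption lag time: the pediatric parameter set contains none.

Units are canonical throughout: µg for amounts, L for volumes, h for time, so
central concentration (amount/V2) is µg/L ≡ ng/mL and the steady-state
identity AUC_τ = F1·Dose/CL lands directly in ng·h/mL.

Steady state is obtained by stacking successive doses until the trough
changes by < 0.01% between intervals (cap 50 doses) rather than by analytic
accumulation formulas, keeping the switched-absorption code on a single path.
Default profile grid 0.05 h.

## Covariate model

Individual parameters derive from 70 kg reference values by fixed-exponent
allometry — power 0.75 for CL and Q, power 1 for V2 and V3 — and, for
elimination clearance only, a renal maturation factor

    Maturation_GFR(PMA) = PMA^3.4 / (47.7^3.4 + PMA^3.4)

with postmenstrual age PMA = postnatal age + 40 weeks of gestation (weeks).
The curve exceeds 0.975 at a postnatal age of 24 months, and renal function
is treated as fully mature (factor exactly 1) beyond that age; the ≤ 2.3%
step at the boundary is deliberate, documented, and tested as bounded.
Q is treated as a distributional, non-renal parameter and is not maturated.

Creatinine clearance, CrCL = 42.5·Height/SCr·(WT/70)^0.7 (mL/min, height in
cm, serum creatinine in µmol/L), is computed and carried as a descriptive
covariate but does not enter the parameter model — renal function acts only
through the maturation term, and no covariate search is performed.  The
year→week conversion uses 365.25/7.  Missing covariates are imputed with
study medians for determinism.

Between-subject variability is log-normal (exponential η) on CL, V2, and V3,
with the CL variance study-specific; residual error is additive on
log-transformed concentrations (σ per study), so σ is numerically a CV for
small values.

## Synthetic trial designs

Two arms are emulated:

* **Rich arm** (phase-1-like): 38 children 4–12 y, a single oral-solution
  dose of 0.03 mg/kg, 13 scheduled samples at 0.5–72 h, assay LLOQ
  0.1 ng/mL, residual log-SD 0.14.
* **Sparse arm** (phase-3-like): 107 children 1.7–18 y, 0.04 mg/kg once
  daily capped at 2 mg; at week 4 a configurable fraction is adjusted to
  0.06 mg/kg (default 0.30) or 0.02 mg/kg (default 0.05), re-capped.  One
  sample 1–3 h after the first dose plus 14–26 h troughs at weeks 8 and 24;
  LLOQ 0.2 ng/mL, residual log-SD 0.35.

Trough visits are modelled as the next daily dose being withheld until after
the blood draw, so the elapsed time since the last actual dose is the sampled
14–26 h window.  By the week-8 visit a subject has been on the adjusted dose
for four weeks (≈ 23 terminal half-lives), so troughs are at steady state on
the current dose.

Demographics come from a growth model: piecewise-linear median weight- and
height-for-age anchored at twelve ages, log-normal weight scatter (SD 0.18),
height co-varying with relative weight through a power-0.3 rule, and serum
creatinine linear in age (20 + 2.2·age µmol/L with small Gaussian noise).
Weights are clipped to each study's observed envelope (15–61 kg rich,
11–110 kg sparse).  Sparse-arm ages are drawn Beta(1.2, 1.8) over the range
so the age distribution is right-skewed with median ≈ 8 y, matching the
reported demographics; a uniform draw would overshoot the weight median by
~30%.  These are simulator conveniences, not claims about the trial
populations: the generator reproduces medians, ranges, and the age-weight
coupling, but not family/clinic-level clustering, longitudinal growth within
the 24-week study, dropout, or adherence dynamics — so passing tests
demonstrate correctness of the machinery under the stated design, not
transportability to any particular real cohort.

Because the IIV magnitudes are not published, the defaults are stated
assumptions: ω_CL 0.30 (rich) and 0.60 (sparse) — the sparse study shows a
far wider post hoc clearance spread — ω_V2 0.40, ω_V3 0.50, absorption IIV
switchable but off.  With these values, natural below-LLOQ censoring alone
produces under 2% of sparse observations; the observed exclusion pattern
(~10% below-limit plus missing dose/time information, and one of 107 subjects
losing every record) is therefore injected as configurable *exclusion
artifacts* representing outpatient non-compliance and assay loss.  Artifact
injection is seed-stable and never removes a non-designated subject's last
usable observation, so exactly one subject drops out when requested.

## Data preparation

Filtering is the plain exclusion (M1) rule: observation rows flagged
below-LLOQ (or below a supplied limit), missing-time, missing-dose-info, or
not-analyzed are removed; rows matching several rules are counted once, in
that priority order.  Retained values are never altered, order is preserved,
and the filter is idempotent.  Subjects with no remaining observations leave
the analysis population.  On the packaged count fixtures this reproduces the
published bookkeeping exactly: 481 of 494 records retained from 38/38
subjects in the rich arm, and 244 of 291 from 106/107 in the sparse arm
(25 below-limit + 1 not-analyzed + 21 missing-dose exclusions).

## Estimation

The population objective is the FOCE-with-interaction approximation to the
−2 log marginal likelihood.  Per subject, the conditional mode η̂ of the
random effects (the empirical Bayes estimate) is found by Levenberg-damped
Gauss-Newton on the penalized log-scale least squares (gradient tolerance
1e-6, η restarted at 0 for every objective evaluation so the objective is a
deterministic function of the population parameters), with a quasi-Newton
fallback for large-residual subjects where pure Gauss-Newton cycles.  The
Laplace curvature uses the first-order linearization G = ∂f/∂η at η̂ (central
differences, relative step 1e-4); with an additive-on-log error model the
residual variance does not depend on η, so evaluating at the mode carries the
interaction term exactly.  The per-subject contribution is

    n log(2πσ²) + ‖y − f(η̂)‖²/σ² + η̂ᵀΩ⁻¹η̂ + log det Ω
      + log det(GᵀG/σ² + Ω⁻¹).

On toy problems this agrees with 64-node adaptive Gauss-Hermite quadrature of
the exact marginal likelihood to well under 0.1 units.

For speed, the inner problems of all subjects are solved simultaneously: one
batched closed-form evaluation covers every subject and every η-perturbation,
after which the 3×3 Gauss-Newton updates are applied per subject.  Dose
geometry, amounts, and the before/after-switch split are precomputed per
dataset; only rate constants change between evaluations.  Contributions of
doses more than 30 doses before an observation are dropped (≈ 10⁻⁵ relative
at the terminal half-life of ~29 h).

The outer problem estimates per-study CL, shared V2/Q/V3, per-study ω_CL,
ω_V2, ω_V3, and per-study σ, all log-transformed (positive by construction),
with absorption and F1 always fixed; Ω is diagonal.  A quasi-Newton stage
(L-BFGS-B, finite-difference gradients, step 1e-5) is followed by a
derivative-free Nelder-Mead polish (default budget 300 evaluations).
Standard errors come from the inverse of a central finite-difference Hessian
of the objective (step 1e-3 on the log scale), mapped to the natural scale by
the delta method; relative SE is 100·SE/estimate and the 95% interval is
estimate ± 1.96·SE.  A non-positive-definite Hessian marks SEs unavailable
rather than failing the fit.

Shrinkage: η-shrinkage = (1 − SD(η̂)/ω)·100 per random effect, per study for
CL; ε-shrinkage = (1 − SD(IWRES))·100 with IWRES = (log DV − log IPRED)/σ.
Post hoc exposure per subject uses the empirical-Bayes clearance:
AUC = F1·(current daily dose)/CL_i, Css = AUC/24, and the predose
concentration from the individual steady-state profile.

### Recovery performance

The packaged recovery experiment (38 rich + 107 sparse subjects simulated at
the final-model values, refit from neutral starting values) is what
`scripts/acceptance.py` runs; the suite asserts the medians over three seeds
recover the rich-arm clearance within 15%, the sparse-arm clearance and V2
within 20%, and the rich-arm residual SD within 20%.  One fit takes on the
order of 1–2 minutes on a single CPU at the default optimizer budgets; the
problem sizes mirror the original studies, so no scaling down is needed.

## Diagnostics

CWRES follow the same FOCE linearization as estimation: residuals of the
log-observations about the population linearization f(η̂) − Gη̂, whitened by
the Cholesky factor of GΩGᵀ + σ²I.  Under the generating model they are
standard normal to within Monte-Carlo error; a singular covariance excludes
the subject from the table with a report rather than failing.  Q-Q inputs are
a pure function of the residual table (normal scores via the (i−0.375)/(n+¼)
rule).

The visual predictive check keeps the observed trial exactly as designed —
same subjects, covariates, doses, and sampling times — and redraws only η and
ε from the fitted model, comparing observed 5/50/95th percentiles per bin
(nominal times for the rich arm; day-1 vs trough occasions for the sparse
arm) with the band of those percentiles across replicates.  Within one trial
the bins are strongly correlated (a cohort's clearance draws shift every time
point together), so calibration statements are made across replicate trials,
not bin-by-bin within one.

## Dose-exposure bridging

Typical (η = 0) profiles are simulated on an age grid at 0.02/0.04/0.06 mg/kg
once daily, capped at 2 mg, using the sparse-study clearance and the
median-for-age weight from the growth model.  The adult reference on 2 mg
once daily is anchored to the single published adult quantity: its clearance
is F1·2000 µg / 109.3 ng·h/mL ≈ 15.7 L/h, with the pediatric disposition
shape and solution absorption.  This surrogate matches the adult exposure
scale exactly and the profile shape only approximately — the true adult model
is unpublished — and is labelled an approximation wherever it appears.
Tablet-specific absorption at the 2 mg cap is ignored.  Exposure ratios
(child/adult AUC, Cmax, Css) are deterministic arithmetic; Monte-Carlo Cmax
envelopes for the adult use a 0.30 log-SD clearance IIV.

Uncapped, steady-state AUC at a fixed per-kg dose scales as weight^0.25
(F·d·WT / (CL_tv·(WT/70)^0.75)); the cap makes exposure decrease with weight
above the cap threshold.  Both are verified numerically.

## Numerical edge cases

* An absorption rate coinciding with a hybrid disposition constant would make
  the closed form 0/0; rates are nudged by 1e-9 relative, far below any
  tolerance used.
* Closed-form cancellation can leave ~1e-16-relative negative concentrations
  at t ≈ 0; outputs are clipped at zero.
* Datasets round-trip exactly through CSV (`%.17g` on write, round-trip float
  parsing on read).
* ω → 0 degenerates the objective continuously to the fixed-effects
  log-normal −2LL; subjects without observations contribute zero and sit at
  the prior mode.

## Known limitations

No inter-occasion variability, no covariance between random effects, no
likelihood-based handling of censored observations (exclusion only), no IV
route, no nonlinear elimination, no adult renal-decline term (no subjects
over 18), and no efficacy/PD linkage.  The estimator's random-effect vector
is fixed at (CL, V2, V3); absorption IIV exists only in the simulator and is
off by default.
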