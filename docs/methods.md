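# Methods

## The dosing problem

Cisplatin for head-and-neck cancer is given as a 3-hour intravenous
infusion of 75–100 mg/m² every ~21 days. With so short an infusion the
dose cannot be adjusted in real time, but two routine drug-monitoring
samples per course — a trough immediately before the infusion and a peak
(Cmax) immediately after it — are enough to identify a patient's
individual pharmacokinetic parameters against a population prior. Once a
target exposure window is known, the next course's dose can be computed in
closed form. `cisdose` implements that whole chain: individual PK
identification, exposure summarization, therapeutic-window search,
exposure-outcome model benchmarking, and dose individualization, plus a
virtual-patient generator so the chain can be validated end to end without
patient data.

## Disposition model (`pkcore`)

Plasma platinum follows linear three-compartment (tri-exponential)
kinetics. After a bolus of `dose` mg,

    C(t) = dose · (A e^(−αt) + B e^(−βt) + C e^(−γt)),

with macro-coefficients A, B, C in L⁻¹ (per mg of dose, so mg × L⁻¹ gives
mg/L ≡ µg/mL) and rates α > β > γ. A zero-order infusion of duration T and
multi-dose superposition have closed forms by linearity; no ODE solver is
used at run time (a stiff-ODE integration of the equivalent micro-constant
system serves as an independent oracle in the tests, agreeing to < 1e-6
relative over 0–504 h).

Reference population values (adult head-and-neck patients, rich
sampling): A = 0.008106, B = 0.008095, C = 0.006742 L⁻¹;
α = 0.5113, β = 0.07893, γ = 0.05439.

**Unit decision.** The source of these rate constants labels them per
day, but only a per-hour reading reproduces the cohort scales that
accompany them — clearance ≈ 4.2 L/h, AUC ≈ 42 µg·h/mL and Cmax ≈ 3.3
µg/mL for a 164 mg, 3-h infusion; the per-day reading is off by more than
an order of magnitude. `cisdose` therefore defaults to h⁻¹ and keeps a
`time_unit` field for the literal reading. A knock-on consequence to be
aware of: with γ in h⁻¹ the terminal half-life is ln2/γ ≈ 12.7 h, so the
model's day-21 trough is vanishingly small (~1e-12 µg/mL) — measured
troughs of ~0.2 µg/mL at day 21 are not reproducible under any parameter
reading consistent with the printed clearance. Synthetic day-21 troughs
consequently fall below the assay's quantification limit and exercise the
BLQ-handling path.

Macro→micro conversion follows the standard mammillary-model identities:
V1 = 1/(A+B+C); k21, k31 are the roots of x² − Sx + P with S and P the
dose-weighted symmetric functions of the rates; k10 = αβγ/(k21·k31); k12
and k13 solve the remaining trace/second-symmetric-function identities.
Rates closer than 1e-9 relative raise an explicit non-identifiability
error rather than silently ill-conditioning. Derived parameters:
CL = 1/Σ(Aᵢ/λᵢ), kel = k10, t½ = ln2/γ, AUC = dose/CL.

## Bayesian individual fit (`bayesfit`)

All six macro parameters are estimated on the log scale by minimizing

    J(θ) = Σⱼ wⱼ (C_obs,j − C_pred,j)² / (σ_prop·C_pred,j + σ_add)²
         + Σᵢ (log θᵢ − log θ_pop,i)² / ωᵢ²,

a penalized weighted least squares whose penalty is an independent
log-normal population prior. Defaults: ω = 0.3 on A, B, C (matching the
~31% clearance CV seen in adults) and 0.2 on the rates; residual model
σ_prop = 0.15 (the assay's validated precision bound) plus an additive
floor σ_add = 0.05 µg/mL (half the 0.1 µg/mL lower limit of
quantification). Observations below 0.1 µg/mL are imputed at LLOQ/2 and
down-weighted (w = 0.5), and are flagged in the fit.

Optimization is quasi-Newton (L-BFGS-B) from five starts — the prior mean
plus four seeded log-perturbations — with a 1e-8 objective tolerance;
rates are sorted into α > β > γ on exit (exact ties nudged by 1e-6
relative). Precision is the inverse curvature of J at the optimum
(finite-difference Hessian; covariance 2·H⁻¹, whose log-scale diagonal
square roots are natural-scale relative SEs). A fit is *accepted* when
every relative SE is below 15%. With only two samples per course the
weakly identified axes default to the prior width (0.2–0.3), so sparse-
data fits rarely clear that bar; the flag is reported and downstream
stages consume fits regardless, preferring measured concentrations where
they exist (TDM primacy).

On 200 virtual patients with two samples per course over three courses
and 15% assay noise, the median relative clearance error of the MAP
estimates is ~10%, and shrinkage makes their variance smaller than a
near-unpenalized fit's.

## Exposure and outcomes (`cohort`)

Per-course Cmax is the concentration at the infusion end (full
superposition, so residual drug counts), Cmin the concentration just
before the next infusion (a 21-day horizon for the last course), AUC is
dose/CL; the exposure metrics are means over the first min(3, available)
courses, with measured peaks/troughs overriding model values where
present. Nephrotoxicity uses the CTCAE creatinine rule — any value
strictly above baseline×1.5 **or** baseline+26 µmol/L — and severe
ototoxicity is consumed as a CTCAE grade ≥ 3 flag (no audiometric rule is
modelled). Clinical benefit = CR/PR/SD response AND neither severe
toxicity.

## Therapeutic window (`window`)

The window is the closed interval [lower, upper] of the exposure metric
(mean Cmax by default) maximizing the concordance count: patients inside
with benefit plus patients outside without it. Two searchers:

- `grid_search`: exhaustive over a regular grid spanning the data ± one
  step (default 0.1 µg/mL). Exact at its resolution; the reference
  oracle. Ties resolve to the widest window, then the lowest lower bound
  (the most permissive dosing target).
- `tpe_search`: a minimal tree-structured Parzen estimator over the
  continuous (lower, width) space with uniform priors. Design: 20 startup
  trials per run, always including the trivial all-inside and all-outside
  windows (so the result can never fall below either); good/bad split at
  the γ = 0.25 quantile applied hyperopt-style (good set =
  ceil(0.25·√n), capped at 25); per-coordinate adaptive Parzen mixtures
  with neighbour-spacing bandwidths plus one uniform prior component; 24
  candidates per iteration scored by the density ratio l/g; every fourth
  trial drawn from the prior (the concordance surface is piecewise
  constant, and purely exploitative samplers stall on its plateaus); the
  200-trial budget split over two independent runs.

On 80-patient cohorts the TPE result is on average within ~0.3 concordant
patients of the exhaustive grid (often better, since it is not limited to
the grid's resolution); in roughly 10–15% of cohorts it ends 2–4 patients
short — the near-optimal basin of a piecewise-constant count objective
can occupy well under 1% of the search area, which no 200-evaluation
continuous search finds reliably. Contingency tables (toxicity, efficacy,
benefit; inside vs outside) round percentages to the nearest integer.

## Model benchmarking (`mlbench`)

The harness itself — preprocessing, 70/30 response-stratified split,
5-fold cross-validated random hyperparameter search (20 configurations
per family), held-out scoring, permutation importance — is implemented
here; the eight classifier families are scikit-learn/xgboost estimators
behind one adapter: elastic-net logistic regression ("generalized linear
model", tuning λ and α), Gaussian naive Bayes (variance smoothing),
SGD logistic regression (step size), MLP (hidden layers/units), decision
tree (minimum leaf size), gradient-boosted trees (number of trees),
random forest (depth, trees, leaf size), XGBoost (learning rate, depth).
Deep learning is deliberately out of scope for cohorts of this size.
Numerics are min-max normalized with parameters learned on the training
partition only (constant columns map to 0); categoricals are one-hot
encoded. The positive class for recall/precision is clinical benefit;
precision with no positive predictions is reported as 0 with a flag.
Permutation importance shuffles one feature at a time in a copy of the
evaluation set (the fitted model is untouched), five seeded repeats,
reporting the mean and SD of the accuracy drop; it is computed on the
held-out test partition.

## Dose individualization (`dosing`)

By linearity, the next-course dose hitting a target end-of-infusion
concentration is D* = (target − C_res)/u(T), where C_res is the decayed
residual of all prior courses at the new peak time and u(T) the
individual per-mg end-of-infusion response. Default target: the window
midpoint (3.1 µg/mL for [2.1, 4.1]); default spacing 21 days, overridden
by actual administration times when known. If the residual alone exceeds
the target the proposal is infeasible (dose 0, flagged). No safety clamp
is applied by default; an optional cap reports both the capped and
uncapped values. Percentage changes round half away from zero. The
validation-style report tabulates simulated day-21 troughs against
measured troughs (paired t = mean(d)/(sd(d)/√n)) and proposed against
actual doses.

## Virtual cohort (`synth`)

Defaults emulate the study conditions: 80 patients; BSA ~ N(1.76, 0.19²)
truncated to [1.23, 2.16] m²; age N(58, 11²) in [15, 85]; 23:57 F:M;
doses of 75 or 100 mg/m² × BSA, three 3-h courses spaced
Uniform(20.2, 23) days; log-normal inter-individual variability with CV
0.30 on A, B, C and 0.20 on the rates; sampling = peak each course
(jittered ±5 min around the infusion end) and trough before each later
course, with 15% proportional + 0.05 µg/mL additive assay error,
truncated at zero.

Two structural choices matter:

- **Correlated coefficients.** 85% of the A/B/C log-variance is a shared
  deviate (each coefficient keeps its marginal CV of 0.30). The macro-
  coefficients all scale with 1/V1, so their variability is mostly a
  common volume effect; with fully independent deviates the cohort-level
  clearance and peak CVs come out near 21–24%, well below the ~31%
  observed clinically, while the shared factor reproduces CL CV ≈ 0.31
  and Cmax CV ≈ 0.34 at CL ≈ 4.2 L/h.
- **Invented outcome model.** No exposure-outcome law is available to
  copy, so the generator uses two opposed logistics in the mean Cmax:
  p_toxicity = expit(3·(Cmax − 4.1)) and p_efficacy =
  expit(3·(Cmax − 2.1)), making the benefit-maximizing window ≈
  [2.1, 4.1] µg/mL by construction. Severe toxicity splits 17:12 between
  nephro- and ototoxicity in expectation; creatinine series are generated
  consistent with the sampled nephrotoxicity label (a >50% rise injected
  at a random course for positives; fluctuations bounded inside both rule
  branches for negatives); efficacy maps to CR/PR/SD (0.1/0.4/0.5) or PD.

Ground truth (individual macros, true exposure, outcome probabilities) is
returned separately from the observable records and never enters any
estimation path.

What passing tests on this cohort do **not** show about real data:
the generator has no inter-occasion variability (PK is constant across
courses, which is exactly the assumption dose individualization relies
on), no covariate effects on PK, no informative sampling times, and its
exposure-outcome link is the invented one above — recovery of the
[2.1, 4.1] window demonstrates the pipeline's correctness, not a clinical
finding.

## Problem sizes and numerical choices

Defaults used by the test-suite and the acceptance script: 200 patients
for parameter recovery, 2000 for window recovery (boundary tails need
patients beyond 4.1 µg/mL), 50 cohorts of 80 for the TPE-vs-grid
comparison, 20 patients for dose round trips, a search budget of 10–20
configurations per classifier family. Optimizer tolerance 1e-8 on the
objective; Hessian step 1e-4 on the log scale; eigen-separation tolerance
1e-9 relative; window boundaries closed on both sides everywhere; all
times in hours from each patient's first infusion start; concentrations
in µg/mL ≡ mg/L; doses in mg.

## Known limitations

- The per-day vs per-hour rate-constant ambiguity is resolved
  pragmatically (see above); day-21 trough magnitudes are not
  reproducible either way.
- The acceptance flag (all relative SEs < 15%) is rarely attainable from
  two samples per course under the default prior; it is reported honestly
  rather than relaxed.
- TPE at its default 200-trial budget tracks the exhaustive grid on
  average but not in the worst case (see `window` above).
- Nonlinear or saturable kinetics, protein binding/ultrafilterable
  speciation, covariate PK models and mechanistic toxicity dynamics are
  out of scope.
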