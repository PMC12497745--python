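# Methods

## Structural and statistical model

Clozapine is given orally on a maintenance schedule and monitored by trough
sampling. The package models disposition as a one compartment with
first-order absorption and first-order elimination — the minimal structure
consistent with the parameter set (CL/F, V/F, Ka); bioavailability is
absorbed into the apparent parameters (F ≡ 1). Concentrations follow the
closed form

    C(t) = (D/V)·ka/(ka − ke)·(e^{−ke·t} − e^{−ka·t}),   ke = CL/V,

superposed over the dosing history. Repeating regimens use the exact
geometric-series sum of that expression, so finite histories, steady state
(infinite superposition) and their agreement are all analytic; when
|ka − ke| < 1e−8·ka the flip-flop limit (D/V)·ka·t·e^{−ka·t} (summed over
doses with its arithmetico-geometric closed form) replaces the 0/0
expression. Time is in hours, amounts in mg; concentrations are mg/L
internally and ng/mL externally (factor exactly 1000).

Covariates act multiplicatively on the typical parameters: allometric weight
scaling first (exponents 0.75 on clearance, 1 on volume, 70 kg reference),
then the zopiclone factor (1 + θ_ZOP·ZOP) on clearance, then any additional
effects (power form for continuous covariates around their population
median, linear-fractional form for categorical ones). Order is irrelevant
since all factors are multiplicative. Between-subject variability is a
log-normal random effect on clearance only; the residual model is
proportional. Defaults throughout are the published final estimates
(θ_CL 29.6 L/h, θ_V 308 L, Ka 1.3 h⁻¹ fixed, θ_ZOP −0.254, ω 0.348,
σ 0.257).

## Estimation

The per-subject marginal likelihood integrates the proportional-error
conditional likelihood over the clearance random effect. The integral is
approximated by the Laplace method at the conditional mode with the residual
variance evaluated at the conditional prediction ("with interaction"), the
same accuracy class as first-order conditional estimation:

    −2 log L_i ≈ 2·h_i(η̂) + log h_i''(η̂) − log 2π.

Numerical choices:

* **Inner problem** (one η per subject, all subjects vectorized): a
  linearized warm start (weighted least squares of log-residuals on the
  log-prediction slope) followed by safeguarded Newton iterations;
  derivatives in η use the complex-step method (exact to machine precision,
  no cancellation), curvature by differencing the complex-step gradient.
  Convergence at gradient < 1e−8 or step < 1e−12; a backtracking Armijo
  fallback handles the rare slow case. η starts fresh each evaluation so the
  objective is a deterministic, smooth function of the population
  parameters.
* **ω → 0**: below ω = 1e−12 the objective switches to the extended
  least-squares closed form Σ[(y−f)²/(σ²f²) + log(2πσ²f²)], which is the
  analytic limit of the Laplace expression (the generic path reproduces it
  numerically down to ω ≈ 1e−8).
* **Outer problem**: L-BFGS-B on log-transformed positive parameters
  (clearance, volume, ω, σ, optionally ka) and untransformed covariate
  coefficients, with a feasibility penalty where any covariate factor is
  non-positive; relative objective tolerance 1e−10, finite-difference step
  1e−5 (sized against the ~1e−10 relative noise floor of the objective). A
  Nelder-Mead polish runs only if L-BFGS-B reports failure.
* **Standard errors**: central-difference Hessian of the objective at the
  optimum (step 1e−3 on the transformed scale), covariance 2·H⁻¹, delta
  method back to the natural scale (for log-parameters the relative SE is
  the SE of the log directly). A non-positive-definite Hessian raises an
  error naming the worst direction; SEs are then reported as unavailable,
  never fabricated.
* **Covariate selection**: forward inclusion at ΔOFV > 3.84 (χ², df 1,
  α 0.05) and backward elimination at ΔOFV > 6.63 (α 0.01). The original
  analysis describes a two-step procedure without quantifying thresholds;
  these are the conventional values. Allometric weight scaling is part of
  the base model, not a searched covariate, mirroring the structure of the
  final equations.

## Synthetic cohorts

The generator emulates the study cohort: 81 subjects by default, body weight
log-normal moment-matched to mean 70.49 kg / SD 13.53 kg and truncated to
[38, 120] kg by rejection (log-normal for positivity and right skew),
zopiclone prevalence 8/81, q12h maintenance dosing expressed in mg/kg/day
(default 8 mg/kg/day, which centres typical troughs in the therapeutic
window), and trough-only sampling. Subjects are observed in the eighth day
of dosing, where the regimen's accumulation is within 1e−7 of its
steady-state asymptote. The study does not report samples per subject; the
default is 2 troughs. Because volume and absorption are weakly identified
from troughs alone, estimation experiments use a documented enriched design
(samples at 1, 2, 4, 8, 12 h after a steady-state dose plus one extra
trough, 6 observations/subject). Negative simulated observations (possible
under the normal proportional error, ~5e−5 probability at σ = 0.257) are
truncated to zero and counted in the dataset metadata. Ground-truth η and
individual parameters are stored for recovery studies.

What the generator does **not** emulate: assay quantification limits,
dose titration and adherence, dropout, time-varying covariates, correlated
co-medication patterns, or model misspecification (the fitted structure is
the generating structure). Passing recovery tests therefore demonstrate
internal consistency of estimator and simulator, not robustness on real
clinical data.

## Model qualification

* **Goodness of fit**: population predictions at η = 0, individual
  predictions at the empirical-Bayes mode, and conditional weighted
  residuals from the first-order conditional linearization
  (V = G·ω²·Gᵀ + diag(σ²·IPRED²), decorrelated by Cholesky). On data
  simulated from the fitted model these are mean-0, SD-1 to first order.
* **VPC**: replicate datasets simulated under the fitted model with the
  original design; observed 5th/50th/95th percentiles per time bin compared
  with their simulated 95% bands. Bins are quantile-based (default 6), or
  one bin per distinct time when the design has few; bins with under 5
  observations are flagged rather than dropped.
* **Bootstrap**: subjects resampled with replacement (same n), each
  replicate refit from the original estimates (implemented as
  subject-multiplicity weights on the objective, which is equivalent for
  independent subjects and avoids rebuilding datasets). Percentile 95% CIs
  use linear (type-7) interpolation; bias% = (median − estimate)/estimate ×
  100. Non-converged replicates are excluded and counted, with a warning
  above 10%. A minimum of 200 replicates is enforced (default 1000; the
  replicate count of the original analysis is unreported).

## Dose individualization

Monte Carlo scenarios cover 40–120 kg and 1–10 mg/kg/day for both
co-medication groups. The daily dose is split q12h — the original analysis
states only mg/kg/day; twice-daily dosing is standard maintenance practice
and yields troughs centred in the 350–800 ng/mL window at the recommended
doses (q8h/q24h are configurable and all outputs label the interval).
Simulated troughs carry between-subject variability only (residual error
optional, off by default: the target questions concern true exposure).
Per-cell sub-seeds derive from the master seed and the (weight, dose) cell
only, so matched cells across the two groups share η draws. Recommendations
pick the PTA-maximizing dose per weight (ties to the lower dose; an optional
toxicity cap), merging contiguous weights with equal doses into bands; a
reproduction mode accepts fixed band edges and chooses each band's dose by
its worst-weight PTA. Toxicity exceedance is reported as percent to one
decimal.

## Problem sizes used by the checks

Parameter recovery runs 200 enriched-design subjects (6 observations each,
25% zopiclone); covariate-search operating characteristics use 20 seeded
replicates of that design per hypothesis; the bootstrap calibration runs 20
studies of 30 trough-only subjects at 200 replicates each; Monte Carlo
attainment checks use 1000 draws per scenario (100 000 where compared with
the exact monotone-inversion values). These sizes make the whole suite run
in minutes on a single CPU while keeping every statistical tolerance at
3 standard errors or tighter.

## Known limitations

* One-compartment structure and IIV on clearance only, as in the final
  published model; metabolite (norclozapine) kinetics, nonlinear
  elimination, lag time, and richer random-effect structures are out of
  scope.
* The real patient data are unavailable, so the published bootstrap
  medians/CIs and figure scatter cannot be reproduced exactly; the package
  instead verifies the arithmetic identities the publication prints (DDI
  magnitude, bias column) and the self-consistency of each pipeline stage.
* The Laplace approximation is accurate to well under 1% of the quadrature
  reference on this model family, but both are approximations to the same
  marginal likelihood, not to each other's software implementations.
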