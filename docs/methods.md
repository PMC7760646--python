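# Methods

## The model

Nimotuzumab is an anti-EGFR IgG1 (150 kDa) whose disposition in ADPKD
patients is nonlinear: the antibody binds EGFR in serum and, much more
abundantly, in the cystic kidney tissue, and its non-specific clearance
rises with dose.  The package implements the final population model for a
single-dose phase-I setting:

* **Two-compartment disposition with QSS target binding.**  Free amounts
  `A1` (central) and `A2` (peripheral) exchange through an inter-compartmental
  clearance `Q` and are buffered by binding to a constant pool of target in
  each compartment (`Rtot`, `Rtotp`, mg/L).  Under the quasi-steady-state
  approximation the binding micro-constants collapse into
  `Kss = (koff + kint)/kon`, and each disposition equation is divided by the
  correction factor `1 + R·Kss/(Kss + C)²` — the Jacobian of total with
  respect to free concentration — which is ≥ 1 for all non-negative states.
  Complexed drug is internalized from the central compartment at rate `kint`;
  no elimination of the peripheral complex is assumed.

* **Clearance-stimulating turnover mediator.**  A dimensionless mediator
  `A3` (synthesis `kin`, degradation `kout`) multiplies the non-specific
  clearance `CL`.  Its synthesis is stimulated by the free central
  concentration `C1 = A1/V1` through a sigmoid
  `1 + Smax·C1^γ/(S50^γ + C1^γ)`.  Because `kin = kout·A3(0)` with
  `A3(0) = 1`, the mediator starts at steady state and is confined to
  `[1, 1 + Smax]`; with `Smax = 0` it stays identically 1 and the model
  collapses to a plain QSS TMDD model.

* **Observable.**  The assay measures total drug, so the model's observable
  is `Ctot = C1 + Rtot·C1/(Kss + C1)`.

* **Statistical model.**  Log-normal inter-individual variability on `Rtotp`
  and `kout` (`ω = 1.35` and `1.97` on the log scale — enormous, and central
  to everything that follows), and additive Gaussian error with SD
  `σ = 0.48` on the natural-log concentration.

Units are mg, L, h throughout; time zero is the infusion start.

Two printed ambiguities were resolved as follows and are configurable:

* **Mediator driver.**  The stimulation sigmoid is driven by the free
  central *concentration*, not the amount: `S50` is defined and reported in
  mg/L, so only the concentration reading is dimensionally coherent.
* **V1 at 50 mg.**  The reference estimates include a 53% change of `V1`
  confined to the 50-mg cohort, with no stated sign.  The package default is
  the decrease, `V1(50 mg) = V1·(1 − 0.53)`: the increase would put the
  whole 50-mg profile below `Kss` (free Cmax ≈ 12.4 mg/L < 15.5 mg/L),
  which contradicts the observation that the 50-mg arm spends a short but
  non-zero time above `Kss` and eliminates faster early (a smaller volume
  concentrates the dose, drives the mediator harder and accelerates
  clearance).  `v1_dose50_change` is a signed fraction, and the
  dose-selection reporting always evaluates both signs side by side.
* **Hill coefficient.**  `gamma` has no reported estimate; the default is 1
  (the minimal sigmoid) and it is an ordinary, fittable parameter.

## Numerics

The three-state system is integrated by a compiled (numba) adaptive
Dormand–Prince 5(4) method with infusion start/end as hard segment
boundaries and output times hit exactly by step clamping.  scipy's LSODA is
retained as an independent engine (`simulate(..., engine="lsoda")`); the two
agree to ~1e-9 relative on the reference profile, and both match the exact
matrix-exponential solution of the linear limit to better than 1e-6.  The
compiled path exists purely for throughput: the estimation, bootstrap and
VPC loops need on the order of 1e5–1e6 ODE solves, and a per-solve cost of
~0.1–0.3 ms is what makes those loops tractable on one CPU.  Default
tolerances are rtol 1e-8 / atol 1e-10 (1e-7/1e-8 inside the likelihood);
halving them moves reported exposure metrics by < 0.1%.

Time-above-threshold metrics locate crossings by linear interpolation on the
0.5-h output grid; AUC uses the trapezoid on the same grid.

## Estimation

The marginal likelihood is approximated subject by subject with a Laplace
approximation: the two-dimensional posterior mode of `(η_Rtotp, η_kout)` is
located by a damped Gauss–Newton (Levenberg–Marquardt with per-coordinate
curvature scaling; forward-difference Jacobians of the log-prediction), and
the curvature uses the Gauss–Newton Hessian `JᵀJ/σ² + Ω⁻¹`.  This replaces
the stochastic EM / importance-sampling machinery of the original analysis:
the model and error structure are identical, only the marginalization
differs, and on sharp-posterior toys the Laplace value agrees with adaptive
quadrature to ~3e-5 relative.

Two details matter and are deliberate:

* **Deterministic inner starts.**  The η posterior can carry secondary
  modes along a `Rtotp`/`kout` ridge.  The inner search therefore starts
  from a fixed, history-independent point (the prior mode, or the modes at
  the fit's initial parameters) rather than warm-starting from the previous
  outer iteration — a path-dependent objective derails derivative-free
  outer optimizers long before approximation error does.
* **Outer search.**  Nelder–Mead (adaptive) on log-parameters inside a soft
  box of ±2 log units around the initial values.  Powell's line searches
  proved an order of magnitude more expensive on the correlated (CL, V1)
  valley without finding better optima.

OFV is the Laplace −2 log-likelihood (constants included).  Eta-shrinkage is
`100·(1 − SD(EBE)/ω)` (sample SD), eps-shrinkage `100·(1 − SD(IWRES))`.
Nested models are compared at ΔOFV ≥ 7.879 per df (χ², p = 0.005),
non-nested by AIC.

By default `Kss`, `kint`, `Rtot` and `gamma` are fixed at their reference
values when fitting: a 20-subject single-dose trial does not identify them
jointly with the rest, which mirrors how the reference fit treated the
binding constants as structural anchors.  `Q` and `V2` are additionally held
fixed in the desk-scale pipeline configuration.

**Finite-sample behaviour.**  At n = 20 with `ω_kout = 1.97`, single-trial
estimates of the mediator parameters scatter enormously (individual-seed
errors of ±50–200% for `kout`, `S50` are routine), and this is a property of
the likelihood itself, not of the optimizer: adaptive Gauss–Hermite
quadrature confirms that those displaced optima genuinely dominate the
generating values on their seeds.  Across 10 replicated trials the median
bias of every fitted fixed effect stays within ±30% (and of the ω's within
±50%), which is the level at which the estimator is validated.

## Covariate screening

Stepwise, univariate: continuous covariates enter as power functions
centered on the study median, categorical ones as fractional shifts;
forward inclusion needs ΔOFV ≥ 3.84 (p = 0.05), backward retention
ΔOFV ≥ 6.63 (p = 0.01).  Parameters carrying a random effect are screened
only if their eta-shrinkage is below 35%; parameters without IIV (e.g. CL)
are screened directly.  Screening fits hold the structural and variance
parameters at the base estimates and profile only the covariate coefficient
— the univariate screening approximation that keeps a full scan affordable;
the retained model can afterwards be refitted in full.

## Diagnostics

* **pc-VPC**: bins are the nominal sampling times (the design is balanced).
  Prediction correction is multiplicative on the natural scale — equivalently
  additive on the log scale, matching the error model: each observation and
  each simulated observation is scaled by `median(PRED_bin)/PRED`.  The 95%
  band of each percentile is taken across simulated replicates (default
  1000; calibration checks use 200).
* **Bootstrap**: subjects resampled with replacement to the original n,
  each replicate refitted from the original estimates (default 500
  resamples; coverage checks use 100 with a refinement budget of 150
  simplex evaluations and 8 inner mode-search iterations per replicate —
  enough for the replicate optima to disperse genuinely while keeping a
  full run on one CPU in minutes).  Failed refits are excluded; > 20%
  failures flags the result unreliable.
* **Residuals**: IWRES on the log scale at the EBEs; CWRES from a
  first-order linearization of the log-prediction around the EBE
  (FOCE-style; the exact NONMEM CWRESI algorithm is not reproduced).

## The virtual trial generator

`generate_trial` reproduces the study conditions: 4 cohorts × 5 subjects,
single 30-min infusion of 50/100/200/400 mg, 23 post-dose samples between
0.5 and 672 h plus a pre-dose record, IIV and residual error as above, and
covariates drawn from log-normals matched to the observed cohort's
mean/SD table (sex-specific for total kidney volume; sex 70% female, race
75% Caucasian).  The LLOQ (7.8 ng/mL) is tracked but never binds at these
doses.  Covariates exert no effect on the parameters unless explicitly
injected — the final model retained none, so the default generator is the
covariate-screening true-negative bed, and `covariate_effects` provides the
true-positive bed.

What the generator does *not* emulate: the original study's missingness
(422 of a possible 460 observations, pattern unreported — the generator
produces the complete schedule), assay drift, ADA/immunogenicity, and any
covariate–parameter correlation beyond those injected.  Passing tests
therefore validate the machinery under the stated statistical model, not
the idiosyncrasies of the original dataset.

## Dose selection

A deterministic sweep (50–1200 mg, single 30-min infusion, 1000-h horizon,
0.5-h grid) summarizes each dose by free-concentration Cmax, AUC and the
time above `Kss` = 15.5 mg/L.  With the package's reference parameters the
sweep yields times above `Kss` of ≈ 62.6 / 108.9 / 167.8 / 218.6 / 266.2 /
293.3 h for 50–1200 mg (V1-decrease reading), i.e. a +74% gain for
50→100 mg and +54% / +30% / +22% / +10% for the successive doublings — the
gain per doubling falls below 25% from 400 mg onward.  Under the
V1-increase reading the 50-mg profile never exceeds `Kss` and the 50→100
gain is unbounded.  Neither reading reproduces the originally reported
+150% (50→100) together with "<25% per doubling above 100 mg"; an extensive
scan over the structural ambiguities (mediator driver, V1-change sign and
form, Hill coefficient, threshold and concentration series) found no
combination that does, so those two figures evidently depend on simulation
settings not derivable from the published description.  The pipeline
reports what the model actually computes, for both V1 readings.

## Problem sizes used by the test suite

Replicated-fit studies use 10 trials (parameter recovery), 100 bootstrap
resamples, 200 VPC replicates × 5 trials, and 5 trials for the
covariate-screening power check; these are the package's desk-scale
defaults for routine validation, while the user-facing defaults (1000 VPC
replicates, 500 resamples) match the original analysis.
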