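# Methods

## Structural model

Each citalopram enantiomer follows a depot → parent → metabolite
cascade: first-order absorption (shared ka, fixed at 1 h⁻¹ because one
sample 1–24 h after dosing cannot inform absorption), a one-compartment
parent whose entire elimination forms the desmethyl metabolite
("complete conversion"), and linear metabolite elimination.  Parent and
metabolite share the enantiomer's apparent volume of distribution; with
oral racemate data only, bioavailability is unidentifiable and all
clearances and volumes are apparent (CL/F, V/F).  Each administration
of racemic drug deposits half its milligrams into each enantiomer's
depot; the two enantiomers share no parameters, so the joint model
factorizes exactly into independent R and S halves.

Concentrations are evaluated in closed form.  The cascade solution is
written as divided differences of `exp(-k·t)` over the participating
rate constants — one code path whose equal-rate limits are explicit
L'Hôpital branches rather than near-zero divisions.  The two-rate
kernel switches to its confluent limit below a relative gap of 1e-8;
the three-rate kernel switches at 1e-5 because a second divided
difference loses two orders of cancellation (below that gap the
distinct-rate formula is round-off noise while the confluent limit is
accurate to O(gap)).  Multi-dose profiles are superpositions; for
once-daily runs of equal doses the superposition collapses to exact
geometric sums per exponential term, which is what the estimator's hot
path uses.  An adaptive ODE integration of the same right-hand side
(bolus depot updates between segments, LSODA at rtol 1e-10) serves as
an independent oracle; closed form and integrator agree to better than
1e-5 relative across random parameter sets.

Units: doses mg, volumes L, clearances L/h, times hours since first
dose; concentrations are mg/L internally and ng/mL (×1000) everywhere
visible.

## Covariate and statistical model

Typical values carry the final covariate structure only: sex-specific
CL_Rp/F base with a centered power of age (exponent −0.822), CYP2C19
group-specific CL_Sp/F base with centered powers of age (−1.33) and
weight, weight powers on both metabolite clearances, nothing on volumes
or ka.  Age is centered at 60 years and weight at 70 kg so every factor
is exactly 1 at the centers.  The weight exponent is fixed at 0.75, the
allometric convention reported identically for all three weight
relationships; freeing it remains possible for selection experiments.
The centered-additive (linear) covariate form is implemented as an
alternative for candidate testing but is never part of the final model.
BMI (centered at 25) is available as a candidate covariate and is
retained nowhere, so typical values are invariant to it.

Between-subject variability is log-normal, `P_i = P_typ·e^η`, with the
eta order (CL_p, V, CL_m) per enantiomer.  The R block is diagonal; the
S block carries a (CL_Sp, V_S) covariance; ka has no variability.
Magnitudes are reported in percent as 100·√variance (100·√covariance
for the off-diagonal), the common mixed-effects convention — the
percent convention is a package decision since reports rarely state it.
Residual error is additive for R-citalopram (13.42 ng/mL), proportional
for R-desmethylcitalopram (21.54%), and a single shared proportional
term for both S compounds (21.61%), treated as separate free parameters.

## Trial generator

The generator is the stand-in for the study's raw data and defines the
study conditions used by every downstream experiment:

- 81 analyzed subjects; covariates drawn independently from the cohort
  marginals: age truncated-normal 77.8 ± 8.2 on [47, 90] y, weight
  71.5 ± 17.2 on [40, 122.3] kg, BMI 26.3 ± 5.2 on [15.4, 41.6],
  49.4% female, CYP2C19 EM/RM : IM/PM : missing = 56.8 : 24.7 : 18.5%.
- Once-daily dosing titrated 7 days at 10 mg and 7 at 20 mg before the
  30 mg target (the exact 7/7 split is a configurable convention; only
  the two-week titration is reported), held through day 63.
- One blood draw per visit at weeks 3/6/9, at a uniform [1, 24] h time
  after the morning dose, yielding up to four compound records.
- Independent per-compound missingness (0.16 parents, 0.26 R-metabolite,
  0.20 S-metabolite) chosen once so retained densities approach the
  reported 2.5/2.2/2.5/1.3 observations/subject; quantitation limits
  5 ng/mL (10 for S-desmethylcitalopram), censored records dropped by
  default (complete-case likelihood; a flag mode retains them with
  blank values).  Simulated concentrations below zero (possible under
  additive error) are floored at zero before censoring.

What the generator does not emulate: covariate correlations (real age,
weight and sex are not independent), dose adjustments after titration,
dropout, and any BLQ handling other than complete-case.  Passing tests
therefore demonstrate internal consistency of model + estimator under
the declared design, not fidelity to the withheld clinical dataset.

A kinetic consequence worth noting: with the R-parent half-life near
98 h (ln 2·1830/13), week 3 — one week after the last titration step —
is *not* at steady state for the R compounds: their noise-free
predictions still sit 16–27% below the plateau, while the faster S
compounds (half-life ~44 h) are within 4–7%; by week 6 all four are
within 2%.  The tests assert exactly this behaviour.

## Estimation

The subject-level marginal likelihood uses the first-order conditional
(FOCE) approximation with interaction.  For subject i with conditional
−2 log joint density l(η) (residual SD evaluated at the η-dependent
prediction — the "interaction"), the contribution is

    OFV_i = l(η̂) − d·log 2π + log det(JᵀWJ + Ω⁻¹),

with η̂ the posterior mode, J the prediction sensitivity at η̂, and
W the inverse residual variances.  The Gauss–Newton curvature is the
FOCE convention; a finite-difference full-Laplace Hessian is available
as an alternative in the per-subject path.  On models linear in η with
constant residual SD this expression equals the exact Gaussian marginal
−2 log likelihood, which the tests verify to 1e-6 relative — the
decisive correctness oracle.

The inner η search is a damped Gauss–Newton with exact gradients
(including the interaction terms) and Fisher weights
`1/σ² + 2(σ′/σ)²`; prediction sensitivities come from complex-step
differentiation (step 1e-20), machine-precision and free of
step-size tuning.  All subjects are solved simultaneously on padded
arrays with an active-set sweep; padded cells carry zero time offsets
and amounts and vanish from every sum.  Rate constants closer than
1e-6 relative are nudged apart instead of taking the confluent limit
(the scalar reference path keeps exact limits; both agree to ~1e-12 on
study-like data).  Subjects with no quantifiable observations
contribute exactly zero to the OFV.

The outer problem maximizes the likelihood over log-transformed
positive parameters (raw scale for covariate exponents, Cholesky with
log diagonal for the S 2×2 block) with L-BFGS-B on the mean
per-observation OFV — the scaling keeps the optimizer's unit first
step and tolerances dataset-size invariant.  The inner solver
warm-starts from the η set solved at the most recently *accepted*
outer iterate: all evaluations within one gradient/line-search cycle
share a start, so finite differences stay consistent, while a
per-evaluation warm start would inject hysteresis the line search
reads as noise.  Convergence: relative objective change below 1e-9
(≈1e-4 on the OFV scale for these data) or projected gradient below
1e-7.  An exhausted line search at the numerical noise floor counts as
convergence.  Initial values default to the covariate-free base-model
magnitudes (8.6/14 L/h parents, 23.8/38.5 L/h metabolites, 2050/1450 L
volumes, 30% variabilities, 15 ng/mL / 20% residuals); experiment
drivers that refit the final model start from the published estimates.

Model variants cover the final structure, covariate-free bases, a
parent-only stage (used in the staged covariate build), swapped
residual structures, and a partial-conversion alternative (an extra
direct parent elimination clearance).  Two-compartment dispositions and
direct metabolite dosing are declared on the variant type but are not
fittable.

## Covariate selection and bootstrap

Forward univariate inclusion adds the best-ΔOFV candidate per step,
retained when the drop meets the χ² quantile for its degrees of freedom
(3.84 at 1 df; the CYP2C19 split adds two parameters, hence 5.99);
backward elimination then removes any covariate whose removal costs
less than the same threshold.  The trace mirrors a model-building
table: candidate, OFV, ΔOFV, df, p.

The likelihood surface is multimodal (the very large R-volume
variability, ~167%, trades off against residual error on sparse data).
The selection *experiment* therefore applies likelihood-ratio hygiene:
whenever an augmented fit lands more than the threshold below the
base, the base is refit warm-started from that solution with the
covariate removed, so each ratio compares the best optimum found for
each model and optimizer escapes cannot masquerade as covariate signal.
Its forward steps for CL_Rp run on the parent-only R model, matching
the staged build order (parent first, metabolite added later).

The nonparametric bootstrap resamples subjects with replacement
(original n per replicate), refits from the point estimates, and
reports medians with 2.5/97.5 percentile intervals; failed replicates
are excluded and counted, with a warning status above 20%.

## Post-processing

CWRES uses the FOCE linearization about η̂: mean `f(η̂) − Jη̂`,
covariance `JΩJᵀ + diag(σ²)` with σ at the conditional prediction,
whitened by the symmetric inverse square root (order-invariant, unlike
Cholesky whitening); a singular covariance is ridge-regularized and
flagged.  With Ω = 0 this collapses to (DV − PRED)/σ exactly.  Note
the direction convention: a model whose clearances are too *low*
overpredicts, so observed-minus-expected residuals shift negative.

Empirical-Bayes realized parameters (typical × e^η̂) feed subgroup
summaries (sex, age bands <70/70–79/80–90, weight </≥70 kg, genotype)
with pairwise contrasts computed as (faster − slower)/slower × 100 —
relative to the slower group, the direction used for the "x% faster"
phrasing; the published 30% sex contrast is instead relative to the
larger value and is computed that way by `sex_contrast`.  Steady-state
exposure is AUC₂₄ = daily enantiomer dose / realized CL (verified
against trapezoidal integration of the analytic profile to 1%), and
enantiomer contrasts use the Mann–Whitney U test (exact enumeration for
group sizes ≤ 8 without ties, tie-corrected normal approximation
otherwise; identical pooled values give p = 1 by convention).

## Experiment scales

The simulate-and-refit study uses 5 trials of 81 subjects (the study's
size) and averages the recovered fixed effects; the population summary
uses 2000 subjects; the selection operating-characteristics study uses
20 trials with age (true effect) and BMI (null) as single forward
steps.  These sizes are the package's chosen defaults and are the same
in the tests, the analysis scripts and the acceptance script.

## Known limitations

- Power to detect the age effect at its published magnitude is modest
  under this design: the age-driven spread of log CL_Rp (~0.077) is
  small against between-subject variability plus sex heterogeneity
  (~0.32) and sparse-data estimation noise, giving expected ΔOFV ≈ 3–5
  and retention rates near 30–50%, far below the ΔOFV of 15.6 the
  original data showed.  A stronger real-world age–clearance
  association than the final model's own estimate would explain the
  difference; the generator deliberately does not assume one.
- Complete-case BLQ handling biases low-concentration subjects'
  clearances downward, most visibly for S-desmethylcitalopram.
- The mean realized CL_Sp in the generated population sits ~14–16%
  above the reported cohort mean of the original analysis: the
  reported value is a shrunk empirical-Bayes mean over the real
  (correlated) covariate distribution, while the generator combines
  marginal demographics with the full log-normal variability mean
  factor e^{ω²/2}.
- No inter-occasion variability, no urinary excretion pathway, no
  exposure–response modelling.
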