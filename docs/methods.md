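# Methods

## The model

`screenpref` analyses discrete choice experiments (DCEs) on cancer-screening
programs. A screening offer is a profile over six attributes — procedure
(colonoscopy, CT colonography, 2-day stool, 1-day stool, blood test), pain,
sensitivity, recommendation source, out-of-pocket cost and procedural risk —
and respondents repeatedly choose between two profiles and an opt-out.

Under the random-utility model, respondent *i*'s utility for alternative *j*
in task *t* is

    U_ijt = x_jt' β_i + δ·1[j = left] + ε_ijt,     ε iid Gumbel,

where `x_jt` dummy-codes the profile's non-reference levels plus an opt-out
indicator. The two-stage survey task (pick the better profile, then decide
whether to actually take it) is collapsed into a single three-alternative
choice {left, right, opt-out}: a single opt-out alternative-specific
constant (ASC) and a single left-position constant are estimated in one
regression, which is exactly what that encoding implies. The left constant
captures reading-order bias and applies to the left profile only; it is not
random. The opt-out ASC *is* random: willingness to screen at all is the
most heterogeneous preference in this domain.

**Panel mixed logit (MXL).** β_i ~ N(μ, diag(σ²)), independent normals per
coefficient (only per-coefficient heterogeneity is modelled; the reference
estimates report no correlations). The likelihood of a respondent is the
integral over β of the product of their task-level logit probabilities —
the panel structure ties all of a respondent's tasks to one coefficient
draw. The integral is approximated by quasi-Monte-Carlo (below) and the
simulated likelihood is maximised directly (maximum simulated likelihood,
MSL) by quasi-Newton ascent with analytic gradients. Only |σ| is
identified; SDs are optimised unconstrained and reported in absolute value.

**Latent-class mixed logit (MMML).** A finite mixture of C mixed logits
with a multinomial-logit membership model on respondent covariates
(class 1 = reference): sex, ethnicity, age band (≥61), household income,
marital status, education (two dummies vs pre-university), housing type,
work status, family history of colorectal cancer, prior screening, and four
median-centred psychosocial scores (perceived test safety, social support,
present orientation, intolerance of uncertainty). Estimation is direct MSL
over all class parameters and membership coefficients jointly. Because
latent-class likelihoods are multimodal, the fit runs `n_starts` random
perturbations of a conditional-logit baseline (each for `start_iters`
iterations) and polishes the best to convergence. Classes are labelled
post hoc by the opt-out ASC: the class with the more negative value — the
"strong supporters" of screening — is reported first, and the membership
logit is re-referenced accordingly, resolving label switching
deterministically. Posterior membership follows Bayes' rule (prior ×
simulated within-class panel likelihood, normalised); class shares are
reported both as mean posteriors and as modal-assignment counts. The number
of classes is chosen by BIC against the single-population MXL baseline.

## Quasi-random draws

The mixing integrals use scrambled Halton sequences mapped through the
standard-normal quantile (uniforms clipped away from 0/1, a 16-point
burn-in skipped). Each respondent receives their own independently
Owen-scrambled copy of the sequence, seeded from one spawning seed. Two
properties motivated this over the common "one long sequence, sliced into
per-respondent blocks": each respondent's integral is approximated by a
fully equidistributed point set, and — the decisive point in the package's own
calibration experiments on synthetic data — the integration errors are
*independent across respondents*, so they average out in the sample log-likelihood
instead of pushing all respondents' likelihood contributions in the same
direction. A shared base set (even under per-respondent uniform shifts)
leaves the joint-dimension gaps of the base set common to every respondent
and measurably attenuates the larger SD estimates.

Defaults: 500 draws per respondent for final fits, 200 in the recovery
experiments, 100 per class for the latent-class model. The likelihood is
exactly the conditional logit when all SDs are zero, for any draw count.

## Numerical choices

- All level effects are dummy-coded against reference levels chosen to match
  current screening practice (2-day stool test, 80% sensitivity, S$0, no
  pain, no risk) and "no recommendation". Cost is treated as discrete.
- Softmax probabilities use max-subtraction; all mixture averages are
  computed in log space (log-sum-exp).
- Starting values: conditional-logit estimates for the means and the left
  constant, 0.1 for every SD.
- Optimiser: L-BFGS-B with analytic gradients. L-BFGS can declare
  convergence on plateaus of these likelihoods while a restart (which resets
  the curvature memory) still gains tens of log-likelihood points at study
  scale, so the fit restarts until the objective improves by less than
  `restart_tol` (default 1e-3).
- Standard errors: inverse of the numerical Hessian (central finite
  differences of the analytic gradient); a robust sandwich variant uses the
  per-respondent scores. 95% CIs are Wald intervals (±1.96 SE), matching the
  symmetric intervals the reference estimates print.
- BIC uses n = choice observations (respondents × tasks), logged in every
  fit result; AIC = 2p − 2ℓ.
- A fit is flagged (not silently accepted) on optimizer non-convergence or
  when a prior class share falls below `min_share` (1%).
- Rank-deficient design matrices raise an estimability error naming
  never-observed levels where possible.

## The synthetic-data generator

The study's raw survey data are not public, so the generator emulates the
study conditions end to end: a 20-block × 10-task design generated by
uniform rejection sampling over prohibition-satisfying profiles (stool
tests never appear with S$400/S$1000 cost or with mild pain; the blood test
is deliberately unrestricted), one fixed dominant validity task present in
every block, block assignment round-robin after shuffling, and choices
drawn from the random-utility model above with Gumbel noise.

The data-generating parameters are the package's built-in reference sets:
the published single-population means/SDs and 2-class means of a large
Singapore colorectal-screening preference survey (in `params.py`). Two
gaps in the published values are filled with documented stand-ins:

- *Within-class SDs* of the 2-class model are not published; the generator
  uses the single-population SDs scaled by 0.7 (part of the population
  heterogeneity is absorbed by the class split). Configurable.
- The *membership-model intercept* is not published; the default 0.76 was
  calibrated analytically so that prior class shares under the default
  covariate spec approximate the reported ≈38/62 strong/weak split.

Covariate marginals are census-like values for an urban Asian population
aged ≥40 (e.g. 51% female, 74% ethnic Chinese, 35% aged ≥61); psychosocial
scores are normals with inventory-plausible locations and scales, median-
centred within the sample as the analysis prescribes. The generator draws
covariates independently — it does not reproduce real-world correlations
between, say, age and work status — and models no respondent fatigue,
learning, or attribute non-attendance. Passing recovery tests therefore
show that the estimators invert the assumed data-generating process at
study scale, not that the model is correct for real respondents.

Sample filters mirror the study's exclusions: respondents with any missing
covariate and respondents choosing the dominated profile of the validity
task are removed (as a union — the two sets may overlap), and validity-task
rows are dropped from the analysis set.

## Post-estimation

**Conditional relative importance (CRI).** Per attribute, the spread
(max − min) of its level preference weights, the reference level entering
at 0; ASCs are excluded; profile-based normalisation rescales the CRIs to
sum to 1. Two variants are emitted: CRI of the population means (the
definition implemented literally) and the mean of per-draw CRIs over the
mixing distribution. They can order mid-ranked attributes differently
(spreads of heterogeneous coefficients widen under the second definition),
and neither is asserted to reproduce any particular published ordering.

**Uptake.** A single offered program has no position, so P(take) =
E_β[ exp(x'β) / (exp(x'β) + exp(ASC_optout)) ], the expectation taken over
the mixing distribution (10⁴ quasi-random coefficient draws by default;
closed-form logistic when all SDs are zero). Uptake changes
(relative = ΔP/P_base or absolute) carry 95% CIs by Krinsky–Robb parametric
resampling: parameter vectors are redrawn from the estimator's asymptotic
normal (1,000 reps default) and the change recomputed per draw. The
published ≈5.9% relative-uptake figure for weak supporters depends on
unpublished within-class SDs and an unstated integration method, so the
package asserts only the directional and closed-form zero-SD oracles.

## Problem sizes and experiments

The recovery experiments (`screenpref.experiments`) simulate at the study's
own scale: 1021 respondents × 10 tasks, 200 draws, ten simulate-and-refit
replicates for the single-population model; 600 respondents, 100 draws and
10 starts for the reduced-scale 2-class experiment. Recovery fits use the
full simulated sample (validity task included, no exclusions): the estimand
is the data-generating parameter vector, and excluding simulated validity
failures would selectively truncate the coefficient distribution being
recovered. Unit and property tests run on 4-block designs with 150–400
respondents and 30–50 draws to keep the suite fast.

## Known limitations

- MSL with a finite draw count attenuates the estimates attached to
  high-heterogeneity, rarely shown levels: at 200 draws per respondent the
  recovered SD of the most heterogeneous attribute coefficient, and the
  mean of the S$1000 cost level (barred for stool tests, hence seen in only
  about one legal profile in six), sit a few percent closer to zero than
  the generating values; the effect roughly halves from 200 to 1000 draws.
  Means of well-exposed levels are essentially unaffected. This is a
  documented property of the estimator, not corrected post hoc.
- BIC class selection is scale-sensitive: at reduced sample sizes the
  penalty for the ~50 extra parameters of a second class can exceed the
  mixture's deviance gain even when the data are genuinely two-class, so
  the selection experiments report the full criterion table rather than
  asserting a universal preference for two classes.
- Random coefficients are independent normals; correlated or non-normal
  mixing (lognormal cost, for instance) is out of scope.
- The membership model is a single categorical latent dimension; the
  two-stage task is modelled only in collapsed form.
- Willingness-to-pay monetisation and covariate-reweighted population
  forecasts are out of scope.
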