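# Methods

## Outcome model

For a child with confirmed seroconversion, prediction starts at an anchor age
*time 0* — the confirmatory visit, or `confirmatory + W` in the third-test
design — and the outcome is diabetes diagnosis within the follow-up period
(time 0, time 0 + T]. The interval is half-open on the left and closed on the
right: a diagnosis exactly at time 0 excludes the child (they were already
diabetic when prediction would have started), and one exactly at time 0 + T is
an event. Children whose observation ends event-free inside the horizon are
censored; children diagnosed after the horizon, or followed event-free past
it, are genuine negatives.

The binary T-year outcome is modelled by logistic regression with inverse
probability of censoring weighting (IPCW). Let X be the time from time 0 to
diagnosis or last contact and δ the diagnosis indicator. The censoring
survival function G(t) = P(C > t) is estimated by the Kaplan–Meier
product-limit estimator with the roles of event and censoring swapped.
Weights are

* event within the horizon (δ = 1, X ≤ T): `1 / Ĝ(X⁻)` — the left limit,
  so a subject's own censoring-process jump never enters its weight;
* known event-free through the horizon (X > T): `1 / Ĝ(T)`;
* censored inside the horizon: 0 (the row leaves the weighted likelihood).

At tied times, diagnoses are processed before censorings (subjects diagnosed
at t remain in the risk set of a censoring at t); the alternative order is
available (`ties="censor_first"`). Weights are capped at `w_max = 20`
(configurable) to bound the variance contributed by near-zero Ĝ; every cap
hit is logged. Under this scheme the weighted pseudo-sample Σw is a
consistent estimate of the uncensored cohort size, and with no censoring all
weights are 1 and the fit reduces to ordinary logistic regression.

## Estimation and inference

The weighted Bernoulli log-likelihood is maximised by iteratively reweighted
least squares with step-halving, which makes the likelihood provably
nondecreasing across iterations (asserted at every step). Convergence is
max |Δβ| < 1e-8 within 100 iterations. No regularisation is used; complete or
quasi-complete separation (|linear predictor| > 30, or non-convergence) is
flagged in the fit's messages rather than penalised away. With an unpenalised
fit this *will* occur for near-empty categorical cells — notably the 'missing'
HLA level, which is deliberately kept as its own indicator (a few children
per cohort) rather than dropped, preserving cohort counts.

Because IPCW weights are estimated quantities, not frequency weights, the
default Wald standard errors are the robust sandwich A⁻¹BA⁻¹ (A the weighted
information, B the outer product of weighted score contributions); this is
the estimator under which the 95% CIs attain nominal coverage in the
package's own recovery simulations. The model-based inverse-information SEs
are kept alongside (`ModelFit.se_info`) and agree with
`statsmodels GLM(…, freq_weights=…)`. Odds ratios are exp(β) per log-unit of
level; the OR for an n-fold level increase is exp(β·ln n), which is exactly
multiplicative in n.

## Discrimination

Discrimination is the Uno-type IPCW concordance index truncated at τ = T:
comparable pairs (i, j) have δᵢ = 1, Xᵢ < τ and Xᵢ < Xⱼ; each pair carries
weight 1/Ĝ(Xᵢ⁻)² and counts fully when the risk score orders the pair
correctly, half on score ties. With no censoring and τ beyond the last event
this is exactly the classical concordance/AUC. An evaluation with no
comparable pairs raises `ConcordanceUndefinedError` rather than silently
returning 0.5.

Evaluation uses 10-fold cross-validation with child-level random folds
(seeded). The censoring model and the weighted GLM are fitted on the nine
training folds; the held-out fold is scored by predicted event probability
and its C index uses the train-fold Ĝ (fitting Ĝ on the full data is a
config alternative; the original protocol does not specify). The reported C
is the *mean of the ten fold-level indices*, not a pooled-prediction C.
Percentile 95% bootstrap CIs resample children, never visits. Two variants
exist: `refit` re-runs the entire cross-validation per resample (default B =
1000; expensive), and `fold` resamples the ten fold-level C values (cheap,
used where only an indicative CI is needed); results record which was used.

## Covariate sets

The nine compared covariate sets: (1) baseline — data source (reference
DIPP), sex, diabetes family history, HLA risk group (reference B, explicit
'missing' level), ages at the initial and confirmatory visits; (2)–(4)
positivity indicators at the initial, confirmatory, or both visits; (5)–(7)
log levels at the same visits; (8) baseline + positivity (both); (9) baseline
+ levels (both). The third-test grid models use only the three log levels
from the visit immediately at or before time 0. Continuous covariates enter
unstandardised; all levels are used whether above or below the positivity
threshold, log-transformed as ln(max(mULN, 0.01)) — the floor handles true
zeros and is configurable.

## Synthetic cohorts

`longitudinal` mode emulates the visit-level structure of a multi-study
birth-cohort consortium at desk scale. Per child: static covariates drawn
from the published marginals (source mix with DIPP ≈ 59%, 55.5% male, HLA
groups A/B/C/D ≈ 24/47/13/16% with 0.2% missing); a seroconversion age from
a truncated log-normal (log-mean 1.50, log-sd 0.67, range 0.3–13 y, matching
mean ≈ 5.6 ± 4.2 y); scheduled visits every ≈ 0.45 y (jittered ±15%) from two
intervals before seroconversion until the administrative end of study, drawn
per child uniformly between 15 and 24 years of age (the published cohort
contains follow-up to age 23.9, and a hard cap at 15 would make horizons near
T = 15 unevaluable); and independent dropout with a 0.045/y hazard.

Each antibody converts with probability matching the published confirmatory
positivity (IAA 0.56, GADA 0.62, IA-2A 0.30; at least one forced). Log-mULN
trajectories are: below the positivity threshold before conversion
(N(−1.8, 0.7) truncated below ln 1); after conversion, a child-specific level
at seroconversion N(post-mean, post-sd) + shared child intercept N(0, 0.4) +
a child-specific linear drift N(drift-mean, drift-sd)·(t − s) + visit noise
N(0, 0.3). Post-seroconversion spreads (1.3/1.5/1.7) reflect the very heavy
dispersion of real mULN values; the random drift slope is what makes late
events harder to predict from time-0 levels and a third test informative —
without it the concordance index would not decline with the horizon T.

Onset follows a piecewise-constant hazard exp(η(t)) with η = −3.3 +
0.30·ln IAA + 0.20·ln GADA + 0.35·ln IA-2A (most recent visit's values) +
HLA effects (A +0.5, C −0.3, D −0.6 vs B). The intercept was calibrated once
against the published 37.3% progressor fraction of the retained cohort
(sweep: 0.352 at −3.3, 0.374 at −3.15, 0.413 at −3.0 before the final level
parameters; 0.37 at −3.3 after) and then frozen. Censoring is generated
independently of η by construction.

`logistic_direct` mode is the exactly well-specified counterpart used for
parameter recovery: one feature row per child, event ~
Bernoulli(logistic(η)), an event time uniform on (0, T], and independent
exponential censoring (≈30% censored at the defaults) with an administrative
end at T + 2 years past time 0. Feature vectors are redrawn until at least
one antibody is positive — selection on covariates only, which leaves the
conditional outcome model untouched.

What a green test on these cohorts establishes: that the pipeline's
estimators are correct (oracle equivalences, parameter recovery, CI
coverage) and that the qualitative structure of the published analysis
(baseline < positivity < levels in C; C declining in T; third-test cohorts
nesting and C improving in W) emerges when the generating process has the
assumed structure. What it does not establish: the published C-index values
themselves, which depend on the restricted real cohort; assay harmonisation
artefacts; epitope/affinity biology; visit-schedule irregularities beyond
simple jitter; or covariate-dependent censoring.

## Numerical and design choices

* Positivity is strict: mULN > 1.
* Log floor 0.01 (the original analysis does not state how zeros were
  handled; any fixed small floor keeps the transform defined).
* Child-level seroconversion with several confirmed antibodies: earliest
  confirmatory visit wins, ties by earliest initial visit, then the fixed
  order IAA, GADA, IA-2A. "Consecutive samples" means literally adjacent
  recorded visits, regardless of the gap; a positive–missing–positive
  sequence does not qualify.
* The third-test analysis does not require a visit strictly after the
  confirmatory visit; when none exists the confirmatory visit itself supplies
  the features (logged via `feature_visit_age` for audit).
* Bootstrap default B = 1000; the resampling unit is always the child.
* Folds are simple random partitions; event-stratified folds were considered
  and rejected as a deviation from the stated protocol ("randomly
  splitting").
* Ages are stored to 3 decimals (~day resolution) in the CSV schemas;
  comparisons are exact on stored values.

## Known limitations

The level-trajectory dynamics (drifts, spreads, noise) are
plausibility-driven, not calibrated to the restricted data — the original
study reports no trajectory parameters. Censoring is independent by
construction, so the IPCW assumption holds exactly in simulation; real
dropout may be informative. The generator models no assay differences
between data sources, and ZnT8A is out of scope throughout.
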