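# Methods

This note documents the models, the generative assumptions behind the
synthetic data, the numerical choices, and the limits of what the bundled
tests demonstrate.

## The quality framework and the indicator catalogue

Quality is measured as a two-level tree: 3 domains, 13 fixed sub-domains,
and a configurable set of binary indicators per sub-domain. The catalogue
is configuration, not code: each entry names its sub-domain, its data
source (patient survey, provider survey, chart abstraction, registry) and
a binarization rule (identity on 0/1 values, category-set membership, or a
numeric threshold with direction). The bundled default catalogue carries
4–8 indicators per sub-domain named after each sub-domain's definitional
clauses (e.g. management/informational/relational continuity items;
"adequate frequency of follow-ups" for disease management, thresholded at
4 registry visits per calendar year). It is a synthetic stand-in for a
study instrument that is not publicly available, and is explicitly not a
reconstruction of any real questionnaire.

Two catalogue conventions worth noting. Unanswered raw values always
become masked cells, never 0: silently zeroing nonresponse would deflate
quality. "Don't know"/refusal handling is per-rule configurable through
`categories` / `missing_categories`; the conservative default treats a
refusal on an endorsement item as non-endorsement (0) and lets factual
items route refusals to missing.

## Scoring

Mean-scored sub-domains (the four PHC-system sub-domains, disease
management, the four user-experience sub-domains): per-unit mean over
non-missing indicators; a unit with every cell missing gets an undefined
(NaN) score that is flagged, never imputed as 0 at this stage. Domain
scores are equal-weight means of the constituent sub-domain scores; this
choice reproduces both published domain totals (0.718 and 0.727) exactly
from the published sub-domain values, though whether the original analysis
averaged indicators or sub-domain means is not decidable from the printed
numbers alone — both reproduce them. Clinical care deliberately has no
single domain score because its sub-domains come from disparate sources.
"Above 0.7 is favourable" is read strictly (> 0.7): 0.70 itself is not
favourable.

The headline pipeline scores after imputation (per-imputation scores, then
Rubin pooling of the aggregates and across-imputation averaging of the
per-unit scores); a pre-imputation complete-case path exists (`--no-impute`)
because it is far easier to reason about in tests.

## Rasch scoring

The clinical-care checklists and the vignette instrument are scored with
the dichotomous Rasch model: P(Y_ij = 1 | θ_j) = σ(θ_j − b_i) with
θ_j ~ N(0,1). Choices, in order of consequence:

- **Estimation is MML-EM.** The ability prior is fixed at N(0,1) exactly
  as the model states it (mean and variance are not estimated); item
  difficulties maximise the marginal likelihood with the ability
  integrated out by Gauss–Hermite quadrature (21 nodes by default,
  configurable). MML handles all-0/all-1 respondents without ad hoc
  corrections, which joint ML does not. The E-step produces expected
  per-node success/trial counts per item; the M-step solves one monotone
  1-D equation per item by bracketed root finding on [−35, 35]. The EM
  marginal log-likelihood path is non-decreasing (asserted in tests).
- **Convergence**: max |Δb| < 1e-6 or 500 iterations; hitting the cap
  flags the fit rather than failing silently.
- **Zero-variance items** (all endorsed or none, among respondents
  observed on them) have infinite ML difficulties; they are dropped with
  a warning and recorded on the fit rather than estimated at ±∞.
- **Missing cells** contribute nothing to the likelihood for that
  (unit, item) pair.
- **Person scoring is EAP** (posterior mean on the quadrature grid):
  defined for every response pattern, including all-0 and all-1. Units
  with no observed responses get NaN.
- **The θ → [0,1] mapping** is the test characteristic curve divided by
  the item count: the model-expected proportion of the instrument's
  retained items endorsed at θ. It is bounded, strictly increasing, and
  has limits 0/1 — satisfying the "0 lowest, 1 highest" scale contract.
  The original analysis never states its mapping, so published
  Rasch-scored values (e.g. provider competence 0.314) are design
  neighbourhoods for the generator defaults, not reproduction targets.
- Starting values are logits of observed item failure rates.

## Reliability

Cronbach's alpha with sample variances (n−1) on listwise-complete units,
computed pre-imputation for the three summative scales (PHC-system
indicators, user-experience indicators, the vignette instrument). Alpha on
binary items from the default generator is near zero by construction for
the mean-scored scales (see the generator's limits below); the vignette
scale, which shares a latent trait, shows substantial alpha (~0.6).

## Multiple imputation

Chained equations, visiting columns in order of increasing missingness:
binary columns by a logistic fit on the currently-completed predictors
with a multivariate-normal posterior draw of the coefficients before the
Bernoulli draw (approximate proper imputation); a Jeffreys-Beta/Bernoulli
independence fallback when the logistic fit is degenerate (separation,
zero variance); non-binary numeric columns by predictive mean matching
with 5 donors. Predictors are the encoded covariates plus the other
indicators of the same sub-domain — preserving the within-scale
correlation the summative scores depend on. Defaults m = 10, cycles = 10;
the calibration simulations use m = 5, cycles = 5 on 300×4 matrices, which
is where the bias result (< 0.01 on the [0,1] scale under 25% MCAR) is
measured. Observed cells are never altered; all draws flow from one seed
via `SeedSequence` spawning, one child per completed dataset.

Rubin pooling: Q̄ = mean of estimates, B = their sample variance (n−1),
T = W̄ + (1+1/m)B, df = (m−1)(1 + W̄/((1+1/m)B))²; m = 1 or B = 0
degenerate to T = W̄ with infinite df.

## Cluster-robust inference

All subgroup and regression uncertainty allows arbitrary within-town
correlation. Subgroup means use the CR1 sandwich for a mean (factor
G/(G−1)) with t(G−1) intervals, implemented directly and cross-checked
against constant-only cluster OLS; two-group comparisons are Wald t-tests
from a cluster-robust OLS on a group indicator. The provider regression
fits log(competence) — competence is strictly inside (0,1) by
construction of the TCC mapping, so the log is always defined and
coefficients read as approximate proportional differences — on three
nested specifications (workplace; + gender, education; + permanent post,
licensing exam, job title, administrative role, satisfaction), with
reference levels village clinic / female / college-or-above / "no" /
not-satisfied. Perfectly collinear columns are detected by rank-revealing
QR and dropped with a warning (the generator makes education nearly a
function of workplace on purpose). Optional inverse response-rate weights
per facility level implement a response-rate adjustment; they default off.

With nine clusters the t(G−1) reference is a small-G compromise: the
calibration simulations show type-I error near 0.05 and CI coverage near
95% in this regime, but nine clusters is genuinely few and results there
carry a small-G caveat; the CI-coverage property is asserted at ≥ 90%
over 50 replicates.

## The synthetic generator: what it emulates, and what it does not

Defaults are the study conditions: 1355 patients / 333 providers / 2203
charts; 3 counties × 3 towns (9 town clusters, the clustering level of
the standard errors) × 5 villages per town; covariate marginals from the
published sample table (region, gender, facility level, disease mix; age
bands implied by age ~ N(65.8, 9.4)); per-sub-domain endorsement
probabilities equal to the published mean-scored sub-domain levels;
Rasch instruments whose difficulty ranges (±1 logit around a centre
back-solved through the logistic-normal mean approximation, the vignette
centre including the mean provider covariate shift) place the Rasch-scored
sub-domains near their published levels; provider ability shifts of
+0.5/+0.6 logits for township/county workplaces and +0.25 for permanent
posts; registry visits Poisson(5.5) per patient-year with strictly
increasing visit dates; MCAR (default 5%) or MAR nonresponse keyed on a
fully observed covariate. Where the source is silent (marriage, education,
income, insurance marginals; registry rate; instrument spreads) values
were chosen once as field-realistic and are plain configuration.

Known departures from real data, hence limits on what green tests show:
mean-scored indicators are drawn independently within person, so
inter-item correlation — and therefore Cronbach's alpha — is essentially
zero for those scales (real surveys correlate within respondent); chart
and vignette items share a single latent trait per unit with no
differential item functioning; registry measurement values are pure noise
around disease-typical centres; and the published provider recruitment
count for township health centres is internally inconsistent in the
source, so response-rate arithmetic is only defined for county hospitals
(47/50) and village clinics (179/199). Passing tests demonstrate that the
machinery is correct under its stated model, not that the model captures
every feature of field data.

## Determinism and problem sizes

Every stochastic stage draws from one integer seed through a documented
`SeedSequence` splitting scheme (tables: patients, providers, charts,
registry, missingness, in that order; MICE: one child per imputation).
Identical config+seed reproduces every table and the whole report bundle
byte for byte (asserted in tests).

Simulation sizes used by the test suite and the acceptance script are the
package's own choices for desk-scale runs: Rasch recovery at n = 2000 with
10 items (plus a 3-item, n = 80 brute-force cross-check and a
250/1000/4000 consistency sweep); type-I error at 500 replicates of
n = 180 in 9 clusters; MICE bias at 50 replicates of 300×4 matrices;
regression coverage at 50 replicates of n = 600. Larger runs only sharpen
the same comparisons.
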