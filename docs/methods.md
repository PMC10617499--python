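# Methods

## The scientific problem

Whether ADHD symptoms in adulthood share their aetiology with ADHD and
comorbid symptoms in childhood cannot be answered directly without cohorts
that follow children deep into adulthood. An extended-family design
circumvents the gap: when mothers who are themselves twins, siblings,
half-siblings or cousins each have children, the contrast between
mother–child and avuncular (aunt–child) resemblance separates genetic from
environmental transmission. Children of identical twins share as many genes
with their aunt as with their own mother, but share a rearing household only
with the mother; any excess of the mother–child over the avuncular
correlation therefore points to direct phenotypic transmission rather than
shared genes.

This package implements the two model families used for that design and a
mechanistic simulator of the cohort structure they require, so that every
estimate can be validated by parameter recovery on synthetic data. The real
registry data the design targets are access-restricted and out of scope.

## Models

### Multiple-Children-of-Twins-and-Siblings (MCoTS)

The unit of analysis is an extended family: two related mothers (adult-pair
genetic correlation `gamma` of 1, 0.5, 0.25 or 0.125; household indicator
`kappa`, zero for cousins and paternal half-siblings) and their children.
The adult trait has ACE paths `a1, c1, e1`; the child trait `a2, c2, e2`.
Two parameters carry the science:

* `rA` — the correlation between additive-genetic influences on the adult
  trait and those on the child trait (the intergenerational genetic
  correlation, reported as r_G), entering mother–child covariance as
  `0.5 * rA * a1 * a2` and aunt–child covariance as `0.5 * gamma * rA * a1 * a2`;
* `m` — a direct path from the mother's observed phenotype to each of her
  children's phenotypes (phenotypic transmission, generating passive
  gene–environment correlation).

The full expected covariance, including all second-order `m` terms (the
child variance inflation `m^2 * Var(Y_m)`, the sibling covariance induced by
a shared transmitting mother, and the cross-unit covariance induced by the
two mothers' own correlation), is derived in closed form in
`mcots_model.py` and locked against the simulation oracle for every family
configuration.

`rA` is parameterised directly as a bounded correlation rather than through
a cross-generation Cholesky, so that boundary solutions (`rA = 1`) are
representable and profile intervals can terminate exactly at 1.

### Extended bivariate twin model

Two traits per child (early ADHD and one later outcome) get a standard
bivariate ACE Cholesky decomposition; pairs of related children (full
siblings 0.5, half-siblings 0.25, cousins 0.125) replace the classical
MZ/DZ twin contrast, and the shared-environment correlation is fixed to zero
for cousin and paternal half-sibling pairs, who do not share a household.
Internally the A component is rotated to an `(a11, sa2, rG)`
parameterisation with `a21 = rG * sa2`, `a22 = sqrt(1 - rG^2) * sa2` — an
equivalent model in which the genetic correlation `rG` is itself a bounded
free parameter that can be profiled directly.

### Estimation

Both models are estimated by full-information maximum likelihood: each
family (or pair) contributes the multivariate-normal density of its observed
phenotype entries. Units are grouped by (configuration, missingness
pattern); each group's contribution is computed from its sufficient
statistics, so one likelihood evaluation costs one small Cholesky per
distinct pattern regardless of sample size. A single grand mean per variable
is estimated (inputs are residualized, so means are near zero). Confidence
intervals are profile-likelihood: the interval endpoint is where the
deviance rises by the chi-square(1) critical value with all other parameters
re-optimized, and an endpoint is reported exactly at a parameter bound when
the profile never reaches the critical rise before it. Nested models are
compared by likelihood-ratio tests, with a flag when the constrained
parameter is a variance on the boundary of its space (the naive p-value is
then conservative).

## Synthetic cohort generator

The generator is mechanistic, not a draw from the models' implied
covariance — that independence is what makes the closed-form covariances
testable against simulation moments:

* each mother carries standard-normal genetic scores for the adult trait
  and, correlated `rA` within person, for each child trait; scores are
  correlated `gamma` across the adult pair (cross-person cross-trait
  `gamma * rA`);
* each child receives half its mother's score, half an independent founder
  father's score, and a Mendelian segregation deviate of variance 1/2
  (one father per nuclear unit, so within-unit children are full siblings);
* shared environments are drawn per household (adult pair if they grew up
  together; nuclear unit for children), unique environments per person;
* the child phenotype adds `m` times the mother's phenotype;
* covariate effects (maternal age, parity, birth year, child sex) are added
  so residualization has something to remove; missingness is applied
  completely at random per measure.

Study-default settings mirror the cohort the design targets: 12,735 mother
pairs (25,470 mothers against the cohort's 25,469), ~1.2 children per
mother, maternal age truncated-normal (mean 29.97 y, s.d. 4.21, bounds
17–45), 51% male children, and per-outcome generating `rA` set to the
published point estimates (ADHD 0.55, ODD 0.80, conduct 0.44, anxiety 0.72,
depression 1.0). Values the source does not state are synthetic defaults
chosen once: the relationship mixture (full-sibling mothers dominate, twins
rare), 20% per-measure missingness, adult ACE shares (0.35/0.05/0.60,
a moderate-heritability adult trait), child ACE shares (0.6/0.1/0.3),
transmission `m = 0.1`, and an adult↔age-5 `rA` of 0.55 for the age-5
ADHD column. Each outcome is simulated as its own bivariate system with the
maternal trait — outcomes are conditionally independent given the mother —
because the analyses fit five separate models; a joint five-outcome child
model is deliberately not imposed.

What the generator does **not** emulate: item-level measurement (phenotypes
are continuous Gaussian scores; an optional thresholded-Gaussian item layer
exists for testing scale scoring), assortative mating, sibling imitation,
rater bias, zygosity misclassification, registry linkage error, informative
missingness, and father phenotypes (fathers are unmeasured independent
founders). Passing recovery tests therefore shows the estimator is correct
under the stated generative assumptions, not that those assumptions hold in
any real cohort.

## Numerical choices

* Optimizer: bounded L-BFGS-B with numerical gradients; function tolerance
  1e-9, gradient tolerance 1e-5; five jittered starts by default (the first
  start is deterministic). Recovery studies use one start — multi-start and
  single-start solutions were indistinguishable across replicates.
* Paths `a, c` are bounded at zero (sign-fixing the latent factors), `e` at
  a small positive floor so the covariance stays positive definite;
  correlations live on [-1, 1] directly so boundary solutions are exact.
* A non-positive-definite covariance during optimization returns a large
  penalty (configurable to a hard error), keeping the optimizer inside the
  admissible region.
* Profile endpoints are located by bracketing plus Brent root-finding
  (endpoint tolerance 5e-3), with nuisance refits warm-started from the
  nearest profiled point; a non-monotone profile falls back to the widest
  bracketing solution with a logged message.
* Children within a nuclear unit are exchangeable under the model, so their
  values are sorted within the family vector; this makes the likelihood
  bitwise invariant to input row order without changing its value. Raw
  moment comparisons disable this canonicalisation (sorted coordinates are
  order statistics).
* Within-scale item missingness is prorated when at least 80% of items are
  answered (sum scaled by `n_items / n_answered`, rounded half to even),
  otherwise the score is missing.
* Phenotypic-correlation intervals use Fisher's z; family clustering is
  ignored by default, with a conservative option that uses the number of
  distinct families as the effective sample size.

## Problem sizes

Validation sizes were chosen to keep each suite desk-sized while holding
Monte-Carlo error well inside each tolerance: covariance-oracle checks use
2–6 × 10^5 families per configuration (sampling s.d. of a covariance entry
≤ 0.003 against a 0.01 tolerance); recovery checks in the test suite use 20
replicates of 3,000 families (the acceptance script reruns them at 50
replicates of 5,000); null calibration of the likelihood-ratio test uses
400 replicates of 1,000 families in a twin-and-cousin mixture; kinship
checks drop alleles at 10,000 independent loci.

## Known limitations

* Adult cousin pairs' shared environment is constrained to zero like the
  child-generation rule; the source does not state its choice for the adult
  univariate models.
* Whether the original analyses freely estimated `m`, and whether the
  likelihood unit for the twin models was the dyad or the whole sibship, is
  not documented in the available text; here `m` is free by default and the
  extended twin model accepts either extracted dyads (`mode="all"` or
  `"one"`) or externally supplied pair tables.
* The LRT boundary flag covers variances fixed at zero; mixture-chi-square
  corrections are not implemented.
* No sex-moderation, dominance (ADE), ordinal-liability, or multivariate
  (five-outcome joint) variants.
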