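# Methods

`sdqtransitions` implements a population-level analysis of how children's
behavioural-difficulty profiles change across developmental waves, using
parent-reported Strengths and Difficulties Questionnaire (SDQ) data. The
real cohorts this kind of analysis targets (national birth cohorts such
as the UK Millennium Cohort Study) are access-restricted, so the package
pairs the analysis pipeline with a synthetic-cohort generator that plants
known cluster structure, transition dynamics, and covariate effects,
giving every stage a ground truth to be tested against.

## SDQ scoring and partitioning

The parent SDQ has 25 items in five 5-item subscales (emotional symptoms,
conduct problems, hyperactivity, peer problems, prosocial behaviour),
each item scored 0/1/2. Subscale scores are item sums in 0–10; the
prosocial subscale is reverse-scored (`antisocial = 10 − prosocial`) so
higher always means more difficulty. Children with any incomplete SDQ are
excluded from scoring.

Published three-band cutpoints classify each subscale as
normal/borderline/abnormal. The cutpoints ship as editable package data
(`data/default_bands.yaml`, Goodman's parent 4–17 bands with prosocial
expressed on the reversed scale); the boundary convention is that a score
equal to the upper normal cutpoint is still normal, and one equal to the
upper borderline cutpoint is still borderline. A child with all five
bands normal is **non-elevated**; any borderline-or-abnormal band makes
them **elevated**. All clustering operates on the elevated group only:
including the non-elevated majority would flatten the space into a
single severity axis and drown out profile differences.

Standardisation (z-scoring) is computed within the group handed to it —
in the pipeline, each wave's elevated, outlier-screened children — with
the sample-SD (n−1) convention, configurable via `ddof`.

## Outlier screening

Within each (wave, partition label) stratum two rules run in parallel on
the same input and their flag sets are unioned:

- **univariate**: any subscale value more than `k_sd` (default 3)
  standard deviations from that subscale's *median* (a literal
  median-centred, SD-scaled rule; strict inequality at the boundary);
- **multivariate**: squared Mahalanobis distance to the stratum mean
  under the classical sample covariance exceeding the χ²(df=5) quantile
  at `alpha` (default 0.999 — conservative, and exposed in the API since
  screening severity is a judgement call).

Parallel-and-union was chosen over sequential application because it is
order-invariant. Robust covariance (MCD) is deliberately not used; the
classical estimator keeps the rule transparent and matches common
practice for light contamination. Both rules are scale-equivariant.

## Embedding and cluster selection

Each wave's z-scored elevated group is projected to two dimensions with
UMAP using many neighbours (`n_neighbors = 50`, suppressing fine,
noise-driven structure), a small `min_dist = 0.01` (dense, well-separated
clusters), and the correlation metric (profiles matter by *shape*, not
overall severity). The embedding is deterministic given its seed
(single-threaded exact mode) and is fit once per wave; k-means
(k-means++ seeding, 10 restarts, seeded) partitions the embedded points.

A candidate number of clusters k (searched over 2–10 by default) is
accepted only if it satisfies three criteria:

1. **separation** — mean silhouette > 0.5, with every per-cluster mean
   silhouette positive;
2. **Calinski–Harabasz steep increase** — candidates are ranked by the
   relative forward jump `(CH(k) − CH(k−1))/CH(k−1)`. "Steep increase"
   has no canonical operationalisation; the relative forward jump is
   deterministic, dimensionless, and prefers the k at which adding a
   cluster buys the most separation. The smallest k in the range has no
   backward difference and ranks last; `ch_rule="max_ch"` switches to
   plain CH maximisation.
3. **bootstrap stability** — for B resamples of the rows (default 1,000)
   k-means is refit on the resampled coordinates and each original
   cluster is matched to the bootstrap cluster with the largest Jaccard
   overlap (computed over distinct children present in the resample);
   every cluster's mean best-overlap must reach 0.85.

The bootstrap refits k-means on the *fixed* embedding rather than
re-embedding each resample: re-embedding 1,000 times is far more
expensive and conflates embedding variance with clustering variance. If
no k passes all three criteria the best candidate is returned with
`accepted=False` and per-k diagnostics.

One behaviour worth knowing: with the correlation metric, a planted
profile peaked on a single subscale can split into sub-shapes driven by
the ordering of its *secondary* subscales (the resulting clusters are
still pure in terms of generating profile). Real SDQ profiles, which
differ on several subscales at once, are less prone to this.

## Transition testing

Children present in two consecutive waves are inner-joined on id (those
lost to follow-up leave all denominators). Each (source group,
destination group) cell's proportion is tested against the equal-split
null `p0 = 1/K`, where K counts **all** destination groups including
non-elevated (with five clusters plus the non-elevated group, K = 6), by
the one-sample proportion z test

    z = (p̂ − p0) / sqrt(p0 (1 − p0) / n)

with a two-sided normal p value, Bonferroni-corrected over all cells of
the wave-pair table. A cell is flagged only when the adjusted p is below
α = 0.05 **and** p̂ > p0: the two-sided test with a direction filter
reports above-chance transitions only. The plain z test tracks the exact
binomial test closely where decisions are made (for exact p ≤ 0.05 and
n ≥ 100 the absolute p difference is below 0.01) and agrees in direction
everywhere; centrally (p near 1) the normal approximation can differ
from the exact test by several hundredths, which never affects flags.

Flagged cells are validated by comparing the transitioning children's
source-wave silhouette scores against the whole source cluster's
distribution with a two-sample Kolmogorov–Smirnov test. If transitions
were an artefact of borderline cluster membership, the transitioning
children would sit in the low-silhouette tail; a non-significant KS test
is reassuring. Cells with fewer than 5 members are skipped with a
recorded reason rather than tested.

## Risk-factor identification

For one flagged elevated→elevated cell, children from the same source
cluster form a binary contrast: destination = the flagged cluster
("transition of interest", outcome 1) versus destination = non-elevated
("control transition", outcome 0); other destinations are excluded.

The modelling pipeline is leakage-guarded — every preprocessing
parameter is a function of the training split only:

1. drop participants missing **more than** 30% of features (exactly 30%
   is retained);
2. stratified 80/20 train/test split;
3. KNN imputation (k = 5 by default) fit on train, applied to both;
4. min-max scaling fit on train (test values may leave [0, 1]; constant
   train features map to 0 with a warning);
5. exhaustive grid search over XGBoost hyperparameters (number of trees,
   learning rate, max depth, min child weight, γ, L1 α) with stratified
   5-fold CV, scored by the unweighted mean of accuracy and F1 (the two
   named objectives, combined symmetrically; a lexicographic variant is
   an easy local change), with `scale_pos_weight` fixed to
   n_negative/n_positive throughout.

Candidate features are then filtered twice:

- **gain thresholding** — sweep the distinct positive gain values; for
  each, refit on train with the surviving features and score on test;
  keep the best-scoring set, ties broken toward fewer features. Because
  the sweep selects on the test split, the reported accuracy/F1 carry
  optimistic selection bias; they are model-comparison scores, not
  unbiased performance estimates.
- **permutation survival** — on the tuned all-feature model, shuffle
  each test column (20 repeats by default) and record the mean accuracy
  drop. A feature survives when its mean drop is positive and exceeds a
  noise floor: the larger of the 95th percentile of the drops of
  zero-gain features and the 1% tail of an empirical null mirrored from
  the *negative* drops. The second component matters in practice:
  boosted ensembles give nearly every feature a little gain, leaving the
  zero-gain set empty, while shuffling a non-informative feature
  perturbs held-out accuracy symmetrically around zero — so the negative
  drops calibrate how large a positive drop chance alone produces.

**Genuine risk factors** are the intersection of the threshold-selected
set and the permutation survivors, subject to a no-information gate: if
the selected-feature model's test accuracy does not beat the
majority-class rate, no feature is flagged — a model that cannot
outperform the trivial classifier provides no evidence for any risk
factor. Without the mirrored floor and the gate, an all-noise contrast
(50 noise features, no planted effects) yields on the order of nine
spurious "genuine" factors per run; with them, spurious discoveries are
rare while planted 1.5-log-odds effects at n = 2,000 are recovered
essentially always.

## The synthetic cohort generator

The generator defines the study conditions for all tests:

- **Groups and items.** Per wave, each child belongs to a latent group
  with a 5-vector of subscale means on the 0–10 difficulty scale (one
  group designated non-elevated, default means ≈ 0.5). For each (child,
  subscale), p = mean/10 plus a Gaussian perturbation with SD
  `profile_dispersion` (default 0.08, shared across the subscale's five
  items so sums separate by profile), clamped to [0, 1]; items are
  Binomial(2, p). The prosocial block uses 1 − p so the reverse-scored
  antisocial sum matches its stated difficulty mean. This item model is
  a stand-in — no generative model of real SDQ items exists in the
  literature this package draws on — chosen because it guarantees legal
  item values and controllable subscale means.
- **Transitions.** Consecutive waves are linked by row-stochastic
  matrices. Covariate effects enter as a multinomial logit: destination
  logits are `log(base row) + Σ coef · covariate`, renormalised; zero
  effects reduce exactly to the base matrix, and structural zeros stay
  zero.
- **Covariates and missingness.** Child-level covariates are normal,
  Bernoulli, or uniform. Cells are masked MCAR at a flat rate or MAR
  with probability `expit(logit(rate) + slope · z(conditioning))`
  (slope 1 by default), keeping the marginal rate near nominal. Truth
  labels are never masked.
- **Default cohort** (`example_spec`): three waves (ages 5/11/17 in
  spirit) with 3/5/3 elevated profile groups plus a non-elevated
  majority (share 0.6 at wave 1), planted above-chance transition cells
  (e.g. 0.23 and 0.21 against a null of 1/6; 0.46, 0.33 and 0.32
  against 1/4), ~37% of each elevated group returning to non-elevated,
  covariate effects of 0.7–0.9 log-odds on two planted transitions,
  5–10% covariate missingness, and 5–10% per-wave dropout. Everything
  is deterministic given the spec seed.

What the generator does *not* emulate: survey weights and stratified
sampling, informative attrition, rater effects and item-level response
styles, and within-group covariance structure beyond the shared
per-subscale perturbation. Passing tests therefore demonstrate that the
pipeline recovers structure of the planted kind at realistic sizes and
noise levels — not that real cohort data contain such structure.

## Problem sizes and numerical choices

The test suite runs the heavy stages at reduced but honest sizes chosen
as the smallest that leave comfortable statistical margins: cluster
recovery over 20 seeded cohorts of 1,500 elevated children with B=100
bootstrap; transition error rates over 200 simulations of 500 children
per source; risk-factor recovery over 20 seeds at n=2,000 with 50 noise
features and a small hyperparameter grid. `scripts/acceptance.py` runs
the full pipeline on a 6,000-child default cohort with B=200. Ties in
k-means are handled by seeded restarts; all randomness flows from
explicit integer seeds; silhouette/CH come from scikit-learn and are
cross-checked against brute-force formula evaluations in the tests.

## Known limitations

- Hard k-means assignments; soft or latent-class clustering is out of
  scope.
- The equal-split null treats destination groups symmetrically; a
  realistic null might weight by destination size.
- The threshold sweep's test-set selection bias (above) is inherent to
  the procedure it implements.
- Band cutpoints are data, not code: analyses of populations where the
  published parent bands do not apply should supply their own table.
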