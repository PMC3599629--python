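# Methods

`scalestep` implements a three-step item-response-theory (IRT) strategy for
judging whether an ordinal rating-scale instrument — a depression
questionnaire, say — supports its intended use of the summed item score as a
severity measure, in samples as small as a few dozen respondents.

## Data model

Responses are a persons × items matrix of 0-based integer category codes
with a boolean missing mask (`ResponseMatrix`). Items may have different
numbers of ordered categories. Nonparametric Step-1 statistics and
Cronbach's alpha use listwise-complete cases (matching how such analyses
report a per-instrument "number of observations"); the parametric models use
full-information likelihood, i.e. every person contributes their observed
items, and only persons with no observations at all are dropped. Sparse
categories can be merged with an explicit monotone recode
(`merge_categories`), e.g. `(0,0,1,1,2,2,2)` collapses a 7-category item to
3 categories.

## Step 1 — Mokken scalability

For items \(X_i, X_j\) the pairwise Loevinger coefficient is
\(H_{ij} = \mathrm{Cov}(X_i, X_j) / \mathrm{Covmax}(X_i, X_j)\), where
Covmax is the covariance of the comonotonic coupling of the two observed
marginals: sort both score vectors descending, pair them rank by rank, take
the covariance. By the rearrangement inequality this is the maximum
covariance attainable over all pairings of the two marginals (the test
suite keeps a brute-force enumeration oracle for exactly this claim). Item
and total coefficients are ratio-of-sums aggregates,

\[ H_i = \frac{\sum_{j \ne i} \mathrm{Cov}_{ij}}{\sum_{j \ne i}
\mathrm{Covmax}_{ij}}, \qquad H = \frac{\sum_{i<j} \mathrm{Cov}_{ij}}
{\sum_{i<j} \mathrm{Covmax}_{ij}}, \]

so \(H\) is also the Covmax-weighted mean of the \(H_i\) (asserted to
1e-12). Perfect Guttman data gives \(H = 1\) exactly: both covariance
matrices are computed with the same dot-product arithmetic, and with
integer codes the float operations are exact. Classification follows the
conventional cutoffs: below 0.3 unscalable, 0.3–0.4 weak, 0.4–0.5 medium,
0.5+ strong.

**Inference.** With n ≈ 60 the asymptotics for H are unreliable, so
intervals are resampling-based: a percentile bootstrap over persons
(default B = 1000, level 0.90; endpoints are order statistics of the
replicate vector), and a permutation null for a single item's \(H_i\)
obtained by shuffling that item across persons (default B = 500).
Permutation preserves both marginals, so the Covmax denominator is
invariant and only the item-versus-rest covariance is recomputed — an
exact shortcut the tests verify against full recomputation. Replicate-level
RNGs derive from (seed, counter), making results order-independent and
reproducible.

**AISP.** The automatic item selection procedure is the greedy bottom-up
variant: seed a scale with the unassigned pair of maximal \(H_{ij}\) among
pairs significantly positive, then repeatedly add the item maximising the
provisional scale's H subject to the item's scalability against the scale
being at least the lower bound c (default 0.3) and significantly positive.
Significance is the one-sided normal test \(Z = r\sqrt{n-1}\) (the
delta-method variance of a covariance under independence); the lower bound
is deliberately not imposed on seed pairs, so an extreme c leaves at most
two-item seeds. Ties break toward the lower item index — output is
deterministic.

**Restscore diagnostics.** Manifest monotonicity: for each item, persons
are grouped by the rest score (total minus the item), merging adjacent raw
rest-score values left to right until each group reaches `minsize`
(default 15; the trailing remainder joins the last group — at n ≈ 60 this
yields the familiar low/median/high grouping). A decrease in
\(\hat P(X_i \ge k)\) from a lower to a higher group exceeding `minvi`
(default 0.03) is a violation, tested one-sided at 5% with a two-proportion
z-test. Invariant item ordering uses the same grouping with the rest score
excluding both items of a pair; items are ordered by overall means, and a
within-group reversal of the conditional means beyond 0.03 × (maximum
code) is a violation, tested with a paired one-sided t-test.

## Step 2 — rating scale model

The RSM is the adjacent-category Rasch model
\(P(X_i = k \mid \theta) \propto \exp\{\sum_{l \le k} (\theta - \beta_i -
\tau_l)\}\) with one location \(\beta_i\) per item and a single sum-zero
threshold set \(\tau\); identification fixes the slope at 1 and the latent
mean at 0 with a free latent SD, so "equal discrimination" means the same
thing here as in the constrained graded model. Under the RSM the raw sum
score is sufficient for the person, which is why the step is worth keeping
even when it fails: it is the model implicitly assumed whenever sum scores
are used. The pipeline's Step-2 gate declares the RSM structure untenable
when the equal-discrimination likelihood-ratio test rejects at 5% **or**
the free fit's max/min discrimination ratio exceeds 3 (both configurable).

## Step 3 — graded response model

The GRM is the cumulative-logit 2PL:
\(P(X_i \ge k \mid \theta) = \mathrm{logistic}(a_i(\theta - b_i - t_k))\)
with common sum-zero thresholds \(t\) (the default, appropriate after any
category merging), or \(\mathrm{logistic}(a_i(\theta - b_{ik}))\) with free
item-specific thresholds. The latent trait is standard normal; the logistic
scaling constant is 1 (no 1.7), so discriminations are on the logistic
metric. The nesting chain equal-slope/common-t ⊆ free-slope/common-t ⊆
free-slope/free-t is asserted on fitted log-likelihoods.

**Estimation.** Marginal maximum likelihood by EM over a fixed 41-node
Gauss–Hermite grid (21 nodes in replicated simulation experiments — at
these sample sizes the difference is far below sampling noise). The E-step
computes each person's posterior over nodes; the M-step improves the
expected complete-data log-likelihood with L-BFGS on an unconstrained
parameterisation (log slopes; thresholds as a base location plus log gaps,
which enforces ordering). As a generalised EM this makes the marginal
log-likelihood non-decreasing every iteration; the trace is stored on the
fit and asserted in tests. Convergence is a log-likelihood change below
1e-5 (default), capped at 500 iterations with a flagged fit on
non-convergence; slopes above 20 flag a Heywood-type degeneracy. Starting
values come from the observed cumulative proportions through an inverse
logit. Category probabilities are floored at 1e-12 throughout.

**Standard errors** are from a central finite-difference Hessian of the
marginal log-likelihood (step 1e-4) in natural coordinates (slopes,
locations, free thresholds), with a pseudo-inverse and a note on the fit if
the observed information is near-singular. Empty top categories are dropped
globally (common thresholds) or compressed per item with a recode map
(free thresholds).

**Derived quantities.** Person scores are EAP posterior means with
posterior-SD uncertainties over the quadrature grid, using observed items
only; optional recentering subtracts the mean person estimate jointly from
persons and item locations (the "corrected location" convention). Item
information is Samejima's graded form
\(I_i(\theta) = a_i^2 \sum_k (w_{ik} - w_{i,k+1})^2 / P_{ik}\) with
\(w_{ik} = P^*_{ik}(1 - P^*_{ik})\); for a dichotomous item this reduces to
the 2PL \(a^2 P(1-P)\). Relative item information is the trapezoidal
integral of \(I_i\) over the default grid (−4 to 4, step 0.05) as a
percentage of the integrated total — a documented choice, since "share of
information" has no canonical definition; display buckets round to the
nearest 5 with a "<5" floor while retaining the raw share.

## Evaluation extras

Cronbach's alpha (unbiased variances, complete cases) is included as the
classical comparator. Rank intervals map a person's Wald CI on the latent
scale to ranks by counting other scored persons strictly below each
endpoint (ties in own-rank break by person index); relative ranks are
percentages of the scored count. Cross-instrument agreement is the
Spearman correlation of person estimates plus the fraction of persons
whose ranks differ by ≥ 15 units. Profile flags mark constant responders
and low person-fit responders (standardised pattern log-likelihood at the
EAP estimate below −2); flags are advisory — aberrant persons are reported,
never removed.

## Synthetic data

Generators return the truth they used and are bit-reproducible given a
seed. Missingness is completely at random (the emulated study's handful of
missing cells carries no mechanism information); aberrant responders
(constant, uniform-random) are appended after the coherent persons and
flagged in the truth. `generate_study_like` emulates the target setting:
61 respondents, three blocks (9 items × 5 categories, 9 × 4, 10 × 7)
driven by one shared severity trait, 0–4 missing cells per block, one
constant and one random responder. Block discriminations span 0.27–2.85
and locations −0.6 to 1.8. The shared trait SD is 1.75 rather than 1: a
clinical convenience sample mixing remitted and severely ill patients is
wider than a unit normal, and under a unit trait the block parameters above
imply total scalabilities near 0.30 for every block, erasing the
strong-versus-weak contrast the emulated setting exhibits; with SD 1.75 the
self-rating blocks come out medium-to-strong (H ≈ 0.48–0.51) and the
7-category observer block weak (H ≈ 0.33), with sparse observer-scale top
categories. This was fixed once when the generator was written.

What the generator does **not** emulate: rater anchoring effects (real
observer scales concentrate on even-numbered anchor categories),
informative missingness, multidimensional structure inside a block, and
respondent-specific response styles beyond the two aberrant types. Passing
tests therefore demonstrate correctness of the statistical machinery under
a clean unidimensional graded-response world, not robustness to every
artefact of real questionnaire data.

## Numerical choices and limitations

- Quadrature: 41 Gauss–Hermite nodes default; replicated simulation
  experiments use 21. EAP scores use the fit's own grid.
- Percentile (not BCa) resampling intervals; BCa is a possible extension.
- Restscore grouping merges whole rest-score values; under heavy ties a
  group can absorb most of the sample, in which case the report flags the
  item as having insufficient groups rather than fabricating comparisons.
- The equal-discrimination LR test's chi-square reference is asymptotic;
  at n ≈ 60 treat borderline p-values with caution (the pipeline also
  gates on the discrimination ratio for this reason).
- Free-threshold fits on items with empty interior categories recode the
  item; person scoring transparently applies the stored recode map.
- Rank intervals assume approximate normality of the EAP sampling
  distribution; they are illustrations of measurement precision, not
  formal confidence procedures.
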