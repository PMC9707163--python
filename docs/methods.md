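# Methods

This note documents the statistical procedure `stylemap` implements, the
assumptions behind it, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
conventions that make runs reproducible.

## The model

The unit of analysis is a *group corpus*: a set of comments written by
members of one online community. The working hypothesis is that a
group's collective self-understanding — its norms, values, and purpose —
leaves a trace in the *style* of members' writing (function-word
composition), independently of topic. The pipeline operationalizes
"style distance" between two groups as the separability of their
per-document style vectors.

**Featurization.** Scoring is dictionary-based bag-of-words: a document's
score on category *c* is 100 × (tokens matching any of *c*'s patterns) /
(total tokens). A token may increment several categories; a literal
dictionary entry takes precedence over stem (`word*`) entries for the
same surface form; computed categories (six-letter-plus words,
apostrophe contractions) are predicates on the token. This ignores word
order, negation scope and polysemy by design — the same simplification
the LIWC family of tools makes.

**Dissimilarity.** For each unordered pair of groups a balanced binary
classification task is built: each class contributes min(n_a, n_b)
comments (random under-sampling), rounded **down to an even count** so
the 50:50 train/test split is integral in both halves. This even-down
rule is what makes the pairwise totals reproducible from the per-group
counts alone. An extremely randomised tree ensemble is fit on the train
half and the AUC of its scores on the held-out half is the dissimilarity.
AUC is used rather than accuracy because it is a calibrated two-sample
separability measure: 0.5 = exchangeable samples, 1.0 = disjoint
supports. It is *not* a metric — it saturates at 1, need not satisfy the
triangle inequality, and its diagonal baseline is 0.5 — which has two
consequences handled explicitly below (diagonal convention, negative
eigenvalues).

**Embedding.** Classical (Torgerson) MDS: square the dissimilarities,
double-center (B = −½ J D² J, J = I − 11ᵀ/n), eigendecompose B, and take
the top-k eigenvectors scaled by √eigenvalue. The classical form is used
because the eigenvalue spectrum *is* the dimensionality diagnostic (scree
plot); iterative stress-majorization MDS has no such spectrum. The
residual misfit of the embedding is reported as a normalized stress,
never hidden.

**Clustering.** Ward linkage on the dissimilarity matrix (entries
treated as Euclidean distances via the Lance–Williams recurrence — the
standard practice, with the caveat that AUCs need not embed exactly),
plus k-means on the rows of the symmetric matrix, where each group's
feature vector is its profile of dissimilarities to all groups. Rows
rather than MDS coordinates are the default because clustering the raw
matrix does not inherit the embedding's truncation error; users can
substitute coordinates.

**Value regressions.** Each of ten personal-value scores (per-post
percentage of value-lexicon matches, averaged per group, unweighted by
post length) is regressed on the two MDS coordinates: OLS with
intercept, unstandardized slopes, t-based 95% CIs on n − 3 degrees of
freedom, R², overall F-test p. Ten raw p-values are reported without
multiple-testing correction; with n = 15 groups these regressions are
descriptive, not confirmatory.

**Temporal tracking.** The focal corpus is partitioned into UTC calendar
years (half-open intervals). Anchor–anchor AUCs are computed once and
reused for every slice, so any movement of the focal point is
attributable to the focal group alone. Each per-slice embedding is
aligned to the earliest slice's embedding by orthogonal Procrustes on
the anchor points (rotation/reflection and translation, no scaling —
scaling would absorb real global drift into the alignment). Alignment is
necessary because eigenvector sign and rotation are arbitrary across
independent MDS runs; without it per-year coordinates are not
comparable. Per-axis trends are Spearman rank correlations against time.

## Parameters that matter

| parameter | default | rationale |
|---|---|---|
| minimum words per comment | 50 | standard floor for stable dictionary percentages; shorter posts make percentage features too coarse |
| style categories | 41 | function-word/style set size; the bundled open lexicon has 39 dictionary + 2 computed categories |
| train fraction | 0.5 (fixed) | the balanced 50:50 split is load-bearing for the even-down sampling arithmetic; a larger test half gives a lower-variance AUC |
| ensemble size | 100 trees | scikit-learn default; AUC estimates are insensitive to it at these sample sizes (50 used in the heavier simulations for speed) |
| split candidates | √p features | scikit-learn default for classification |
| k (dimensions) | 2 | supported by the scree in both the published design and the synthetic conditions |
| k (clusters) | 5 | the group-type taxonomy under test; WSS curve over k = 2…9 reported alongside |
| k-means restarts | 25 | exhaustive-search agreement on all small fixtures |
| slice minimum (per class) | 100 | below ~100 balanced samples per class the held-out AUC is too noisy to place a slice |
| diagonal convention | 0 | required by double-centering; the raw AUC baseline 0.5 is available as `diagonal="half"`, and d = max(0, 2·AUC − 1) as an optional transform |

All randomness flows from one master seed; per-pair and per-stage seeds
are derived by SHA-256 over (seed, stage, sorted labels), so results are
independent of iteration order and stable across platforms. Pair
computations are independent by construction; the sequential
implementation is the reference semantics and a parallel map would
reproduce it exactly.

## Numerical conventions

- **Tokenizer**: lowercase; tokens are maximal runs of letters/digits
  with internal apostrophes allowed; everything else separates. This
  makes the 50-word rule and all percentages deterministic.
- **Cleaning rule order** (first match wins): bot author → deleted
  author → deleted/removed body → URL-only → URL stripping → minimum
  words. Reports are exact: input = output + Σ removals.
- **Bot heuristic**: author name ends in "bot" (case-insensitive) or is
  blacklisted. Self-identification has no canonical operationalization;
  this is configurable.
- **Titles**: when a record carries a title it is scored jointly with
  the body (concatenated with one space).
- **Positive class**: the lexicographically larger group label, fixing
  the AUC orientation (symmetric in expectation, deterministic in fact).
- **MDS sign convention**: each coordinate column is flipped so its
  largest-magnitude entry is positive.
- **Negative eigenvalues**: reported in the scree (they diagnose the
  non-Euclidean part of the AUC matrix), excluded from coordinates; no
  additive-constant repair by default.
- **Ward/k-means tie-breaks**: delegated to scipy/scikit-learn; merge
  and assignment determinism is guaranteed by seeding and verified
  against from-scratch oracles on small fixtures.
- **Spearman p-values**: exact by full permutation enumeration for
  n ≤ 9 (covering the nine-slice yearly design; 9! = 362,880 is
  enumerable, 10! is not worth the cost), t-approximation on n − 2 df
  otherwise. Ties get average ranks.
- **Constant-outcome regression**: slopes 0, R² = 0, p = 1 (statsmodels
  leaves them undefined).
- **Slice exclusion**: dropping a year recomputes the trend on the
  remaining aligned coordinates; the alignment reference is kept so the
  remaining coordinates are unchanged.

## The synthetic generator

`stylemap.synthgen` draws each document as an i.i.d. bag of tokens:
token → category by the group's emission probabilities (remainder mass
to an unmatched "filler" category), then a uniform token from that
category's vocabulary. Vocabularies are disjoint across categories and a
matching `.dic` is generated, so lexicon scoring recovers the emission
percentages *exactly* — scoring error is zero by construction and any
test failure localizes to the statistics, not the featurizer. Document
lengths are negative-binomial shifted to a 50-token minimum
(heavy-tailed like forum comments; always passes cleaning).

Archetype sets place type centers on a circle in a 2-D *latent style
space*: two fixed disjoint-support directions in category space are
modulated multiplicatively, so groups differ in which categories they
over- and under-use. Within-type groups are small perturbations (sd 0.01
multiplicative) of the type center. The `separation` knob scales the
circle radius. The simulation studies use **separation 0.3**, which
places between-type AUCs in roughly 0.6–0.95 — the working regime of the
method, comparable to what real group corpora produce — while
within-type AUCs stay near 0.5. This choice is substantive: because AUC
saturates at 1, pushing separation higher drives *all* between-type
dissimilarities to the same ceiling value, and the configuration
degenerates toward a regular simplex whose scree has four comparable
eigenvalues instead of two. Archetype recovery (ARI = 1 at a Ward cut of
5) holds from separation ≈ 0.3 upward; the planar scree signature only
below saturation. Drift corpora interpolate emission probabilities
linearly between two latent positions across slices.

What the generator does **not** emulate: grammar, topic content,
author-level dependence (documents are exchangeable within a group),
bursty posting, vocabulary growth, or correlated category usage beyond
the two latent axes. Passing the recovery tests therefore shows the
*statistical machinery* is correct under its own assumptions — it does
not validate the psychological claim that style reflects group
self-understanding on real data.

## Problem sizes

The simulation studies run at desk scale by choice: 15 groups × 120
documents for structure recovery, 20 replicates × 1,000 documents per
class for null calibration, 14 anchors × 100 documents and 8 drift
slices × 100 documents for trajectory recovery, 50–100 trees per
ensemble. At these sizes the Monte-Carlo bands in the tests are
comfortably wide of their thresholds (null mean AUC lands within ±0.01
of 0.5; drift |ρ| ≥ 0.95; anchor drift ≈ 0.03 on a ~0.45 coordinate
scale).

## Known limitations

- AUC dissimilarities are bounded and non-metric; embeddings carry
  irreducible stress that is reported but not corrected.
- The bundled style and value lexicons are open stand-ins of the right
  shape and size, not clones of the proprietary dictionaries; absolute
  percentages depend on the lexicon and are not comparable across
  lexicons.
- k-means on matrix rows includes the diagonal entry, which mildly
  separates every group from all others under the zero-diagonal
  convention; with 15 groups this is a 1/15 share of the feature vector.
- Procrustes anchoring assumes the anchors themselves are stationary;
  real reference communities drift too, and that drift is absorbed into
  the focal trajectory.
- Yearly slicing assumes enough volume per year; sparse early years are
  skipped (or excluded post hoc) rather than widened.
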