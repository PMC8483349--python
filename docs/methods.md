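# Methods

`eaccd` builds *ordered prognostic grouping systems* from censored,
cause-specific survival data that has been stratified into factor-level
combinations (the subsets of cases sharing one level of every studied
factor, keyed in the registry style `T1aN0M0A0S1`). The goal is a small
number n\* of ordered groups whose survival curves are well separated and
whose ordinal index predicts survival as accurately as the data allow — a
trade-off between stratification and prediction, not a pure fit.

## The pipeline

The fit proceeds in four steps.

**1. Initial dissimilarities.** Each combination's survival is summarised
by its Kaplan-Meier estimate Ŝ(t) completed beyond a horizon τ with an
exponential tail e^(−λt), λ = −log Ŝ(τ)/τ, so the completed curve is
continuous at τ. τ is the largest time at which *every* combination's KM
estimate is still defined (the minimum over combinations of the largest
observed time); a plain Mann-Whitney estimator that requires curves to
reach zero is unstable under censoring, and the tail completion removes
that instability. The Mann-Whitney parameter P(T₁ > T₂) — the probability
a random subject from combination 1 outlives one from combination 2 — is
then estimated as D\_e = A + B + C:

* A = −∫₀^min(τ₁,τ₂) S₁(t) dS₂(t) (Lebesgue–Stieltjes against the step
  part of curve 2),
* B covers the horizon gap (zero when τ₁ = τ₂, the analysis default),
* C = λ₂/(λ₁+λ₂) · e^(−(λ₁+λ₂)·max(τ₁,τ₂)) (the joint tail mass).

The initial dissimilarity is |D\_e − 0.5| ∈ [0, 0.5]. For exact
exponential curves with rates λ₁, λ₂ the three terms telescope to
λ₂/(λ₁+λ₂) for any τ, which is what makes the synthetic cohorts below
analytically checkable.

*Tie convention.* Whenever curve 1 is evaluated at an atom of curve 2, the
mean of its left limit and value is used — ties in failure time get half
credit. The source formulation leaves the tie convention open; this choice
makes D\_e(c₁,c₂) + D\_e(c₂,c₁) = 1 and D\_e(c,c) = 0.5 hold exactly (not
just up to tie mass) and reduces to the plain Stieltjes sum whenever jump
times are distinct. Degenerate cases are fixed by convention: a curve with
no events by τ has λ = 0 (flat tail), and when both arms have λ = 0 the C
term takes its equal-rates limit 1/2; a curve that reaches zero by τ
carries no tail mass (B and C terms involving it are 0).

**2. Learned dissimilarities.** The initial matrix is refined by a
co-clustering ensemble: for k = 2 … M−1 the M combinations are partitioned
by the two-phase Partitioning Around Medoids algorithm (greedy BUILD
seeding, then best-improvement SWAP until no exchange lowers the
objective), and the learned dissimilarity of a pair is the fraction of
partitions separating it. The published description of this step defers to
an ensemble whose parameters (number of runs, randomisation, k
distribution) are not recoverable; the deterministic equal-weight k-sweep
is this package's documented construction, chosen for reproducibility and
zero tuning. A bootstrap variant (resample combinations, rerun, average)
is available behind an explicit seed. All PAM tie-breaks go to the lowest
index (BUILD candidates, SWAP pairs, assignment of equidistant items), so
the default ensemble is bit-reproducible. PAM is a heuristic: on
unstructured random matrices it can rest at a single-swap-stable local
optimum above the exhaustive k-medoids optimum; on the near-block matrices
that survival dissimilarities actually form it reaches the optimum on
every fixture in the test suite.

**3. Minimax-linkage clustering.** The learned matrix is clustered
agglomeratively with minimax linkage: merge the pair of clusters whose
union has the smallest minimax radius min_p max_x d(p, x); the minimiser p
is the cluster's prototype — an actual combination at the centre of a ball
of radius equal to the merge height, which keeps every internal node of
the dendrogram interpretable. Equal-radius merges break to the
lexicographically smallest cluster-id pair and equal prototypes to the
lowest leaf index. Minimax linkage can invert heights; inversions are
flagged, and cutting is by merge order (undo the last k−1 merges), so they
never affect the groups.

**4. C-index knee selection.** For each k up to a cap (default
min(M, 30), for readable curves), the dendrogram is cut, clusters are
renumbered 1…k by decreasing pooled KM survival at the ordering horizon
(60 months — five-year rates are the field's standard summary; ties break
by decreasing mean observed time), and Harrell's concordance between the
ordinal group number and observed survival is recorded; C(1) = 0.5 by
convention. n\* is the knee of this curve: the k whose point lies farthest
(perpendicular distance) from the chord joining the curve's endpoints,
ties to the smallest k, with an explicit override for exploring around the
knee. The ordinal group number is used as the risk score — the grouping
itself, not a refitted score, is what is being evaluated.

Harrell's C counts pairs with distinct observed times whose earlier time
is an event; the pair is concordant when the earlier time carries the
strictly higher risk score, score ties count 1/2, and equal observed times
are excluded. The implementation counts in O(k·n log n) for k distinct
scores and matches an O(n²) pair scan to 1e−12 in the tests.

## Validation toolkit

* **Adjacent groups** are compared with a univariate two-group Cox fit
  (Newton iteration on the partial likelihood to score < 1e−8; Breslow tie
  handling by default because month-granular registry times are heavily
  tied, Efron behind a flag) and the logrank test. Pairs with all events
  in one arm are flagged inestimable rather than reported at a diverging
  estimate. All CIs are 95%, all tests two-sided.
* **Two groupings of the same cases** are compared by the difference of
  their Harrell C-indices. Both estimates share their permissible pairs,
  so the variance of the difference comes from the Hájek projection of the
  ratio-of-U-statistics form (per-case influence values); a leave-one-out
  jackknife is provided as a cross-check and agrees within 10% on the test
  fixtures, and the analytic standard error tracks a 1000-resample
  bootstrap within 15%.
* **Association** between two ordinal assignments: contingency table with
  totals, and mid-rank (tie-corrected) Spearman correlation.
* **Risk-category distributions**: given a partition of group numbers into
  categories (e.g. low/medium/high), the per-factor-level case
  distribution across categories.

## Cohort handling

Rows with a missing or inadmissible factor level are dropped (complete
cases only) and counted. Numeric factors can be recoded by right-closed
cut points (an age cutoff of 70 sends 70 to the younger level, 71 to the
older). Combinations with fewer than 25 cases (configurable) are removed
before fitting — below that the KM tails are too noisy for the
dissimilarity to be meaningful. The temporal split is purely year-based:
training = diagnosed before the cutoff year, validation = diagnosed in it;
the rare-combination filter applies to the training side only, and
validation cases whose combination is absent from the filtered training
set are excluded and counted, so training + validation + exclusions
exactly partition the input.

## Synthetic cohorts

The generator emulates the structure of a registry extract: tens of
combinations, per-combination samples ≥ 25, exponential cause-specific
event times, administrative censoring at a follow-up horizon, an
independent Uniform(0, horizon) censoring stream applied to a fraction of
subjects, and uniform diagnosis years for the temporal split. The standard
study conditions are 24 combinations over 3 factors, 4 true groups with
rates (0.002, 0.006, 0.02, 0.06) per month (adjacent hazard ratios 3 to
10/3), n = 300 per combination, a 150-month horizon, 20% extra censoring,
seed 20240901. Exponential times were chosen because the effect size then
has the closed form λ₂/(λ₁+λ₂), so every stage of the pipeline can be
checked against algebra; a Weibull shape option exists for robustness
checks. Each combination draws from its own child seed, so editing one
combination leaves the others' draws unchanged.

What the generator does *not* emulate: real registries have non-uniform
case mixes across combinations, non-exponential and non-proportional
hazards, cause-of-death misclassification, and factor levels correlated
with censoring. Passing the recovery tests therefore shows the pipeline is
correct and well calibrated under its own assumptions, not that a
particular clinical cohort would yield the same grouping.

## Numerical choices and limitations

* Right-continuous convention throughout: S(t) = P(T > t), evaluation at a
  jump returns the post-jump value, matching P(T₁>T₂) = E[S₁(T₂)].
* The A and B integrals are computed exactly (jump sums and piecewise
  exponential segments), not on a grid; the dense-grid integration lives
  only in the test oracles.
* System files are canonical JSON (sorted keys, full-precision floats), so
  identical inputs give hash-identical artifacts; dissimilarity matrices
  round-trip bit-exactly through their CSV form.
* Problem sizes in the test suite and the reproduction script (24
  combinations, 300 cases each, 20 seeds) are chosen so the planted
  structure is comfortably identifiable while the whole suite runs in
  minutes on one CPU.
* Zero-time cases are retained (the KM estimator handles them); no left
  truncation and no competing-risks estimators — the event flag is assumed
  to encode cause-specific death already.
* No multiple-testing adjustment is applied to the adjacent-pair tests;
  they are reported unadjusted, as is conventional for this kind of
  descriptive stratification check.
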