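# Methods

## Consensus statistics on ordinal scales

Let a panel of `q` raters score an item on an ordered scale with numeric
rank values `x_1 < … < x_n`, and let `p_i` be the fraction of raters at
rank `i`, `μ = Σ p_i x_i` and `d_x = x_n − x_1` the scale width. The
package computes

* Shannon entropy `H = −Σ p_i log2 p_i` (bits; `0·log 0 ≡ 0`),
* consensus `Cns = 1 + Σ p_i log2(1 − |x_i − μ|/d_x)`,
* dissension `1 − Cns`,
* strength-of-consensus `SoC(r) = 1 + Σ p_i log2(1 − |x_i − r|/(2 d_x))`
  for a reference rank `r` on the scale.

Assumptions and conventions:

* **`d_x` is the full scale width**, not the observed response range. This
  is what makes the statistics comparable across panels and exactly
  reproduces the published worked example this implementation is validated
  against.
* **Population standard deviation** (divisor `q`, not `q − 1`) is reported
  alongside, again matching the validation table. The std is descriptive
  only; no inference is built on it.
* **Terms with `p_i = 0` contribute exactly zero** — no log is evaluated,
  so the extremes never produce `log 0`.
* Ranges: `Cns ∈ [0, 1]`, with 1 iff unanimous and 0 for an even split on
  the two extremes. `SoC(r) ∈ [0, 1]`: the halved denominator bounds the
  log argument below by 1/2, and the minimum 0 is attained exactly when
  every response sits on the extreme rank opposite `r`. (A claim of an
  open interval `(0, 1]` sometimes made for this statistic is not correct;
  the zero case is degenerate but attainable.)
* Both statistics are invariant under positive affine relabeling of the
  rank values (`x → a·x + b`, `a > 0`) and depend only on counts, not on
  which rater said what. Symmetric count vectors give palindromic SoC
  profiles.
* All computation is double precision and unrounded; three-decimal
  rounding (round-half-even) is applied only in human-readable report
  tables.

A known caveat of the worked-example table used for validation: its two
middle consensus entries (0.425, 0.605) do not agree with direct
evaluation of the consensus formula (≈0.434, ≈0.751), while every one of
its twenty strength-of-consensus cells reproduces exactly. The formula is
treated as authoritative; the implementation is additionally checked
against an independent term-by-term brute-force oracle over all 5-rank
count vectors with `q ≤ 6`.

## Sample-size weighting (Gompertz)

`w(q) = exp(−α·exp(−β·q))` multiplies a consensus or SoC value to discount
small panels. Defaults `α = 0.725`, `β = 0.05` implement the policy
"panels of 100+ raters are not penalized (w ≥ 0.995); an empty panel is
penalized to about half". Note `exp(−0.725) ≈ 0.484`, i.e. the actual
floor is a 51.6% penalty — the stated "50% maximum" is honored to ≈2%
slack rather than re-fitting α. Both parameters are exposed per metric;
they are context constants, never fitted from data. The factor multiplies
the whole statistic, not individual summation terms, and the same factor
can optionally be applied to the consensus scalar.

Per-rank weights are a separate, multiplicative adjustment of a SoC
profile with no renormalization: unit weights are the identity, zero
weights act as selectors, and the weighted profile stays in `[0, 1]` when
weights are `≤ 1`. No normalization rule is imposed because none is
canonical; callers who need comparability across metrics should keep
weights on a common scale.

## CCE vector assembly and normalization

A schema is an ordered list of metric specs — quantitative (scalar copied
verbatim; optionally flagged binary) or qualitative (a rank scale plus
optional weighting). Layout is quantitative metrics first, then one SoC
block per qualitative metric, ranks ascending; the layout is written into
a JSON sidecar next to every cohort CSV so it is never implicit. The
canonical example schema (consults, LOS/PLOS ratio, readmission + four
rated importances on a 5-point scale) yields 23 dimensions. A schema flag
can append the consensus scalar after each SoC block (27 dims for the
example); it is off by default.

Cohort normalization is per-dimension min-max to `[0, 1]`, with two
conventions: constant dimensions map to 0.5 (they contribute nothing to
distances; 0.5 avoids ±0 sign noise), and binary 0/1 metrics pass through
untouched. The fitted scaler is frozen and reusable so a new encounter is
scored on the reference cohort's scale — a reference-based decision
support tool must score one vector at a time. Normalization is idempotent
and preserves per-dimension rank order.

Serialization is bit-stable: values are written as `repr` and read back
with round-trip float parsing (pandas' default fast parser can lose the
last ulp).

## Similarity scoring

Distances from a reference vector (artificial ideal or an actual best
encounter — both supported, neither privileged): Euclidean, cosine
(`1 − cos θ ∈ [0, 2]`, undefined for zero vectors), Canberra (sensitive
near zero; `0/0` terms contribute 0), and Mahalanobis
`sqrt((x−y)ᵀ S⁻¹ (x−y))`.

`S` is the population covariance of the normalized cohort, with the
reference excluded from estimation. SoC blocks are strongly correlated by
construction (neighbouring ranks of one profile move together), so `S` is
routinely near-singular; the default ridge `S + λI` with
`λ = 10⁻⁶·tr(S)/dim` keeps the inverse defined while perturbing
well-conditioned cases negligibly. Setting the ridge to zero demands exact
invertibility and raises on singular input. With `S = I` the Mahalanobis
distance reduces to the Euclidean one (tested to 1e−10).

Rankings sort ascending by distance with ties broken lexicographically by
encounter id, so output is deterministic and invariant to cohort input
order.

## KNN and k-Means

Both are written from first principles at desk scale so every step is
auditable, and both default to Euclidean distance on normalized vectors
with an optional Mahalanobis geometry (whitening by the Cholesky factor of
the precision matrix).

* KNN: majority vote among the `k` nearest; vote ties break by smaller
  mean neighbour distance, then lexicographically smaller class id.
* k-Means: Lloyd iterations from a seeded greedy farthest-point
  initialization (first centre uniform by seed, each next centre the point
  farthest from its nearest chosen centre). Convergence is declared when
  assignments stop changing; `max_iter` defaults to 300. Inertia is
  asserted non-increasing at every iteration; an emptied cluster is
  re-seated on the worst-fitted point. Runs are bit-reproducible given the
  seed. On cohorts of ≤ 8 points the restart-minimum inertia is verified
  in the tests against exhaustive enumeration of all partitions.

## Synthetic data

The generators exist so every pipeline stage is testable without external
data; they emulate the shape of the inputs, not clinical reality.

* **Surveys**: rater responses are i.i.d. draws from a discretized
  Gaussian kernel over the rank values,
  `p_i ∝ exp(−c²(x_i − mode)²/2)`, with concentration `c ≥ 0`. `c = 0` is
  exactly uniform (maximum dissension), `c → ∞` is unanimous, and
  empirical consensus is monotone in `c` — the full regime the statistics
  must resolve. A rounded-and-clipped continuous Gaussian was considered
  and rejected: clipping piles mass on the end ranks, so no spread setting
  yields the uniform limit.
* **Cohorts**: encounters are assigned round-robin to planted clusters;
  each cluster fixes a Poisson consult rate, a log-normal LOS/PLOS ratio,
  a Bernoulli readmission probability, and per-metric survey modes and
  concentration. Planted labels are returned for recovery scoring. The
  `well_separated_scenario` helper (up to 4 clusters) spaces cluster
  centres at ≥ 10× the within-cluster spread on the ratio metric
  (log-scale gaps ≈ 0.7 vs σ = 0.03) with distinct survey modes at
  concentration 4, a regime where k-Means must recover the labels with
  adjusted Rand ≥ 0.99; the tests run 20 seeds each at 40–60 encounters.

What passing these tests shows: the pipeline is internally consistent and
recovers structure it was told to plant. What it does not show: that real
encounter data clusters this cleanly, that real expert panels follow a
single-mode kernel, or that the metric families (Poisson / log-normal /
Bernoulli) match any particular institution's distributions.

## Problem sizes and numerical choices

Default test and demonstration sizes — panels of 10–25 raters, cohorts of
24–60 encounters, 23 dimensions, 20 seeds per recovery property — are desk
scale by design: the method targets feature engineering and reference
scoring, not large-scale learning, and these sizes exercise every code
path. Key tolerances: oracle equivalence 1e−12; Mahalanobis/Euclidean
identity 1e−10; linear-transform invariance 1e−8; published-table
comparisons exact at 3 printed decimals under round-half-even.

## Known limitations

* The consensus statistics treat the rank *values* as the interval on
  which distances to the mean/reference are measured; a different numeric
  relabeling with unequal gaps changes results (by design — affine maps do
  not).
* The Gompertz floor is 48.4%, not exactly 50% (see above).
* k-Means is a local optimizer; single-seed runs can land in local optima
  on hard geometry. Use restarts (the tests do).
* The CLI's `score` command estimates covariance from the scored cohort
  itself; scoring a single encounter against a frozen historical model is
  available through the library API (`ReferenceModel` + frozen
  `CohortNormalizer`), not the CLI.
* No time-series trending of per-encounter vectors is provided; store
  per-time-point vectors and analyse externally.
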