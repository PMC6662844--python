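# Methods

## The analysis model

The scientific question is whether a continuous inattention/hyperactivity
trait (an 18-item rating scale filled in by teachers, integer score
0–54) shifts the *tail* of a child's inter-item transition-distance
distribution during search, leaving the bulk unchanged — the signature of
more frequent exploratory long jumps rather than a globally different
search process.

Distances are Euclidean (mm) for visual cancellation paths and
`1 − cosine similarity` of word vectors for fluency lists. Cosine
similarity of arbitrary real vectors lies in [−1, 1], so semantic
distance lies in [0, 2]; no clipping is applied, since the upper tail is
exactly the quantity under test. Identical consecutive tokens (immediate
repetitions) are assigned distance exactly 0. A transition with an
out-of-vocabulary token is dropped and counted per child
(`skipped_pairs`); the remaining transitions keep their inter-response
times, so distances and IRTs always align.

### Exceedance-count cluster test

For a level grid `q = 0.50 … 0.99` (step 0.01) over the pooled
distances of all children, the per-child exceedance count at level `q`
is the number of that child's distances strictly above the pooled
empirical quantile (linear interpolation, type 7, everywhere in the
package). A Poisson regression of counts on the median-split group is
fitted at each level. With one binary predictor the MLE is closed form —
slope = log rate ratio, Fisher SE `sqrt(1/s_low + 1/s_high)` — and the
resampling loop uses that closed form vectorised over levels and
resamples; a test pins its exact agreement with the IRLS fitter.

Adjacent levels share counts, so per-level p-values are strongly
dependent; familywise error over the sweep is controlled
cluster-wise: maximal runs of consecutive levels with `p < α_cluster`
form clusters whose mass (run length by default, `sum_z` optional) is
referred to the empirical distribution of the *maximum* cluster mass
under child-level resampling. The default scheme permutes group labels
across children — the exact exchangeable null for a two-group contrast —
with a within-group bootstrap (statistics recentred at the observed
slopes) as an alternative. A cluster is significant iff its mass
strictly exceeds the empirical `1 − α_family` quantile of the null
maxima. Defaults: `α_cluster = α_family = 0.05`, 1000 resamples (100 is
reproducible via configuration but resolves a 0.05 tail poorly).

Levels at which one group has all-zero counts are flagged degenerate and
recorded with `p = 1`, keeping the p-vector full length for the cluster
machinery. Exceedance is strict (`>`); with heavy ties at a threshold
this matters and is therefore fixed, not configurable. A consequence
worth knowing: as the level approaches 0 the threshold tends to the
pooled minimum, and values tied with the minimum are *not* counted.

### Quantile-regression sweep

At each level `q = 0.50 … 0.95` (step 0.05) the raw distances of all
children are regressed on the trait score by minimising the pinball loss
`Σ ρ_q(y − Xβ)`. The minimiser is computed exactly as a linear program
(the dual formulation — `max y'a` s.t. `X'a = 0`, `a_i ∈ [q−1, q]` —
whose equality-constraint marginals are the coefficients; HiGHS solver).
Because transitions are nested within children, inference uses a
participant-clustered bootstrap: children are resampled with
replacement, the LP is re-solved, the SE is the bootstrap SD and
p-values use the normal approximation. This is a deliberately simple,
fully specified contract; shrinkage-type mixed quantile estimators can
give different point estimates on the same data.

### Exploration index

Per child, the index sums the child's own empirical distance quantiles
at the levels the quantile-regression sweep flags as significant
(default interpretation `child_quantile`; `level_sum` and
`exceedance_count` are available because the verbal definition of
"summing the significant quantiles" admits all three readings; no claim
is made about which is canonical). The cross-task relation is assessed
by OLS of the semantic index on the visual index controlling for the
trait score. When no level is significant the index is identically 0 and
the correlation step is skipped rather than fitted on a constant column.

### Supporting fits

* `fit_poisson` — own IRLS/Newton implementation of the log-link Poisson
  MLE (tolerance 1e−12 on coefficients), Fisher-information SEs,
  two-sided normal p; cross-checked against statsmodels GLM in the test
  suite. Counts must be non-negative integers; an optional log-exposure
  offset exists but the per-child regressions follow the no-offset
  convention.
* `fit_ols` — statsmodels OLS behind the module surface, with an explicit
  QR rank check that names collinear columns.
* `fit_random_intercept` — statsmodels MixedLM by REML. Fixed-effect t
  statistics use containment degrees of freedom
  `df = n_obs − n_fixed − n_clusters + 1` (recorded in `model_tag`; no
  universal convention exists for mixed-model df). A between-cluster
  variance ratio below 1e−4 is treated as a boundary solution and the
  fit degrades to OLS with a warning, which also covers all-singleton
  clusters where the variance is unidentifiable.

### Cohort handling

Children whose parent rating exceeds the teacher rating by more than one
standard deviation are excluded; the reference SD defaults to the SD of
teacher scores over the included cohort (the analysis covariate), with
`parent` and `difference` selectable. The median split assigns scores
strictly greater than the median to `high`, ties to `low`, computed over
included participants *after* exclusion (both the median and the
exclusion count are logged, since the ordering of those two steps is a
genuine freedom). Scores must be integers in [0, 54]; fractional input
is rejected, not rounded.

## The synthetic cohort generator

The generator is this package's own model — the minimal
exploitation/exploration mixture that produces the tail-only signature —
and doubles as the test bed for every stage.

* **Trait scores.** Drawn from a gamma distribution moment-matched
  *after* truncation to [0, 54] (shape ≈ 0.688, scale ≈ 27.2), rounded
  to integers, so the realised cohort has mean ≈ 13.8, SD ≈ 13.33 and
  median 9. A truncated normal cannot realise these moments on this
  support (its maximum SD at that mean is ≈ 12.3); rating-scale scores
  in non-clinical cohorts pile up near 0 with a long right tail, which
  the gamma captures. Parent scores are teacher scores plus integer
  N(0, 7) noise, clipped to the scale — about 2–4 of 87 children then
  trip the exclusion rule.
* **Board.** A4 landscape (297 × 210 mm, 6 mm margins), 7 equal columns
  each holding 5 targets and 40 distractors placed by dart throwing with
  a 7 mm minimum centre-to-centre spacing (an unsatisfiable spacing
  raises an error suggesting a smaller one). Target quadrant counts are
  balanced to {9, 9, 9, 8} by a fixed per-column top/bottom quota table;
  the start target is the upper-left-most target of column 1's top half.
* **Visual agent.** From the start target, each step moves to the
  nearest unvisited target with probability `1 − p_jump(score)` and to a
  uniformly chosen unvisited target otherwise, where
  `p_jump(score) = logistic(−3 + 0.04·score)` — about 0.05 at score 0
  and 0.25 at score 47. Path length is Poisson with mean 30, capped at
  the 35 targets. Local steps give the distribution bulk (~20–40 mm);
  jumps populate the tail.
* **Semantic space and agent.** Eight Gaussian patches in a 16-d latent
  space, 12 animal tokens each (taxonomic groups), members unit-normed
  around unit-norm centres with spread 0.35, giving the bimodal distance
  distribution seen in fluency data: ~0.1 within patches, ~1.0 between.
  The agent walks to the nearest unsampled patch-mate and jumps to a new
  random patch with probability `p_jump(score)` (or when the patch is
  exhausted). Immediate repetitions are injected with probability
  `0.02 + 0.0015·score` per transition; distant repetitions at a
  trait-independent 0.01. Production length is Poisson with mean 27.
* **IRTs.** `irt = base_c + 8.2·distance + N(0, 1)` seconds, truncated
  at 0, with a per-child baseline `base_c ~ N(1.0, 0.5²)`. The floor at
  0 bites at small distances (the baseline is ~1 s), which slightly
  attenuates fitted slopes relative to the nominal 8.2 — a property of
  the generative model, not of the estimator, and the reason the
  estimator-recovery test simulates from the random-intercept model
  directly.

All randomness flows from one seed through named `SeedSequence`
substreams (cohort, board, semantic space, per-child paths), so any
component can be varied in isolation and whole runs are bit-reproducible
from the manifest.

### What the generator does not emulate

Distractor interference and crossing-out motor time; lexical frequency,
age or production-order effects; trait-linked production counts (off by
default, available as an option); translation noise or out-of-vocabulary
productions (the simulated lists are always in-vocabulary; OOV handling
is exercised by dedicated tests); any dependence of jump *length* on the
trait (only the jump *rate* is trait-linked). Passing tests therefore
show that the detectors recover a rate-type tail inflation under clean
conditions, not that real cancellation or fluency data meet these
assumptions.

## Problem sizes and numerical choices

Desk-scale checks use cohorts of 40–84 children (the study scale),
1000-resample nulls, and 100–200 bootstrap refits per quantile level —
the full default pipeline on 84 children runs in about half a minute on
one CPU. Familywise error of the cluster test, measured over 200 null
cohorts of 60 children at a 0.02-step grid, sits near 0.035 for nominal
0.05 (slightly conservative, as expected from the discrete mass and the
strict exceedance convention). Empirical quantiles are type 7
everywhere. LP tolerance is HiGHS default; the pinball optimum is
verified against 200 × 200 grid oracles and statsmodels QuantReg in the
tests. The committed toy embedding (60 animal tokens, 16-d, unit norm,
text word2vec format, 8-decimal fixed point) is regenerated
byte-identically from its seed; the dog/cat pair is constructed with
cosine similarity exactly 0.29 before quantisation.

## Known limitations

* With ~2400 pooled transitions, the 0.99 grid level has only ~24
  exceedances; the per-level Wald z there is noise-limited, so
  significant clusters often end at 0.96–0.98 rather than the grid
  maximum even when the planted effect is purely in the tail. A cluster
  reaching 0.99 in most runs would require a substantially larger
  jump-rate ratio than the default `b = 0.04` produces.
* The quantile-regression contract (pooled pinball + clustered
  bootstrap) ignores child-level shrinkage; its point estimates are not
  comparable coefficient-for-coefficient with mixed-quantile estimators.
* The Poisson exceedance model treats counts as independent given group;
  overdispersion across children is absorbed by the resampling null (the
  per-level Wald p-values alone would be anti-conservative).
* The semantic effect is intrinsically weaker than the visual one here
  (forced patch exhaustion makes everyone jump), so single cohorts of 84
  children detect a significant semantic cluster only about half the
  time.
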