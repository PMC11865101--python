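# Methods

This note documents the statistical procedure `actisleep` implements, the
assumptions behind it, the synthetic data-generating process used to
exercise it, and the numerical and design choices that were genuinely open.

## Data model

The unit of observation is a **participant-day**. Raw input is one CSV row
per day with a step count, durations (seconds) of light, moderate and
intense activity, and durations of light and deep sleep; any measurement
may be missing. An analyzable **case** exists for day *d* only when both
sleep targets are present on day *d* and all four activity quantities are
present on each of the three preceding *calendar* days. Two consequences
of this rule are deliberate:

- Every case carries the complete set of 28 features with no missing
  values, so all downstream analyses (correlation, discovery, permutation)
  operate on identical case sets per participant.
- Lags are calendar lags, not observation-index lags: a missing or absent
  day breaks the window, because "activity during the three prior days" is
  a temporal statement. A missing row is treated exactly like a row of
  missing measurements.

The 28 features are mean/min/max of each of the 4 activity quantities over
windows of 1, 2, 3 days ending on day *d − 1*; over a 1-day window the
three aggregates coincide and only the mean is kept (canonical form,
enforced by the `FeatureId` type).

**Inclusion.** Participants with strictly more than 30 cases enter the
analysis; the strict inequality matters at the boundary (30 cases out,
31 in) and is asserted by tests.

**Pooling.** For group-level analysis every feature and target column is
z-standardized *within participant* (sample SD, n − 1) before pooling, so
pooled associations cannot merely restate between-person differences in
habitual activity or sleep. A column that is constant within any
participant has no rank or subgroup information and an SD of zero there;
such columns are excluded from the pooled table for all participants
(rather than 0-imputed, which would dilute pooled correlations) and are
reported in the table's provenance and by a warning.

## Correlation screen

Spearman's ρ is computed as the Pearson correlation of mid-ranks (average
ranks on ties — the standard convention; the implementation is checked
against an independent rank-then-Pearson oracle and against
`scipy.stats.spearmanr`). Two-sided p-values use the t-distributed
statistic t = r·√((n−2)/(1−r²)) with n − 2 degrees of freedom, applied at
every n rather than an exact permutation law; an exact enumeration option
exists for n ≤ 8 as a testing aid. Constant columns yield an *undefined*
correlation (an error type), deliberately distinct from r = 0.

The family for Holm–Bonferroni step-down control is all 28 features × 2
targets = 56 tests within a scope (a participant, or the pooled table);
the family size is configurable (`family='per-target'` gives 28). For
reporting, the largest-|r| Holm-significant feature per (scope, target) is
flagged as the headline, and |r| is labeled negligible/weak/moderate/strong
at the conventional 0.10/0.40/0.60 boundaries.

## Subgroup discovery

The search space is every condition `feature ≤ t` or `feature ≥ t` with
*t* an observed value, whose covered fraction lies in [0.10, 0.90] — the
size constraint keeps findings generalizable. Candidates inducing the same
membership set are deduplicated. Quality is the **explained variance**

    EV = 1 − SS_within / SS_total = SS_between / SS_total ∈ [0, 1],

with SS_within the sum of squared deviations of each case from its own
group mean (subgroup or complement) and SS_total the squared deviations
from the grand mean. EV is invariant to positive affine transforms of the
target, invariant under membership complementation, and equals the squared
point-biserial correlation between membership and target — the last
identity is used as a second independent oracle in the tests. Sample-vs-
population normalization of the sums of squares cancels in the ratio, so
the reported scale is unambiguous. The quality measure is pluggable: any
callable `(target_values, membership) → float` can replace EV (at the cost
of the slower generic search path).

The search is exhaustive, not beam or binned: with 28 features, at most
2n observed thresholds each and case counts in the tens-to-hundreds,
exhaustive search is exact and cheap, and equals what an unlimited-width
depth-1 beam would return. For much larger tables an optional `bins`
setting thins candidate thresholds to an equal-frequency grid of split
points, trading exactness for speed; the default is exact. Internally, memberships of `≤` conditions are
prefixes of each feature's value-sorted order, so all admissible splits
are scored from per-feature sort orders and prefix sums
(`SS_between = c_k²(1/k + 1/(n−k))` for the prefix sum c_k of the centered
target — centering avoids the catastrophic cancellation of the raw
three-term form). The sort orders depend only on the features, which is
what makes the permutation test below cheap: each permuted target is
re-scored against every condition in a few vectorized passes.

**Tie-breaking.** A subgroup and its complement induce the same split and
therefore *always* tie on EV. Ties are resolved toward the **smaller**
subgroup — the side whose mean deviates more from the grand mean and the
natural side to report (a 36%-of-days subgroup with markedly longer sleep,
rather than its unremarkable 64% complement) — then `≤` before `≥`, then
smaller |threshold|, then feature name. The rule is deterministic and
makes discovery invariant to case order.

## Significance: Distribution of False Discoveries

Maximizing EV over thousands of correlated conditions guarantees a
non-trivial best EV even under independence. The DFD quantifies this
selection effect directly: the target column is swap-randomized (uniform
random permutation; features untouched, preserving their joint
distribution), the full discovery is re-run under identical constraints,
and the best EV recorded — B times. The observed best quality is located
in this null distribution via the add-one estimator

    p = (1 + #{null ≥ observed}) / (1 + B),

which is a valid permutation p-value: strictly positive, exact under
exchangeability of the target given the features, conservative on ties.
Significance is declared when p < α (strictly), α = 0.05 by default.
B defaults to 1 000 (minimum 100 enforced); permutation streams are
spawned per-permutation from a single seed sequence, so extending B leaves
earlier null draws unchanged (streamed reproducibility, asserted by test).

At group level the default permutes **within participant**: per-participant
standardization already removed participant means, but within-participant
swapping additionally preserves each participant's case count and target
marginal under the null. Global permutation is available
(`within_participant=False` / `--permute global`); which variant the
motivating analyses used is not documented, so both are provided and the
choice is logged in the run provenance.

One DFD test is performed per (scope, target), validating only that
pair's single best subgroup.

## Synthetic cohort generator

The generator emulates the cohort the analysis assumes rather than any
device internals:

| component | model | default |
|---|---|---|
| participants | independent | 18 |
| days per participant | uniform integer range, consecutive calendar days | 32–173 |
| daily steps | log-normal around a per-participant median drawn log-uniformly | median range 1 000–10 000, log-SD 0.5 |
| activity durations | gamma (right-skewed, ≥ 0) around per-participant means | light ≈ 2–4.5 h, moderate/intense ≈ 10–50 min |
| sleep durations | normal, resampled into [0, 24 h) | light ≈ 3 h–4.5 h ± 45 min, deep ≈ 3.2–4.3 h ± 40 min |
| missingness | independent per field per day (MCAR) | 5% |

These scales reproduce the cohort summaries the analysis targets (median
daily steps ≈ 4 000 with wide between-person spread; total sleep ≈ 7.5
h/day split roughly evenly into light and deep). Shapes were chosen once —
log-normal/gamma for right-skewed activity, truncated normal for roughly
symmetric sleep — and are exposed in `CohortConfig` rather than revisited.

**Planted effects** provide ground truth: after the activity series is
simulated, the chosen lagged descriptor is computed, its per-participant
empirical quantile becomes the threshold, and qualifying days have the
target mean shifted by `shift` × the participant's configured target SD.
Step-function shifts (not linear dose–response) are planted because the
discovery method searches threshold conditions. The implied subgroup
fraction must lie strictly inside (0.10, 0.90) so the planted subgroup is
admissible.

**What the generator does not emulate** — and hence what passing tests do
not establish about real tracker data: within-person autocorrelation and
weekly rhythms (days are i.i.d. given the participant), informative
missingness (wear-time compliance correlates with activity in reality),
device-side capping/smoothing of durations, sleep–activity feedback in the
reverse direction, and intervention effects. Calibration results (type-I
error ≈ 5%) therefore certify the procedure under exchangeability, not
under serial dependence; on strongly autocorrelated targets a
day-permutation null is known to be optimistic.

## Numerical choices and degenerate inputs

- SDs use the n − 1 denominator everywhere (stated for reproducibility).
- EV is computed on the centered target and clipped to [0, 1] against
  last-ulp excursions; zero total variance raises an undefined-quality
  error rather than returning 0.
- The subgroup/overall mean ratio ("normalized target mean", > 1 ⇔ longer
  than usual) is suppressed — replaced by the absolute mean difference —
  when the overall mean is non-positive or numerically ~0, as on
  standardized group-level tables.
- |r| = 1 reports p = 0 (the t statistic diverges); n < 3 scopes are
  skipped with a warning; discovery requires ≥ 10 cases per scope.
- Permutations yielding no admissible subgroup (e.g. a constant permuted
  target) record null quality 0 with a warning.
- Condition text renders durations in minutes up to 2 h and as "H h and
  M min" above, steps as integers, and standardized thresholds in SD
  units; the rendering is injective over the 28 features.

## Problem sizes used in the validation suite

The shipped tests and `scripts/acceptance.py` validate at sizes chosen to
make the statistical claims testable while keeping the suite quick: oracle
equivalence on 50 random tables up to n = 200; DFD calibration on 500
(tests) / 200 (acceptance script) null datasets of 60 cases × 28 features
with 500 permutations; planted-effect recovery and power at n = 150 cases
over 100 (tests) / 60 (script) seeds; the full-pipeline replica at 18
participants × 60–173 days with 500 permutations. Statements about rates
(recovery ≥ 90%, type-I error within the binomial band around 5%) are
Monte-Carlo estimates at exactly these sizes.

## Known limitations

- Single-condition (depth-1) descriptions only; no multi-condition rules,
  nominal descriptors, or non-mean target models.
- The t approximation for Spearman p-values is used at all n, including
  small individual-level samples, for fidelity to the screening procedure
  being replicated rather than statistical optimality.
- No imputation: aggressive missingness shrinks case counts quickly (a
  case needs 14 observed cells across 4 days).
- The DFD validates the single best subgroup per (scope, target); it makes
  no simultaneous statement about the rest of the ranked list.
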