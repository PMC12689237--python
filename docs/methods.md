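# Methods

## Elicitation model

A respondent's record holds three preference blocks over the EQ-5D-5L
descriptive system (dimensions MO, SC, UA, PD, AD in that fixed order;
levels 1–5):

**Swing weights.** The respondent picks the most important dimension, which
is fixed at 100, and rates the other four against it on 0–100. Weights are
the normalized ratings, w_d = s_d / Σ_e s_e. The elicitation itself does not
dictate the normalization; dividing by the sum is the standard completion of
swing weighting for an additive model and is adopted here. The denominator
is ≥ 100 (the chosen dimension), so the weights are always defined, sum to
one to machine precision, and a rating vector (100, 0, 0, 0, 0) produces the
degenerate but valid weight vector (1, 0, 0, 0, 0).

**Level decrements.** Levels 2–4 of each dimension are rated on a VAS whose
endpoints are level 1 (fixed at 100) and level 5 (fixed at 0); only the
three free ratings are stored. The proportion of the dimension's decrement
incurred at level l is λ_{d,l} = (100 − r_{d,l}) / 100, with λ = 0 at level
1 and λ = 1 at level 5 by construction. Ratings out of order ("illogical",
see QC) simply produce non-monotone λ; nothing is corrected or imputed.

**Anchoring.** The dead-vs-55555 choice puts the less preferred option at 0
on a VAS with full health at 100. Two branches:

- 55555 preferred, or indifferent (folded into this branch with a rating of
  0): dead sits at 0, the 55555 rating b gives u(55555) = b/100 ∈ [0, 1].
- dead preferred: 55555 sits at 0 and dead is rated a. Requiring dead ↦ 0
  and full health ↦ 1 maps 55555 to (0 − a)/(100 − a) = −a/(100 − a),
  unbounded below and undefined at a = 100. The a = 100 response (dead rated
  equal to full health) is the one automatic exclusion in the pipeline.
  a = 0 gives u(55555) = 0, continuous with the indifference case.

Each respondent's u(55555) is censored at −1 *before* any averaging. The
order matters: the cohort's uncensored mean is dominated by the hyperbolic
tail of −a/(100 − a), and censoring per respondent is what bounds each
individual's influence.

**Utility.** With δ_{d,l} = (1 − u55) · w_d · λ_{d,l},
U(s) = 1 − Σ_d δ_{d,l_d(s)}. Identities used as test anchors: U(11111) = 1
exactly (λ = 0 at level 1 is exact in floating point), U(55555) = u55 up to
~1e−15 summation noise (the weights sum to 1 only to machine precision), and
utility depends on each dimension only through its own δ column (additive
separability; verified by a swap-one-dimension test).

## Quality control

- *Illogical* = a strictly higher rating for a more severe level within a
  dimension, over the pairs (2,3), (2,4), (3,4). Ties are tolerated — VAS
  coarseness makes them common — and the implied endpoints cannot generate
  findings. Illogical responses are reported, not excluded.
- *Extreme* = a free rating exactly 0 or 100; reported as a fraction of the
  15 stored ratings, overall and per respondent. Retained.
- *Exclusion*: only the anchoring degeneracy (dead preferred, a = 100). The
  mirror-image b = 100 (55555 rated at full health) yields a valid but flat
  PUF — every decrement zero — and is retained with a warning.
- *Timing*: respondents strictly below the median completion time are
  "fast", the rest "slow" (at-the-median respondents go to "slow"; the split
  rule must be fixed somewhere to be deterministic, and this is the choice).
  Illogical-finding counts are compared with a two-sided Wilcoxon rank-sum
  test using mid-ranks for ties. For groups of ≤ 10 each the p-value is an
  exact permutation probability P(|W − E W| ≥ |w_obs − E W|) over all
  C(n, n1) assignments; otherwise a tie-corrected normal approximation
  without continuity correction, which simulations in the test suite show
  holds the 5 % level to within ±2 points at n = 200 on heavily tied count
  data.

## Tariff

The group tariff is the arithmetic mean of the individual δ tables — no
regression, the structural advantage of the PUF design. Confidence
intervals: the data source gives no interval method, so the default is a
seeded nonparametric percentile bootstrap over respondents (B = 1000, 95 %),
which makes no distributional assumption and tolerates the heavy-tailed,
bimodal anchoring data; a per-coefficient t-interval is available
(`ci_method="t"`) and leaves the point estimates untouched. The mean
preserves linearity, so 1 − Σ_d mean δ_{d,5} equals the mean censored u55
and the pooled tariff equals the size-weighted mean of subgroup tariffs;
both identities are asserted in tests at 1e−9/1e−12.

Subgroup tariffs follow home language, with Afrikaans and English merged
into one group (their individual samples are small); groups below a
configurable minimum size (default 5) are estimated anyway but warned about,
never suppressed. The monotonicity audit flags every decrease of the mean
decrement as a level worsens and reports each dimension's 4→5 step, the
diagnostic for the characteristically larger final step.

## Heterogeneity

The u(55555) distribution splits respondents into *compressed* (u55 ≥ 0;
they prefer 55555 to dead, utilities confined to roughly [0.5, 1]) and
*stretched* (u55 < 0, spanning down to −1). The split is operationalized as
the sign of the censored u55, with 0 assigned to compressed — the attitude
toward death is what defines the groups, so the sign rule is the natural
formalization; a distance-based clustering would be an extension, not the
definition. Utility profiles are computed over a seeded uniform
without-replacement sample of states (default 100) that always includes
"11111" and "55555" so the extremes anchor the picture; states are ranked
best→worst by the group mean (ties broken by code), and each respondent's
Euclidean distance from the group mean over the sampled states is reported.
Plots (profile lines coloured by distance; u55 histogram) are optional; the
CSV/JSON tables are the contract.

## Synthetic cohorts

The generator is the package's stand-in for the non-public survey data; its
defaults are the study conditions, not tuning knobs.

- **Anchoring mixture.** With probability p = 0.38 a respondent is
  *stretched*: dead preferred, a ~ Uniform(50, 97.5). The support's lower
  edge 50 means −a/(100 − a) ≤ −1 always, so every stretched respondent
  censors to exactly −1 (and a < 100 never divides by zero); by quadrature
  E[−a/(100 − a)] ≈ −5.307. Otherwise *compressed*:
  b ~ Uniform(40, 98.7), mean 69.35. The resulting mixture means are
  0.62·0.6935 − 0.38 ≈ 0.050 (censored) and 0.62·0.6935 − 0.38·5.307 ≈
  −1.587 (uncensored), and the two supports leave a (−1, 0.4) gap in the
  u(55555) distribution — the three statistics plus the gap that the
  emulated sample exhibits. `expected_u55` recomputes both means by
  quadrature and is cross-checked in the tests by an independent
  integration.
- **Swing task.** Most-important dimension drawn from (MO .35, SC .15,
  UA .15, PD .10, AD .25); non-chosen ratings from scaled Betas with means
  85/80/80/68/82 — mobility most prominent and pain/discomfort lowest, the
  plausible ordering for such samples. No exact calibration to published
  medians is attempted: those medians mix the chosen-dimension (=100) cases
  into each margin, and matching them exactly would over-fit a display
  statistic.
- **Level ratings.** Per dimension, the 0–100 range is split into four gaps
  by a Dirichlet(2, 2, 2, 3) draw; cumulative sums from the top give
  strictly decreasing (r2, r3, r4), so ratings are logical *by
  construction*. Expected decrement proportions are (2, 4, 6, 9)/9 — evenly
  spaced with a larger 4→5 step. Illogical responses exist only when
  `illogical_rate` > 0 (an adjacent-pair swap per dimension), extreme
  responses only via `extreme_rate_boost` (snap to the nearer of 0/100);
  both default to 0 so that response error is a separate, switchable layer.
- **Demographics.** Category probabilities follow the emulated sample's
  margins (52.5 % aged 20–39, 47.5 % female, 75.4 % Black African, 26.2 %
  low-income area; languages 28:6:12:15 English:Afrikaans:Zulu:Tswana).
  Completion time is log-normal with median 10 min and σ = √(2 ln 1.1)
  ≈ 0.437, so the mean is 11 min and the central 99 % spans roughly 3–31
  min.
- **Reproducibility.** One seed; per-respondent sub-streams spawned by
  index, so enlarging a cohort never reshuffles existing respondents.
  Respondents are mutually independent, and task blocks within a respondent
  are independent — no correlation structure is claimed by the data source,
  so none is imposed.

`make_study_fixture` produces the packaged 61-row synthetic fixture with the
exact marginal counts above and exactly one a = 100 respondent, so the
exclusion rule always fires exactly once on it.

`expected_decrements` is the parameter-recovery oracle:
E[δ_{d,l}] = E[1 − u55] · E[w_d] · E[λ_{d,l}], valid only for noise-free
configs (with corruption the factors are no longer independent). E[1 − u55]
is exact (quadrature over the mixture), E[λ] exact from Dirichlet means, and
E[w] — intractable in closed form because of the normalization — comes from
a large seeded Monte Carlo of the swing mechanism whose standard error is
propagated into the comparison tolerance.

## What the simulations do and do not show

Passing tests demonstrate that the pipeline arithmetic is exact (oracle
equivalence at 1e−12 over all 3125 states), that aggregation recovers the
generator's known expectations within Monte-Carlo error, and that the
anchoring summary statistics of a large default cohort sit at their
calibrated values. They do not validate the behavioural model itself:
real respondents exhibit interviewer effects, wave effects, within-person
correlation between task blocks, and language/translation effects that the
generator deliberately omits, and the uniform anchor-rating distributions
are a parsimonious shape choice, not an estimate.

## Problem sizes and numerical choices

Simulation-backed tests use cohorts of 200–10,000 respondents: 10,000 for
the anchoring means (binomial SE ≈ 0.5 pp on the mixture share), 5,000 for
parameter recovery (3-combined-SE bands on all 20 coefficients), 200 × 3125
for oracle equivalence, and 1,000 replicates for the rank-sum type-I check.
All comparisons of supposedly identical floating-point quantities use
absolute tolerances of 1e−9 to 1e−15 as noted above; exported CSVs round to
4 decimals by default (`--precision`) while everything upstream stays in
double precision. Degenerate inputs are handled explicitly: empty cohorts
and single-respondent aggregates are errors, a one-respondent subgroup
gets a point-mass interval, and an all-equal-duration cohort makes the
timing split fail loudly rather than silently produce an empty group.
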