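# Methods

## Model and estimation

For each gender × food series the energy-adjusted intake table
`R_ij` (age group `i` = 1..5, survey `j` = 1..3) is decomposed as

    R_ij = m + a_i + t_j + e_ij,

with `sum_i a_i = sum_j t_j = 0` and residual row and column means
zero. Estimation is by mean polish: initialize the grand term to the
overall mean, then alternately sweep row means into the age effects and
column means into the period effects, folding the mean of each effect
vector back into the grand term, until the largest adjustment in a full
sweep falls below the tolerance. On a complete table this fixed point
is exactly the closed-form two-way decomposition (`a_i` = row mean −
grand, `t_j` = column mean − grand), so the iteration converges in at
most two sweeps and the sweep order (rows first, then columns — the
package's fixed choice) cannot change the result; both facts are
asserted by tests rather than assumed. The iterative engine is kept
because the median variant shares it.

Cohort effects are defined on the residuals. With 10-year age bands and
10-year survey spacing, all respondents born in the same decade lie on
one diagonal of the grid; the cell `(i, j)` belongs to the birth decade
starting `1960 − 10(i−1) + 10(j−1)`. The seven diagonals partition the
15 cells with sizes 1, 2, 3, 3, 3, 2, 1 (birth decades 1920 … 1980).
The cohort effect `c(k)` is the unweighted arithmetic mean of cohort
`k`'s residuals. Since residual rows and columns are centered, the
cell-count-weighted mean of all seven `c(k)` is identically zero — a
closure identity the tests check on every decomposition. `c(k)` is an
interaction measure with no reference level and is therefore never
anchored.

Interpretation caveat: the three APC dimensions are linearly
confounded. This decomposition does not resolve the identification
problem; it *defines* the cohort effect as the non-additive remainder
after age and period means are removed. A cohort pattern that is
exactly additive in age and period is absorbed into `a` and `t` and
will not appear in `c(k)` (the synthetic-recovery example shows a +5
injected interaction surfacing as ≈ +4 on its diagonal, the rest
absorbed by the additive fit). No standard errors or tests are
attached; the output is descriptive.

## Energy adjustment and units

Intakes are re-expressed as g per 4,186 kJ (1,000 kcal) per day:
`intake / energy × 4186`. Adjustment is applied to cell means (ratio of
mean intake to mean energy), because the package consumes aggregated
tables; whether the original survey tabulations adjusted per subject
and then averaged is not knowable from published tables. The microdata
generator supports the per-subject route so the two orderings can be
compared — they differ, because a ratio of means is not a mean of
ratios. The kcal→kJ factor is fixed at 4.186; energy units are declared
per input file, never auto-detected.

## Harmonization

Food-coding changes between survey waves are corrected by explicit
`(food, year, divisor)` rules. The single default rule divides rice in
2009 by exactly 2 (the 2009 wave recorded steamed rather than milled
rice, roughly doubling weights). The divisor is 2, not the 2.12 implied
by the raw steaming ratio, matching the halving convention of the
reference analysis. Every modified record is tagged with the rule id
and logged; applying a rule to an already-tagged record raises rather
than silently compounding the division. Synthetic data carries no
coding artifact, so pipeline runs on generated input disable
harmonization (`harmonize: false` / `--no-harmonize`).

## Reporting defaults

Age effects are anchored to the 20–29 group and period effects to 1989
(reference entries exactly 0); anchoring preserves pairwise differences
and fitted values. Cohort effects are computed for all seven diagonals
but reported for birth decades 1930–1979 — the five cohorts observed in
at least two cells; the two single-cell corner cohorts (1920–29,
1980–89) still shape the polish and appear, flagged, in the sidecar.
Report tables round to 1 decimal; all computation and the sidecar stay
at full precision, so rounding never feeds back into the decomposition.
An `n_subjects`-weighted alternative for the cohort residual averages
is provided (`weights=n_subjects`) because cell counts vary more than
10-fold across waves; the default is unweighted.

## Numerical choices

Convergence tolerance 1e-10 (absolute, on the largest sweep
adjustment); max 20 iterations for mean polish (2 suffice; more
signals a bug and sets `converged=False`, a warning rather than an
error), 100 for median polish, whose convergence has no two-sweep
guarantee. Reconstruction `m + a_i + t_j + e_ij = R_ij` is exact to
1e-9 in tests. Missing cells are fatal — the diagonals presuppose a
complete table and no imputation is offered. Non-finite inputs are
rejected at table construction.

## Synthetic data

The generators realize the additive model with optional diagonal
interactions: `latent(i,j) = grand + a_i + t_j + c(decade(i,j))`.

* **Cell-table generator** — adds N(0, `noise_sd`) to each latent cell
  and emits cell means with energy pinned at 4,186 kJ, making the
  adjustment step the identity so recovered effects compare directly
  with the truth. Default `noise_sd` is 1 g/4,186 kJ/day, the order of
  a survey cell mean's standard error at a few hundred subjects;
  defaults elsewhere are grand 100 g/4,186 kJ/day with zero effects,
  an interaction-free baseline into which callers inject truth.
* **Microdata generator** — draws per-subject energies (normal, gender
  × age means from the published tables, CV 0.2, clipped at a 2,000 kJ
  floor) and gamma intakes with mean `latent × energy / 4186` and shape
  4 (CV 0.5): non-negative and right-skewed, the conventional shape
  for daily intakes. Aggregated cell means converge to the latent
  values as n grows, verified against a delta-method variance bound.

Default per-cell subject counts follow the published survey layout
(25–1,011 per gender × age × wave), so generated data reproduces the
real design's very uneven precision. Both generators are bit-reproducible
from the spec seed. What they do **not** emulate: survey sampling
design (districts, households), seasonal recording effects,
food-composition-table revisions (beyond the rice rule's existence),
between-food correlations, and reporting error — so passing recovery
tests demonstrate correctness of the decomposition, not robustness to
real survey biases.

The packaged reference fixture is a verbatim transcription of the
published year-averaged gender × age intake marginals with per-wave
subject counts. The per-year 5 × 3 tables behind the published effect
estimates were never released, so the fixture cannot be polished (its
periods are collapsed and the package refuses it as decomposition
input); published anchored effect rows instead serve as injected truth
for zero-residual round-trip fixtures. Relatedly, the year-averaged
marginal age contrasts do not equal the polish age effects (e.g. men's
meat: −46.5 marginal vs −22.2 polished), and whether the published
marginals are n-weighted is not stated — the package offers both
weighted and unweighted marginal summaries and does not guess.

## Problem sizes

The property suites use what the estimator's cost makes comfortable:
1,000 random 5 × 3 tables for the closed-form equivalence check and
3 × 200 seeded replicates (noise sd 0, 1, 5) for parameter recovery,
each polish being a handful of 15-cell mean sweeps.

## Known limitations

* Only the fixed 5 × 3 grid is supported; the grid geometry (equal age
  band and survey spacing) is what makes cohorts diagonals, and
  generalizing it would change the cohort partition logic.
* Median-polish cohort effects inherit the median variant's weaker
  guarantees: residual row/column *medians*, not means, tend to zero,
  so the cohort closure identity holds only approximately.
* The energy-adjustment ordering question above is surfaced, not
  resolved.
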