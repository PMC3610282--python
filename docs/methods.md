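# Methods

## The measure

For case *i* with observations x_i1 … x_iM_i on a non-negative ratio scale,
every unordered pair (x, y) contributes

    d(x, y) = log2(|x − y| / max(x, y) + 1),    d(0, 0) = 0

and IBMD is the mean of d over all within-case pairs, pooled across cases:

    IBMD = [ Σ_i Σ_{j<k} d(x_ij, x_ik) ] / Σ_i C(M_i, 2).

Writing r = min/max, d = log2(2 − r): the kernel depends only on the ratio
of the two readings. Consequences we rely on and test:

* **Range.** Each term is in [0, 1], so IBMD ∈ [0, 1]; it is 0 exactly when
  every within-case pair is tied, and a (0, c>0) pair scores exactly 1.
* **Scale invariance.** Multiplying every observation by c > 0 leaves IBMD
  unchanged; this is what makes the measure comparable across populations
  whose trait ranges differ, where ICC/CCC are not.
* **Metric axioms.** On positive reals d is symmetric, zero iff the readings
  are equal, and empirically satisfies the triangle inequality (property-
  tested on 10⁴ random triples; we do not rely on a proof).

The logarithm is base 2 throughout: the two-observer form of the measure is
defined with log₂, and only base 2 normalizes the maximal pair (0, c) to
exactly 1.

Conventions for edge cases:

* A case with M_i < 2 contributes no pair to numerator or denominator. Such
  cases are dropped before any analysis (and before bootstrap resampling, so
  every replicate is well defined), counted in `n_cases_dropped`, and a
  warning is logged.
* A case whose observations are all zero contributes C(M_i, 2) pairs of
  value 0 — the 0/0 convention defines the kernel value; it is not an
  exclusion rule.
* Duplicate observer labels within a case are rejected at parse time: the
  estimator has no provision for replicates per observer.
* Kernels are computed in double precision and never rounded inside the
  estimator; the 3-decimal figures in human-readable reports are formatting
  only. The pooled sum uses exact (`math.fsum`) summation, so the point
  estimate is bit-for-bit invariant to case order and within-case
  observation order.

## Bootstrap inference

The sampling unit is the case. One replicate draws N cases with replacement
from the N usable cases, each carrying its whole observation vector
(observers are never resampled), and recomputes IBMD; B replicates (default
B = 1000, appropriate for 90–95% intervals) yield an empirical distribution
whose α/2 and 1−α/2 quantiles form the percentile CI (default level 0.95).
The reported point estimate is always the IBMD of the original table, never
a bootstrap mean. Quantiles use linear interpolation between order
statistics (the default empirical quantile); with B = 1000 and α = 0.05 the
index B·α/2 = 25 is integral, and conventions differ at that margin by less
than the stochastic wobble across seeds.

Because a replicate only re-weights whole cases, the per-case pair-sum and
pair-count are sufficient statistics; the implementation precomputes them
once and evaluates a replicate as a ratio of two sums, which makes B = 1000
effectively instantaneous at study sizes. A replicate whose resampled cases
are all internally constant legally has value 0; there is no redraw. A fixed
seed reproduces the interval bit for bit; with no seed the generator is
entropy-seeded and the run is not reproducible.

**Two-population comparison.** Each group is bootstrapped on its own child
stream spawned from the single root seed, so one group's interval does not
depend on the other group's size. The comparison verdict is the CI-overlap
criterion: disjoint 95% intervals are reported as significantly different
disagreement. As an additional diagnostic the tool pairs replicate r of the
two groups and reports a percentile CI for IBMD_b − IBMD_a; this difference
interval is an extension beyond the overlap criterion and is labelled
separately in reports. Groups whose usable case counts differ by more than
an order of magnitude trigger a warning. No p-values are computed, and BCa
or studentized intervals are out of scope.

## Comparators

For side-by-side reporting the package includes the classical measures, all
of which require complete rectangular data (IBMD is the only measure here
that accepts ragged tables):

* **ICC** — two-way random effects, absolute agreement, single measures
  (ICC(A,1)). This is the agreement-appropriate variant: raters are treated
  as a random sample and systematic rater bias counts against agreement. The
  variant name is embedded in every result. Computation is delegated to
  `pingouin.intraclass_corr`; the test suite checks it against an
  independently coded ANOVA mean-squares computation.
* **CCC** — Lin's concordance correlation coefficient,
  2·s_xy / (s_x² + s_y² + (x̄ − ȳ)²) with biased (1/N) moment estimators, as
  in Lin's original definition; the sample-vs-population variance choice
  changes the value at small N, hence it is fixed and documented here.
  Two observers only.
* **Limits of agreement** — Bland–Altman bias = mean(x−y) and
  bias ± 1.96·sd(x−y) with the sample (n−1) standard deviation. Two
  observers only.

A deliberate demonstration in the test suite generates two synthetic
populations with identical observer error but very different trait variance:
ICC moves materially while IBMD stays put — the reliability-vs-agreement
distinction that motivates the measure.

## Packaged data and the synthetic generator

Two transcribed studies ship as wide CSVs with a group column, frozen by
SHA-256 digests that the loaders verify (a silent edit of the transcription
fails loudly):

* `gymnasts.csv` — 40 performances × 8 judges, scores 0–10, groups
  old/new rulebook (20/20).
* `maternal_hr.csv` — 26 one-hour cardiotocography segments × 3
  obstetricians, baseline estimates in bpm, groups initial/last hour of
  labor (13/13).

**Known discrepancy.** The packaged gymnastics transcription reproduces the
originally reported new-rulebook estimate (0.174) and both maternal
estimates (0.048/0.048) exactly, and all published CI endpoints to well
within ±0.01, but the old-rulebook group computes to 0.093 where 0.090 was
originally reported. The transcription has been re-verified cell by cell;
the source table and the source value are simply inconsistent with each
other (a single outlying cell — gymnast 12, judge 8, 7.40 where the other
seven judges gave 8.5–9.9 — would reconcile them if it read 9.40). We
package the table as printed rather than emending data, and flag the
affected expectation in the acceptance tests.

**Generator.** `simulate_ratings` draws a true value t_i per case uniformly
on `true_value_range`, and observer j reports t_i·exp(ε_ij) with
ε_ij ~ N(0, noise_scale²) — multiplicative log-normal observer error, the
natural model for a ratio-scale measure (a 10% error is a 10% error at 60
and at 110 bpm) and one under which the generated table's IBMD is unit-
invariant, which the tests exercise end to end. Defaults describe a small
agreement study: 30 cases, 3 observers, true values 60–110 bpm (a maternal
heart-rate baseline range), noise_scale 0.1 (≈10% observer error), no
missingness. Observations are dropped independently with `missing_rate`;
a case left with fewer than two observations is redrawn, so every generated
case is usable. An additive-error variant (`noise_model="additive"`,
truncated at zero) exists for comparator demonstrations and is not the
default. The generator is i.i.d. across observers: it does not emulate
systematic rater bias, rater-specific variances or correlated errors, so
passing calibration tests speak to sampling noise under this model, not to
robustness against structured rater effects in real data.

**Calibration.** The test suite checks interval calibration at desk scale:
200 datasets of 30 cases (noise_scale 0.1, B = 500) against the model's
large-sample IBMD estimated once from a 100 000-case run, with observed 95%
CI coverage required in [0.90, 0.99] — a band acknowledging both the 200-
replicate binomial wobble and the percentile bootstrap's known slight
undercoverage at n = 30. Problem sizes throughout (B = 1000 for study CIs,
B = 500 × 200 datasets for calibration, 10⁴ random triples for the metric
axioms) were chosen as the smallest that make the checks sharp.

## Interfaces

Wide CSV (first column case id, one column per observer, blank cell =
missing, never zero) and long CSV (`case_id, observer_id, value`, unique
pairs); both strict about period decimals — decimal commas are rejected, not
coerced. A grouping column may name the population of each case; `compute`
runs per group, `compare` requires exactly two. JSON reports embed the seed,
B, level and tool version; estimates appear at machine precision in JSON and
rounded to 3 decimals in human reports. Exit codes: 0 success, 1 usage
error, 2 data error.
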