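# Methods

## The model

The analysis treats a bivariate association not through its central
tendency but through the *empty corners* of its scatter.  If low x
precludes high y, the upper-left corner of the plot is empty; the degree
of necessity is the size of that empty region relative to the whole
observable region.  Symmetrically, an empty lower-right corner means high
x guarantees high-ish y — a degree of sufficiency — and that corner is
exactly the upper-left corner of the plot with the axes exchanged.  The
extended analysis computes both, tests each against a permutation null,
and tests their difference with a bootstrap, because a one-corner analysis
alone cannot distinguish "necessary but not sufficient" from an
association that is equally necessary and sufficient (or sufficient but
not necessary): by the rules of logic, if x were necessary-but-not-
sufficient for y, then y would have to be sufficient and *not* necessary
for x, so a significantly empty lower-right corner contradicts that
reading, and the package says so in a report note.

## Geometry conventions

**Scope.** The empirical rectangle spanned by observed minima and maxima.
Theoretical scale bounds are never used: the effect size is a statement
about where observed data do not go, relative to where they do.
Zero range on either axis makes the effect undefined
(`DegenerateScopeError`).

**CE-FDH ceiling.** c(x) = max{y_i : x_i ≤ x}, a right-continuous,
non-decreasing step function — the lowest such function with no
observation strictly above it (the free-disposal property).  Ties in x are
absorbed by the running maximum; observations are never jittered, since
jitter would perturb areas.  The ceiling zone is {(x, y) in scope :
y > c(x)} and its area is a finite rectangle sum, exact to machine
precision.  The *peers* are the observations where the running maximum
strictly increases — the non-dominated upper-left points.

**CR-FDH ceiling.** The ordinary least-squares line through the CE-FDH
peers, clipped to the scope rectangle; its zone area is exact
trapezoid/triangle geometry, with the rectangle split at the points where
the line crosses the scope's top and bottom.  With fewer than two distinct
peers no line is identified and the step ceiling is kept, with a logged
warning.  CE-FDH is the default technique; CR-FDH is opt-in.

No numerical quadrature is used anywhere, so all areas and effect sizes
are deterministic given the data.

**Sufficiency.** Computed as the necessity effect of the axis-swapped
sample and relabeled.  A property test verifies it also equals an
independently coded direct integration of the lower-right region
{(x, y) : x > max{x_i : y_i ≤ y}} to 1e-12 relative.

## Inference

**Permutation test** (default K = 10,000).  The outcome vector is shuffled
against the fixed determinant vector and d recomputed per draw; for the
sufficiency direction the sample is swapped first and then shuffled the
same way, which makes the whole report exactly equivariant under axis swap
of the input.  The p-value uses add-one smoothing,
p = (#{d_perm ≥ d_obs} + 1)/(K + 1), so p is never 0 and permuted values
tied with the observed d count against it (conservative).  The scope is
invariant under permutation (the value multisets are unchanged), which the
implementation asserts instead of recomputing per draw.

**Bootstrap difference test** (default B = 10,000).  Rows are resampled
with replacement; each resample with a non-degenerate scope contributes
d_nec − d_suf.  The reported difference is the *mean* of the bootstrap
distribution with SE its sample standard deviation, Z = mean/SE and a
two-sided standard-normal p.  Two-sidedness is a deliberate choice: the
alternative (more necessity than sufficiency or the reverse) is
directionless a priori.  The plug-in difference d_nec − d_suf of the
original sample is reported alongside, since the two can differ visibly in
small samples.  Degenerate resamples are skipped and counted in the log,
not errored — at small n an all-identical resample is routine.  If every
resampled difference is identical (SE = 0) the Z is undefined; the result
is flagged and p set to 1.

**Seeding.**  `run_extended_nca` derives sub-seeds from the master seed
with numpy's `SeedSequence.spawn`: one child shared by the two permutation
tests (this is what makes the swap-equivariance exact rather than only
distributional), one for the bootstrap, which draws its row indices before
touching any values so that axis swap negates every resampled difference
bit-for-bit.  The same master seed yields a byte-identical JSON report.

**Interpretation.**  With significance level α (default 0.05):
no_nonrandomness if neither effect is permutation-significant; otherwise
equal_degrees if the difference p ≥ α; otherwise necessity_dominant or
sufficiency_dominant by the sign of the bootstrap mean.  `guard_ok` is
true iff the larger of the two observed effects is itself
permutation-significant; a significant difference with `guard_ok` false is
reported but annotated as not interpretable.

## Synthetic data

The generators produce unit-square samples whose asymptotic empty-corner
fractions are known analytically, so recovery and calibration are testable
without any external data.  Defaults: n = 533 (the sample size of the
survey study this method is typically demonstrated on) and corner fraction
0.12 (the magnitude of effect typical of that setting).

* `necessity_only` — uniform below the straight ceiling from (0, 1−h) to
  (1, 1) with h = 2·fraction, so the excluded triangle has area exactly
  `fraction`; feasible for fraction ≤ 0.5 (at 0.5 the ceiling is y = x).
  Corners (0, 0) and (1, 1−h) are pinned so the empirical scope is stable
  across seeds — a fixture choice that makes recovery tests crisp, not a
  claim about real data.
* `sufficiency_only` — the axis swap of `necessity_only`, same seed.
* `both` — uniform on the diagonal band |y − x| ≤ 1 − √(2·fraction), each
  excluded corner triangle of area `fraction` (feasible below 0.5);
  corners (0, 0) and (1, 1) pinned.
* `independent` — uniform with all four corners pinned.  Note the pinned
  (0, 1) corner puts the CE-FDH ceiling at the scope top, so d = 0
  *exactly*: this model is the clean null fixture for "observed d = 0 ⇒
  p = 1", while type-I calibration uses plain (unpinned) uniform draws.
* `swap_symmetric` — a uniform set unioned with its own axis-swap image
  (odd n adds one diagonal point), so d_nec = d_suf by construction and
  the bootstrap difference distribution is symmetric about zero.

**Estimator bias.**  The CE-FDH step nests *below* a straight frontier
through the data, so the measured empty area at finite n slightly
*over*-estimates the generating corner fraction; shrinkage of the
empirical scope (the observed maxima fall short of the square's edge)
offsets only part of this.  At fraction 0.5, fifty seeds give d within
[0.495, 0.513] at n = 5000, tightening to [0.500, 0.504] at n = 50,000,
converging to the analytic 0.5 from above; the recovery test asserts
|d − 0.5| ≤ 0.02 at n = 5000.  The recovery error roughly halves per
four-fold increase in n.

What the generators do not emulate: discrete Likert-type marginals,
instrument-specific score distributions, or measurement error.  Passing
the recovery and calibration tests shows the estimators and tests behave
as designed under their own assumptions, not that any particular real
association is necessary or sufficient.

## I/O conventions

CSV in: comma-separated, header row, UTF-8; columns selected by name;
rows with a missing or non-numeric entry in either column are dropped
listwise, with the drop count and per-column n/mean/sd logged so they can
be checked against a source study's descriptives.  Spreadsheet formats are
deliberately not parsed; convert to CSV first.  Floats are written at full
precision (`%.17g`) and read back with round-trip parsing, so
generator → CSV → loader is bit-exact.

Reports: the TSV row rounds to 3 decimals, renders p < 0.001 as
"<0.001" and the difference as "mean (SE)"; JSON carries full precision
plus seeds, technique, the plug-in difference, skip counts and the guard
flag, and contains no timestamps, so fixed inputs give byte-identical
output.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run at sizes chosen to finish
in seconds on one CPU while keeping every Monte-Carlo band comfortably
wider than its standard error: grid-oracle comparisons at G = 2000 over
100 random samples, exhaustive permutation enumeration up to n = 6 against
K = 20,000 sampled draws, type-I calibration with 400 replicates of n =
100 at K = 200, recovery at n = 5000, and the full pipeline at the default
n = 533 with K = B = 10,000.

## Known limitations

* Only the bivariate, single-determinant analysis is covered: no
  bottleneck tables, no multiple simultaneous determinants, no CE-VRS or
  quantile-regression ceilings, no confidence intervals for d.
* The bootstrap Z referral to the standard normal is an approximation; at
  very small n the difference distribution can be lumpy and the flagged
  SE = 0 path is the only protection against outright degeneracy.
* The permutation p's add-one smoothing is a deliberate convention; other
  implementations may divide by K without the +1 and can report p = 0.
* Effect sizes are scope-relative: adding even one extreme observation
  changes the scope rectangle and hence every d.
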