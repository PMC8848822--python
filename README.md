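# extnca — extended necessary condition analysis

Necessary condition analysis (NCA) asks whether a low value of a
determinant X *precludes* a high value of an outcome Y, by measuring how
much of the upper-left corner of the X–Y scatter is empty.  A widely
discussed pitfall is that a significant NCA result is often read as "X is
necessary but not sufficient for Y", when the test by itself only detects
some unspecified non-randomness in the association.  `extnca` implements
the extended form of the analysis that makes the conclusion specific: it
quantifies **both** directions and tests their difference.

For a sample of paired observations (x_i, y_i):

* the **scope** is the empirical rectangle
  [min x, max x] × [min y, max y];
* the **necessity effect** is d = A_ceiling / A_scope, where A_ceiling is
  the area between the ceiling line and the top of the scope.  The default
  ceiling is CE-FDH (ceiling envelopment with a free disposal hull): the
  lowest non-decreasing step function c(x) = max{y_i : x_i ≤ x} with no
  point above it.  CR-FDH (the OLS line through the CE-FDH peers) is
  available as an alternative;
* the **sufficiency effect** of X on Y is the empty lower-right corner,
  which is identically the necessity effect of Y on X and is computed as
  such;
* each effect gets a **permutation p-value** (y re-shuffled against x,
  default 10,000 draws, add-one smoothing so p ≥ 1/(K+1));
* the **difference** d_nec − d_suf gets a bootstrap Z-test: over resamples
  drawn with replacement (default 10,000), Z = mean(differences) /
  sd(differences), with a two-sided normal p;
* an **interpretation layer** combines the three tests — equal degrees of
  necessity and sufficiency, necessity-dominant, sufficiency-dominant, or
  no detected non-randomness — guarded by the rule that a significant
  difference is only interpreted when the *stronger* effect is itself
  permutation-significant, and flags data that contradict a "necessary but
  not sufficient" reading (a significant reverse-direction necessity
  effect does exactly that).

## Worked example

Five points (1,2), (2,3), (3,3), (4,5), (5,4).  The scope is 4 wide by 3
tall (area 12); the CE-FDH ceiling steps through 2, 3, 3, 5, 5, leaving an
empty upper-left area of 7.

```sh
python examples/01_effect_sizes.py
```

```
scope: x [1.0, 5.0], y [2.0, 5.0], area 12.0
ceiling steps: ((1.0, 2.0), (2.0, 3.0), (3.0, 3.0), (4.0, 5.0), (5.0, 5.0))
ceiling peers: ((1.0, 2.0), (2.0, 3.0), (4.0, 5.0))
empty upper-left area: 7.0
ce_fdh: necessity d = 0.5833, sufficiency d = 0.5000
cr_fdh: necessity d = 0.3750, sufficiency d = 0.3333
```

necessity d = 7/12: over half the scope is a forbidden upper-left corner —
in this toy data a low x strongly precludes a high y.  The sufficiency
effect 6/12 is the empty lower-right corner (equivalently, the necessity
of y on x).  CR-FDH replaces the step with the least-squares line through
the three peers, which here is y = x + 1, giving the smaller d = 4.5/12.

The full pipeline on synthetic data whose two corners are empty by
construction (diagonal band, each corner's asymptotic fraction 0.12):

```sh
python examples/02_extended_analysis.py
```

```
variables	necessity_d	necessity_p	sufficiency_d	sufficiency_p	difference_d_se	difference_p
x -> y	0.147	<0.001	0.161	<0.001	-0.012 (0.007)	0.087
# interpretation: equal_degrees (guard_ok=true)
# note: the reverse-direction necessity effect (sufficiency of x on y) is significant, which contradicts a 'necessary but not sufficient' reading of x for y
```

Both corners are significantly empty but their difference is not
significant, so the association is read as *equally* necessary and
sufficient — the specific conclusion the original one-corner analysis
cannot deliver.

## Command line

```sh
extnca simulate --model both --n 533 --fraction 0.12 --seed 1 -o band.csv
extnca analyze band.csv --x x --y y --seed 1 --format json --plot diag.png
```

`analyze` reads a CSV (header row, listwise deletion of incomplete rows,
drop counts and per-column descriptives logged), prints the one-row report
as TSV or full-precision JSON, and optionally writes a two-panel figure:
the scatter with scope rectangle, ceiling and floor, plus the histogram of
the bootstrap differences with zero marked.  A fixed seed makes the JSON
byte-identical across runs.

## Layout

- `src/extnca/core.py` — scope, CE-FDH / CR-FDH ceilings, exact corner
  areas, effect sizes
- `src/extnca/inference.py` — permutation test, bootstrap difference
  Z-test, interpretation logic, orchestrator
- `src/extnca/synthetic.py` — seeded generators with known corner
  structure
- `src/extnca/io.py` — CSV loading, TSV/JSON reports, diagnostics figure
- `src/extnca/cli.py` — the `extnca` command
- `docs/methods.md` — model, conventions and numerical choices
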