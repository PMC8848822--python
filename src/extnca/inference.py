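"""Resampling inference and the interpretation layer.

Three pieces sit on top of the corner-area effect sizes:

* a permutation test per direction — the observed pairing of x and y is
  destroyed by shuffling, the effect size recomputed each time, and the
  upper-tail p-value reported with add-one smoothing so p is never 0;
* a bootstrap Z-test for the necessity-minus-sufficiency difference — the
  difference d_nec - d_suf is recomputed over resamples drawn with
  replacement, and Z = mean(differences) / sd(differences), with a
  two-sided standard-normal p;
* a logic layer that turns the three p-values into one of four readings
  (necessity-dominant, sufficiency-dominant, equal degrees, or no detected
  non-randomness), guarded by the rule that a significant difference is
  only interpreted when the *stronger* of the two effects is itself
  permutation-significant.

A significant necessity effect alone does not establish that x is necessary
but not sufficient for y: by elementary logic, if x were necessary but not
sufficient for y then y would have to be sufficient (and not necessary) for
x, so a significant reverse-direction necessity effect contradicts that
reading.  The interpretation layer emits a note when the data show this
contradiction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import (
    Direction,
    EffectResult,
    PairedSample,
    Technique,
    cefdh_d,
    compute_scope,
    effect,
    necessity_effect,
)
from .exceptions import ParameterError

logger = logging.getLogger(__name__)

Interpretation = str  # one of INTERPRETATIONS

INTERPRETATIONS = (
    "necessity_dominant",
    "sufficiency_dominant",
    "equal_degrees",
    "no_nonrandomness",
)

DEFAULT_PERMUTATIONS = 10_000
DEFAULT_BOOTSTRAP = 10_000
DEFAULT_ALPHA = 0.05


# ---------------------------------------------------------------------------
# Result types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PermutationResult:
    d_obs: float
    p: float
    n_permutations: int
    seed: int | None
    direction: Direction
    technique: Technique


@dataclass(frozen=True)
class BootstrapDifferenceResult:
    mean_diff: float
    se_diff: float
    z: float
    p: float
    n_bootstrap: int
    seed: int | None
    plugin_diff: float
    n_skipped: int = 0
    se_zero: bool = False
    differences: np.ndarray = field(default=None, repr=False, compare=False)


@dataclass(frozen=True)
class ExtendedReport:
    """One table row of the extended analysis: both directions with
    permutation p-values, the bootstrap difference test, the guard flag and
    the logical interpretation."""

    labels: tuple[str, str]
    n: int
    technique: Technique
    alpha: float
    necessity: EffectResult
    necessity_p: PermutationResult
    sufficiency: EffectResult
    sufficiency_p: PermutationResult
    difference: BootstrapDifferenceResult
    guard_ok: bool
    interpretation: Interpretation
    notes: tuple[str, ...]
    seed: int | None


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------

def permutation_p(
    sample: PairedSample,
    direction: Direction = "necessity_x_on_y",
    technique: Technique = "ce_fdh",
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int | np.random.SeedSequence | None = None,
) -> PermutationResult:
    """Permutation significance of one direction's effect size.

    The outcome vector is shuffled against the fixed determinant vector
    ``n_permutations`` times and d recomputed each time.  For the
    sufficiency direction the sample is axis-swapped first (sufficiency of
    x on y is the necessity of y on x), then shuffled the same way.  The
    p-value uses add-one smoothing,

        p = (#{d_perm >= d_obs} + 1) / (K + 1),

    so p >= 1/(K+1) and permuted values tied with d_obs count against the
    observed effect (conservative).
    """
    if n_permutations < 1:
        raise ParameterError("n_permutations must be >= 1")
    work = sample if direction == "necessity_x_on_y" else sample.swapped()
    scope = compute_scope(work)  # raises on degenerate scope
    d_obs = necessity_effect(work, technique).d

    rng = np.random.default_rng(seed)
    order = np.argsort(work.x, kind="stable")
    xs = work.x[order]
    y = work.y

    # Shuffling permutes the y multiset only, so the scope rectangle is
    # invariant across permutations; assert rather than recompute per draw.
    assert scope == compute_scope(PairedSample(work.x, np.roll(y, 1)))

    if technique == "ce_fdh":
        perm = rng.permuted(np.broadcast_to(y, (n_permutations, y.size)), axis=1)
        cm = np.maximum.accumulate(perm, axis=1)
        widths = np.diff(xs)
        zones = np.sum((scope.y_max - cm[:, :-1]) * widths, axis=1)
        d_perm = zones / scope.area
    else:
        d_perm = np.empty(n_permutations)
        for k in range(n_permutations):
            ys = rng.permutation(y)
            d_perm[k] = necessity_effect(PairedSample(work.x, ys), technique).d

    count = int(np.sum(d_perm >= d_obs))
    p = (count + 1) / (n_permutations + 1)
    return PermutationResult(
        d_obs=float(d_obs), p=float(p), n_permutations=n_permutations,
        seed=_seed_repr(seed), direction=direction, technique=technique,
    )


# ---------------------------------------------------------------------------
# Bootstrap difference test
# ---------------------------------------------------------------------------

def bootstrap_difference(
    sample: PairedSample,
    technique: Technique = "ce_fdh",
    n_bootstrap: int = DEFAULT_BOOTSTRAP,
    seed: int | np.random.SeedSequence | None = None,
) -> BootstrapDifferenceResult:
    """Bootstrap Z-test for the necessity-minus-sufficiency difference.

    Draws n rows with replacement ``n_bootstrap`` times; for each resample
    with a non-degenerate scope computes d_nec - d_suf.  The reported
    statistic is the mean of those differences divided by their sample
    standard deviation (the bootstrap SE), referred to the standard normal
    two-sidedly.  Resamples whose scope degenerates are skipped and counted.
    The observed plug-in difference is reported alongside.
    """
    if n_bootstrap < 2:
        raise ParameterError("n_bootstrap must be >= 2")
    compute_scope(sample)  # raises on degenerate scope
    plugin = necessity_effect(sample, technique).d - sufficiency_effect_d(sample, technique)

    rng = np.random.default_rng(seed)
    n = sample.n
    idx = rng.integers(0, n, size=(n_bootstrap, n))

    if technique == "ce_fdh":
        diffs = _cefdh_diffs_vectorized(sample.x, sample.y, idx)
    else:
        diffs = np.empty(n_bootstrap)
        for k in range(n_bootstrap):
            xb, yb = sample.x[idx[k]], sample.y[idx[k]]
            dn = cr_pair_d(xb, yb)
            ds = cr_pair_d(yb, xb)
            diffs[k] = dn - ds if (dn == dn and ds == ds) else np.nan

    valid = diffs[~np.isnan(diffs)]
    n_skipped = int(n_bootstrap - valid.size)
    if n_skipped:
        logger.info("bootstrap_difference: skipped %d degenerate resamples", n_skipped)
    if valid.size < 2:
        raise ParameterError("fewer than 2 non-degenerate bootstrap resamples")

    mean_diff = float(valid.mean())
    se_diff = float(valid.std(ddof=1))
    if se_diff == 0.0:
        logger.warning("bootstrap_difference: difference constant across resamples")
        return BootstrapDifferenceResult(
            mean_diff=mean_diff, se_diff=0.0, z=float("nan"), p=1.0,
            n_bootstrap=n_bootstrap, seed=_seed_repr(seed), plugin_diff=float(plugin),
            n_skipped=n_skipped, se_zero=True, differences=valid,
        )
    z = mean_diff / se_diff
    p = float(2.0 * stats.norm.sf(abs(z)))
    return BootstrapDifferenceResult(
        mean_diff=mean_diff, se_diff=se_diff, z=float(z), p=p,
        n_bootstrap=n_bootstrap, seed=_seed_repr(seed), plugin_diff=float(plugin),
        n_skipped=n_skipped, differences=valid,
    )


def sufficiency_effect_d(sample: PairedSample, technique: Technique) -> float:
    from .core import sufficiency_effect
    return sufficiency_effect(sample, technique).d


def cr_pair_d(x: np.ndarray, y: np.ndarray) -> float:
    """CR-FDH necessity d for raw arrays; nan on degenerate scope."""
    try:
        return necessity_effect(PairedSample(x, y), "cr_fdh").d
    except Exception:
        return float("nan")


def _cefdh_diffs_vectorized(x: np.ndarray, y: np.ndarray,
                            idx: np.ndarray) -> np.ndarray:
    """d_nec - d_suf per bootstrap resample (rows of ``idx``), CE-FDH.

    Degenerate resamples (zero x- or y-range) yield nan.
    """
    xb = x[idx]
    yb = y[idx]
    dn = _cefdh_d_rows(xb, yb)
    ds = _cefdh_d_rows(yb, xb)
    return dn - ds


def _cefdh_d_rows(xb: np.ndarray, yb: np.ndarray) -> np.ndarray:
    """Row-wise CE-FDH necessity d for (B, n) paired arrays; nan where the
    resampled scope is degenerate."""
    order = np.argsort(xb, axis=1, kind="stable")
    xs = np.take_along_axis(xb, order, axis=1)
    ys = np.take_along_axis(yb, order, axis=1)
    cm = np.maximum.accumulate(ys, axis=1)
    widths = np.diff(xs, axis=1)
    ymax = ys.max(axis=1)
    ymin = ys.min(axis=1)
    zones = np.sum((ymax[:, None] - cm[:, :-1]) * widths, axis=1)
    xrange_ = xs[:, -1] - xs[:, 0]
    yrange = ymax - ymin
    with np.errstate(divide="ignore", invalid="ignore"):
        d = zones / (xrange_ * yrange)
    d[(xrange_ == 0) | (yrange == 0)] = np.nan
    return d


# ---------------------------------------------------------------------------
# Interpretation
# ---------------------------------------------------------------------------

def interpret_pattern(
    necessity_p: PermutationResult,
    sufficiency_p: PermutationResult,
    difference: BootstrapDifferenceResult,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[Interpretation, bool, tuple[str, ...]]:
    """Combine the three tests into a reading of the association.

    Returns (interpretation, guard_ok, notes).  ``guard_ok`` is true iff the
    larger of the two effect sizes is itself permutation-significant; a
    significant difference should not be interpreted without it.
    """
    nec_sig = necessity_p.p < alpha
    suf_sig = sufficiency_p.p < alpha
    if necessity_p.d_obs >= sufficiency_p.d_obs:
        guard_ok = nec_sig
    else:
        guard_ok = suf_sig

    notes: list[str] = []
    if not (nec_sig or suf_sig):
        interpretation = "no_nonrandomness"
    elif difference.p >= alpha:
        interpretation = "equal_degrees"
    elif difference.mean_diff > 0:
        interpretation = "necessity_dominant"
    else:
        interpretation = "sufficiency_dominant"

    if not guard_ok and difference.p < alpha:
        notes.append(
            "difference is significant but the stronger effect is not "
            "permutation-significant; do not interpret the difference"
        )
    if suf_sig:
        notes.append(
            "the reverse-direction necessity effect (sufficiency of x on y) "
            "is significant, which contradicts a 'necessary but not "
            "sufficient' reading of x for y"
        )
    if difference.se_zero:
        notes.append("difference constant across bootstrap resamples (SE = 0)")
    return interpretation, guard_ok, tuple(notes)


# ---------------------------------------------------------------------------
# Orchestrator
# ---------------------------------------------------------------------------

def run_extended_nca(
    sample: PairedSample,
    technique: Technique = "ce_fdh",
    n_permutations: int = DEFAULT_PERMUTATIONS,
    n_bootstrap: int = DEFAULT_BOOTSTRAP,
    seed: int | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> ExtendedReport:
    """Run the full extended analysis and assemble one report row.

    Sub-seeds for the permutation and bootstrap stages are derived
    reproducibly from the master seed; the same master seed yields a
    bit-identical report.  Both permutation tests share one sub-seed so the
    report is exactly equivariant under axis swap of the input (the
    necessity and sufficiency blocks exchange and the difference negates).
    """
    ss = np.random.SeedSequence(seed)
    perm_ss, boot_ss = ss.spawn(2)

    nec = necessity_effect(sample, technique)
    suf = effect(sample, "sufficiency_x_on_y", technique)
    nec_p = permutation_p(sample, "necessity_x_on_y", technique, n_permutations, perm_ss)
    suf_p = permutation_p(sample, "sufficiency_x_on_y", technique, n_permutations, perm_ss)
    diff = bootstrap_difference(sample, technique, n_bootstrap, boot_ss)
    interpretation, guard_ok, notes = interpret_pattern(nec_p, suf_p, diff, alpha)

    logger.info(
        "extended NCA: n=%d technique=%s seed=%s d_nec=%.4f (p=%.4g) "
        "d_suf=%.4f (p=%.4g) diff=%.4f (SE=%.4f, p=%.4g) -> %s",
        sample.n, technique, seed, nec.d, nec_p.p, suf.d, suf_p.p,
        diff.mean_diff, diff.se_diff, diff.p, interpretation,
    )
    return ExtendedReport(
        labels=sample.labels, n=sample.n, technique=technique, alpha=alpha,
        necessity=nec, necessity_p=nec_p, sufficiency=suf, sufficiency_p=suf_p,
        difference=diff, guard_ok=guard_ok, interpretation=interpretation,
        notes=notes, seed=seed,
    )


def _seed_repr(seed) -> int | None:
    if seed is None:
        return None
    if isinstance(seed, np.random.SeedSequence):
        return int(seed.entropy) if isinstance(seed.entropy, int) and seed.entropy < 2**63 else None
    return int(seed)
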