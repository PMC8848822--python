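"""Core necessary-condition-analysis geometry.

NCA quantifies to what degree a low value of a determinant X precludes a
high value of an outcome Y by measuring the empty region in the upper-left
corner of the X-Y scatter.  The empirical *scope* is the rectangle spanned
by the observed minima and maxima of both variables; a *ceiling* bounds the
occupied region from above; the *effect size* d is the area between the
ceiling and the top of the scope, divided by the scope area, so d lies in
[0, 1].

Two ceiling techniques are provided:

* ``ce_fdh`` — ceiling envelopment with a free disposal hull: the lowest
  non-decreasing, right-continuous step function with no observation
  strictly above it, c(x) = max{y_i : x_i <= x}.
* ``cr_fdh`` — ceiling regression: the ordinary least-squares line through
  the CE-FDH peers (the non-dominated upper-left observations), clipped to
  the scope rectangle.

The *sufficiency* effect of X on Y (the empty lower-right corner) is, by
construction, the necessity effect of Y on X, and is computed that way.

All areas are computed in closed form (rectangle and trapezoid sums), never
by numerical quadrature, so results are deterministic to machine precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .exceptions import DegenerateScopeError, InsufficientDataError

logger = logging.getLogger(__name__)

Direction = Literal["necessity_x_on_y", "sufficiency_x_on_y"]
Technique = Literal["ce_fdh", "cr_fdh"]

TECHNIQUES: tuple[str, ...] = ("ce_fdh", "cr_fdh")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairedSample:
    """A cleaned set of paired observations (x_i, y_i).

    Missing-data handling happens upstream (see :func:`extnca.io.load_sample`);
    a PairedSample always holds complete, finite pairs.
    """

    x: np.ndarray
    y: np.ndarray
    labels: tuple[str, str] = ("x", "y")

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if x.size < 2:
            raise InsufficientDataError(
                f"need at least 2 complete pairs, got {x.size}"
            )
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValueError("x and y must be finite (clean missing values upstream)")

    @property
    def n(self) -> int:
        return int(self.x.size)

    def swapped(self) -> "PairedSample":
        """The axis-swapped sample (x <-> y), used for sufficiency effects."""
        return PairedSample(self.y, self.x, (self.labels[1], self.labels[0]))


@dataclass(frozen=True)
class Scope:
    """The empirical bounding rectangle of a sample and its area."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)

    def swapped(self) -> "Scope":
        return Scope(self.y_min, self.y_max, self.x_min, self.x_max)


@dataclass(frozen=True)
class CeilingStep:
    """A right-continuous, non-decreasing step ceiling c(x) on the scope.

    ``knots`` holds one (x_break, level) pair per distinct observed x, with
    level = max{y_i : x_i <= x_break}; c(x) equals the level of the largest
    break not exceeding x.  ``peers`` are the observations at which the
    running maximum strictly increases — the non-dominated upper-left points
    that generate the hull.
    """

    knots: tuple[tuple[float, float], ...]
    peers: tuple[tuple[float, float], ...]

    def __call__(self, x: float | np.ndarray) -> np.ndarray:
        xb = np.array([k[0] for k in self.knots])
        lv = np.array([k[1] for k in self.knots])
        idx = np.clip(np.searchsorted(xb, np.asarray(x, dtype=float), side="right") - 1, 0, None)
        return lv[idx]

    @property
    def levels(self) -> np.ndarray:
        return np.array([k[1] for k in self.knots])

    @property
    def breaks(self) -> np.ndarray:
        return np.array([k[0] for k in self.knots])


@dataclass(frozen=True)
class CeilingLine:
    """A straight ceiling y = intercept + slope * x (the CR-FDH line)."""

    slope: float
    intercept: float
    peers: tuple[tuple[float, float], ...] = field(default=())
    fallback_step: CeilingStep | None = None

    def __call__(self, x: float | np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


@dataclass(frozen=True)
class EffectResult:
    """One direction's effect size with the areas that produced it."""

    direction: Direction
    technique: Technique
    d: float
    ceiling_zone: float
    scope_area: float


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def compute_scope(sample: PairedSample) -> Scope:
    """The empirical scope rectangle spanned by observed min/max of x and y.

    Raises
    ------
    DegenerateScopeError
        If x or y has zero range, so the rectangle has no area and effect
        sizes are undefined.
    """
    x_min, x_max = float(sample.x.min()), float(sample.x.max())
    y_min, y_max = float(sample.y.min()), float(sample.y.max())
    if x_min == x_max or y_min == y_max:
        raise DegenerateScopeError(
            f"scope degenerate: x range {x_max - x_min}, y range {y_max - y_min}"
        )
    return Scope(x_min, x_max, y_min, y_max)


def ce_fdh_ceiling(sample: PairedSample, scope: Scope | None = None) -> CeilingStep:
    """The CE-FDH step ceiling: lowest non-decreasing right-continuous step
    function with no observation strictly above it, c(x) = max{y_i : x_i <= x}.
    """
    if scope is None:
        scope = compute_scope(sample)
    order = np.argsort(sample.x, kind="stable")
    xs = sample.x[order]
    ys = sample.y[order]
    ux, last_idx = _unique_last(xs)
    run_max = np.maximum.accumulate(ys)[last_idx]  # level at each distinct x
    knots = tuple(zip(ux.tolist(), run_max.tolist()))
    # peers: first attainment of each strict increase of the running max
    prev = np.concatenate(([-np.inf], run_max[:-1]))
    rising = run_max > prev
    peers = tuple(zip(ux[rising].tolist(), run_max[rising].tolist()))
    return CeilingStep(knots=knots, peers=peers)


def ceiling_zone_area(ceiling: CeilingStep | CeilingLine, scope: Scope) -> float:
    """Exact area of the empty region above the ceiling inside the scope.

    For a step ceiling this is a finite rectangle sum
    sum_k (x_{k+1} - x_k) * (y_max - c(x_k)); for a line it is the exact
    trapezoid/triangle area above the line clipped to the scope rectangle.
    """
    if isinstance(ceiling, CeilingLine):
        return _area_above_line(ceiling.slope, ceiling.intercept, scope)
    xb = ceiling.breaks
    lv = ceiling.levels
    edges = np.concatenate((xb, [scope.x_max]))
    widths = np.diff(edges)
    area = float(np.sum(widths * (scope.y_max - lv)))
    return max(area, 0.0)


def cr_fdh_ceiling(sample: PairedSample, scope: Scope | None = None) -> CeilingLine:
    """The CR-FDH ceiling: OLS line through the CE-FDH peers.

    With fewer than 2 distinct peers no line is identified; the CE-FDH step
    is kept as a fallback (carried on the returned object) and a warning is
    logged.
    """
    if scope is None:
        scope = compute_scope(sample)
    step = ce_fdh_ceiling(sample, scope)
    px = np.array([p[0] for p in step.peers])
    py = np.array([p[1] for p in step.peers])
    if np.unique(px).size < 2:
        logger.warning(
            "cr_fdh: fewer than 2 distinct CE-FDH peers; falling back to the "
            "CE-FDH step ceiling"
        )
        return CeilingLine(slope=0.0, intercept=float(py.max()),
                           peers=step.peers, fallback_step=step)
    slope, intercept = np.polyfit(px, py, 1)
    return CeilingLine(slope=float(slope), intercept=float(intercept), peers=step.peers)


def necessity_effect(sample: PairedSample, technique: Technique = "ce_fdh") -> EffectResult:
    """Necessity effect of x on y: relative empty upper-left area.

    d = (area above the ceiling inside the scope) / (scope area).
    """
    scope = compute_scope(sample)
    if technique == "ce_fdh":
        zone = ceiling_zone_area(ce_fdh_ceiling(sample, scope), scope)
    elif technique == "cr_fdh":
        line = cr_fdh_ceiling(sample, scope)
        if line.fallback_step is not None:
            zone = ceiling_zone_area(line.fallback_step, scope)
        else:
            zone = ceiling_zone_area(line, scope)
    else:
        raise ValueError(f"unknown technique {technique!r}")
    d = zone / scope.area
    return EffectResult(
        direction="necessity_x_on_y",
        technique=technique,
        d=float(d),
        ceiling_zone=float(zone),
        scope_area=float(scope.area),
    )


def sufficiency_effect(sample: PairedSample, technique: Technique = "ce_fdh") -> EffectResult:
    """Sufficiency effect of x on y: relative empty lower-right area.

    Equal, by construction, to the necessity effect of y on x, and computed
    as such on the axis-swapped sample.
    """
    res = necessity_effect(sample.swapped(), technique)
    return replace(res, direction="sufficiency_x_on_y")


def effect(sample: PairedSample, direction: Direction,
           technique: Technique = "ce_fdh") -> EffectResult:
    """Dispatch on direction."""
    if direction == "necessity_x_on_y":
        return necessity_effect(sample, technique)
    if direction == "sufficiency_x_on_y":
        return sufficiency_effect(sample, technique)
    raise ValueError(f"unknown direction {direction!r}")


# ---------------------------------------------------------------------------
# Internals
# ---------------------------------------------------------------------------

def _unique_last(sorted_x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Distinct values of an already-sorted array and the index of the last
    occurrence of each (so running maxima absorb ties in x)."""
    change = np.concatenate((sorted_x[1:] != sorted_x[:-1], [True]))
    idx = np.nonzero(change)[0]
    return sorted_x[idx], idx


def _area_above_line(slope: float, intercept: float, scope: Scope) -> float:
    """Exact area of {(x, y) in scope : y > slope*x + intercept}.

    The line clipped to [y_min, y_max] is piecewise linear in x; splitting
    [x_min, x_max] at the (in-range) crossings with y_min and y_max makes the
    integrand linear on each piece, so the trapezoid rule is exact.
    """
    cuts = [scope.x_min, scope.x_max]
    if slope != 0.0:
        for level in (scope.y_min, scope.y_max):
            xc = (level - intercept) / slope
            if scope.x_min < xc < scope.x_max:
                cuts.append(xc)
    cuts = sorted(cuts)
    area = 0.0
    for a, b in zip(cuts[:-1], cuts[1:]):
        ga = min(max(intercept + slope * a, scope.y_min), scope.y_max)
        gb = min(max(intercept + slope * b, scope.y_min), scope.y_max)
        area += (b - a) * (scope.y_max - 0.5 * (ga + gb))
    return max(area, 0.0)


def _cefdh_zone_rows(x_sorted: np.ndarray, y_rows: np.ndarray) -> np.ndarray:
    """Vectorized CE-FDH zone areas for many y-vectors against one sorted x.

    ``y_rows`` has shape (B, n), already aligned to ``x_sorted`` order.
    Returns the zone area per row, using each row's own y-maximum as the
    scope top (the x-range is shared).  Tied x's contribute zero-width
    segments, so the running maximum absorbs them correctly.
    """
    cm = np.maximum.accumulate(y_rows, axis=1)
    widths = np.diff(x_sorted)
    ymax = cm[:, -1][:, None]
    return np.sum((ymax - cm[:, :-1]) * widths, axis=1)


def cefdh_d(x: np.ndarray, y: np.ndarray) -> float:
    """CE-FDH necessity d for raw arrays (fast path, no object construction).

    Returns nan for degenerate scope.
    """
    order = np.argsort(x, kind="stable")
    xs = x[order]
    ys = y[order]
    xr = xs[-1] - xs[0]
    ymin, ymax = ys.min(), ys.max()
    if xr == 0 or ymax == ymin:
        return float("nan")
    cm = np.maximum.accumulate(ys)
    zone = np.sum(np.diff(xs) * (ymax - cm[:-1]))
    return float(zone / (xr * (ymax - ymin)))
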