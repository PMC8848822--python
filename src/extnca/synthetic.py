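"""Seeded bivariate generators with known necessity/sufficiency structure.

Each model produces points on the unit square with a controllable empty
corner, so that every inference path can be exercised with a known ground
truth:

* ``necessity_only`` — points uniform below a straight ceiling running from
  (0, 1-h) to (1, 1) with h = 2*ceiling_fraction, so the excluded
  upper-left triangle has area exactly ``ceiling_fraction`` of the unit
  square.  At ceiling_fraction = 0.5 the ceiling is the diagonal y = x.
* ``sufficiency_only`` — the axis swap of necessity_only (same seed).
* ``both`` — a diagonal band: uniform between the slope-one floor and
  ceiling offset so that each excluded corner triangle has area
  ``ceiling_fraction``.
* ``independent`` — uniform on the square.
* ``swap_symmetric`` — the union of a uniform set with its own axis-swap
  image, so necessity and sufficiency effects are equal by construction.

Extreme corner points are pinned (see each model) so the empirical scope is
stable across seeds and the target corner fraction is well defined at
finite n.  This is a fixture choice that makes recovery tests crisp, not a
claim about real survey data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .core import PairedSample
from .exceptions import ParameterError

Model = Literal[
    "necessity_only", "sufficiency_only", "both", "independent", "swap_symmetric"
]

MODELS: tuple[str, ...] = (
    "necessity_only", "sufficiency_only", "both", "independent", "swap_symmetric"
)

#: Default sample size: the size of the quarantine survey sample the method
#: was demonstrated on.
DEFAULT_N = 533

#: Default corner fraction: a modest empty corner of the magnitude typical
#: of the well-being/resilience effect sizes (d ~ 0.12).
DEFAULT_FRACTION = 0.12


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of one synthetic sample.

    ``ceiling_fraction`` is the asymptotic area of the excluded corner
    region relative to the unit square (per corner, for the ``both`` model).
    """

    model: Model
    n: int = DEFAULT_N
    seed: int | None = None
    ceiling_fraction: float = DEFAULT_FRACTION

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ParameterError(f"unknown model {self.model!r}")
        if self.n < 3:
            raise ParameterError("n must be >= 3")
        if not (0.0 <= self.ceiling_fraction < 1.0):
            raise ParameterError("ceiling_fraction must be in [0, 1)")
        if self.model in ("necessity_only", "sufficiency_only") and \
                self.ceiling_fraction > 0.5:
            raise ParameterError(
                f"ceiling_fraction {self.ceiling_fraction} infeasible for "
                f"{self.model}: a straight unit-square ceiling excludes at "
                "most half the square"
            )
        if self.model == "both" and self.ceiling_fraction >= 0.5:
            raise ParameterError(
                f"ceiling_fraction {self.ceiling_fraction} infeasible for "
                "'both': the two excluded corner triangles would leave an "
                "empty band"
            )


def generate(spec: GeneratorSpec) -> PairedSample:
    """Generate one sample; the same spec and seed give an identical sample."""
    rng = np.random.default_rng(spec.seed)
    if spec.model == "necessity_only":
        x, y = _necessity_points(spec.n, spec.ceiling_fraction, rng)
    elif spec.model == "sufficiency_only":
        y, x = _necessity_points(spec.n, spec.ceiling_fraction, rng)
    elif spec.model == "both":
        x, y = _band_points(spec.n, spec.ceiling_fraction, rng)
    elif spec.model == "independent":
        x, y = _independent_points(spec.n, rng)
    else:
        x, y = _swap_symmetric_points(spec.n, rng)
    return PairedSample(x, y, labels=("x", "y"))


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------

def _necessity_points(n: int, fraction: float, rng: np.random.Generator):
    """Uniform below the ceiling y = (1-h) + h*x, h = 2*fraction, with the
    corners (0, 0) and (1, 1-h) pinned so the empirical scope is stable."""
    h = 2.0 * fraction
    pinned_x = np.array([0.0, 1.0])
    pinned_y = np.array([0.0, 1.0 - h])
    xs, ys = _rejection_uniform(
        n - 2, rng, lambda x, y: y <= (1.0 - h) + h * x
    )
    return np.concatenate((pinned_x, xs)), np.concatenate((pinned_y, ys))


def _band_points(n: int, fraction: float, rng: np.random.Generator):
    """Uniform in the diagonal band |y - x| <= 1 - h, where the excluded
    slope-one corner triangles each have area h^2/2 = fraction.  Corners
    (0, 0) and (1, 1) pinned."""
    h = float(np.sqrt(2.0 * fraction))
    half_width = 1.0 - h
    pinned_x = np.array([0.0, 1.0])
    pinned_y = np.array([0.0, 1.0])
    xs, ys = _rejection_uniform(
        n - 2, rng, lambda x, y: np.abs(y - x) <= half_width
    )
    return np.concatenate((pinned_x, xs)), np.concatenate((pinned_y, ys))


def _independent_points(n: int, rng: np.random.Generator):
    """Uniform on the square with all four corners pinned."""
    if n < 4:
        raise ParameterError("independent model needs n >= 4 (four pinned corners)")
    pinned_x = np.array([0.0, 0.0, 1.0, 1.0])
    pinned_y = np.array([0.0, 1.0, 0.0, 1.0])
    xs = rng.random(n - 4)
    ys = rng.random(n - 4)
    return np.concatenate((pinned_x, xs)), np.concatenate((pinned_y, ys))


def _swap_symmetric_points(n: int, rng: np.random.Generator):
    """Union of a uniform random set with its axis-swap image; for odd n one
    extra point is placed on the diagonal (its own swap image)."""
    half = n // 2
    xs = rng.random(half)
    ys = rng.random(half)
    x = np.concatenate((xs, ys))
    y = np.concatenate((ys, xs))
    if n % 2:
        t = rng.random(1)
        x = np.concatenate((x, t))
        y = np.concatenate((y, t))
    return x, y


def _rejection_uniform(n: int, rng: np.random.Generator, accept):
    """n points uniform on the unit square restricted to ``accept(x, y)``."""
    out_x = np.empty(0)
    out_y = np.empty(0)
    while out_x.size < n:
        need = n - out_x.size
        # geometric convergence for any fixed positive acceptance fraction
        m = max(4 * need, 64)
        x = rng.random(m)
        y = rng.random(m)
        keep = accept(x, y)
        out_x = np.concatenate((out_x, x[keep]))
        out_y = np.concatenate((out_y, y[keep]))
    return out_x[:n], out_y[:n]
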