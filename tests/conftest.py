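"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the library's area code paths: areas are
re-counted on uniform grids of cell centers, the lower-right (sufficiency)
region is integrated directly from its own definition, and small-n
permutation p-values are enumerated exhaustively.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from extnca import PairedSample, compute_scope


@pytest.fixture
def five_point() -> PairedSample:
    """The hand-computed worked example: scope area 12, CE-FDH necessity
    zone 7, sufficiency zone 6."""
    return PairedSample(np.array([1.0, 2, 3, 4, 5]), np.array([2.0, 3, 3, 5, 4]))


@pytest.fixture
def four_corners() -> PairedSample:
    """All four unit-square corners: both corner zones are empty-free, d = 0."""
    return PairedSample(np.array([0.0, 0, 1, 1]), np.array([0.0, 1, 0, 1]))


@pytest.fixture
def diagonal3() -> PairedSample:
    return PairedSample(np.array([0.0, 0.5, 1.0]), np.array([0.0, 0.5, 1.0]))


def grid_d_above(ceiling, sample: PairedSample, G: int = 2000) -> float:
    """Grid oracle: fraction of G x G cell centers of the scope strictly
    above the ceiling function.  Column-wise counting; O(G) space."""
    scope = compute_scope(sample)
    xc = scope.x_min + (np.arange(G) + 0.5) * (scope.x_max - scope.x_min) / G
    yc = scope.y_min + (np.arange(G) + 0.5) * (scope.y_max - scope.y_min) / G
    levels = np.asarray(ceiling(xc), dtype=float)
    # count y centers above each column's ceiling level
    counts = G - np.searchsorted(yc, levels, side="right")
    return float(counts.sum()) / (G * G)


def direct_lower_right_d(sample: PairedSample) -> float:
    """Independent sufficiency oracle: relative area of
    {(x, y) in scope : x > max{x_i : y_i <= y}}, integrated over y as a
    rectangle sum from its own definition (no axis swap, no library areas)."""
    scope = compute_scope(sample)
    order = np.argsort(sample.y, kind="stable")
    ys = sample.y[order]
    xs = sample.x[order]
    run_max_x = np.maximum.accumulate(xs)
    area = 0.0
    for k in range(len(ys) - 1):
        area += (ys[k + 1] - ys[k]) * (scope.x_max - max(run_max_x[: k + 1]))
    return area / scope.area


def exhaustive_permutation_p(sample: PairedSample, d_func) -> float:
    """Exact permutation p over all n! re-pairings: the proportion of
    permuted d values >= the observed d (identity included)."""
    d_obs = d_func(sample.x, sample.y)
    count = 0
    total = 0
    for perm in itertools.permutations(range(sample.n)):
        total += 1
        if d_func(sample.x, sample.y[list(perm)]) >= d_obs:
            count += 1
    return count / total


def random_sample(rng: np.random.Generator, n: int | None = None) -> PairedSample:
    """A random non-degenerate sample for property tests."""
    n = n or int(rng.integers(3, 50))
    while True:
        x = np.round(rng.random(n) * 10, 3)
        y = np.round(rng.random(n) * 10, 3)
        if x.min() < x.max() and y.min() < y.max():
            return PairedSample(x, y)
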