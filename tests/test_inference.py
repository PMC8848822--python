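"""Permutation, bootstrap and interpretation layers."""

import dataclasses

import numpy as np
import pytest

from extnca import (
    PairedSample,
    bootstrap_difference,
    interpret_pattern,
    necessity_effect,
    permutation_p,
    run_extended_nca,
    sufficiency_effect,
)
from extnca.core import cefdh_d
from extnca.inference import BootstrapDifferenceResult, PermutationResult

from conftest import exhaustive_permutation_p, random_sample


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------

class TestPermutation:
    def test_zero_effect_gives_p_one(self, four_corners):
        res = permutation_p(four_corners, n_permutations=200, seed=0)
        assert res.d_obs == 0.0
        assert res.p == 1.0

    def test_p_never_zero_and_smoothed(self, five_point):
        res = permutation_p(five_point, n_permutations=50, seed=1)
        assert res.p >= 1 / 51

    @pytest.mark.parametrize("direction", ["necessity_x_on_y", "sufficiency_x_on_y"])
    def test_matches_exhaustive_enumeration(self, direction):
        """Sampled p agrees with full n! enumeration within 2 binomial SE."""
        rng = np.random.default_rng(5)
        s = random_sample(rng, n=6)
        work = s if direction == "necessity_x_on_y" else s.swapped()
        p_exact = exhaustive_permutation_p(work, cefdh_d)
        K = 20_000
        res = permutation_p(s, direction, n_permutations=K, seed=42)
        se = np.sqrt(p_exact * (1 - p_exact) / K)
        assert abs(res.p - p_exact) <= 2 * se + 2 / K  # + smoothing slack

    def test_reproducible(self, five_point):
        a = permutation_p(five_point, n_permutations=300, seed=9)
        b = permutation_p(five_point, n_permutations=300, seed=9)
        assert a == b

    def test_cr_fdh_path_runs(self, five_point):
        res = permutation_p(five_point, technique="cr_fdh",
                            n_permutations=50, seed=3)
        assert res.d_obs == pytest.approx(4.5 / 12)
        assert 0 < res.p <= 1


# ---------------------------------------------------------------------------
# Bootstrap difference
# ---------------------------------------------------------------------------

class TestBootstrapDifference:
    def test_constant_difference_flagged(self):
        """Every non-degenerate resample of the two-point diagonal is the
        full pair, so the difference never varies: SE = 0, flagged, p = 1."""
        s = PairedSample(np.array([0.0, 1.0]), np.array([0.0, 1.0]))
        res = bootstrap_difference(s, n_bootstrap=200, seed=0)
        assert res.se_zero and res.p == 1.0 and np.isnan(res.z)
        assert res.mean_diff == 0.0
        assert res.n_skipped > 0  # identical-pair resamples are degenerate

    def test_swap_symmetric_sample_centers_on_zero(self):
        rng = np.random.default_rng(2)
        xs = rng.random(100)
        ys = rng.random(100)
        s = PairedSample(np.concatenate([xs, ys]), np.concatenate([ys, xs]))
        B = 2000
        res = bootstrap_difference(s, n_bootstrap=B, seed=7)
        assert res.plugin_diff == pytest.approx(0.0, abs=1e-12)
        assert abs(res.mean_diff) <= 3 * res.se_diff / np.sqrt(B)
        assert res.p > 0.5

    def test_plugin_difference_exact(self, five_point):
        res = bootstrap_difference(five_point, n_bootstrap=100, seed=1)
        assert res.plugin_diff == pytest.approx(7 / 12 - 6 / 12, abs=1e-15)

    def test_matches_independent_reimplementation(self, five_point):
        """Same index-draw protocol, differences recomputed per resample by
        independent scalar code."""
        B, seed = 400, 13
        res = bootstrap_difference(five_point, n_bootstrap=B, seed=seed)
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, five_point.n, size=(B, five_point.n))
        diffs = []
        for k in range(B):
            x, y = five_point.x[idx[k]], five_point.y[idx[k]]
            dn = cefdh_d(x, y)
            ds = cefdh_d(y, x)
            if not (np.isnan(dn) or np.isnan(ds)):
                diffs.append(dn - ds)
        assert res.mean_diff == pytest.approx(np.mean(diffs), abs=1e-14)
        assert res.se_diff == pytest.approx(np.std(diffs, ddof=1), abs=1e-14)

    def test_z_is_mean_over_se(self):
        rng = np.random.default_rng(3)
        s = random_sample(rng, n=40)
        res = bootstrap_difference(s, n_bootstrap=500, seed=5)
        if not res.se_zero:
            assert res.z == pytest.approx(res.mean_diff / res.se_diff)
            from scipy import stats
            assert res.p == pytest.approx(2 * stats.norm.sf(abs(res.z)))


# ---------------------------------------------------------------------------
# Interpretation logic
# ---------------------------------------------------------------------------

def _perm(d, p):
    return PermutationResult(d_obs=d, p=p, n_permutations=10_000, seed=0,
                             direction="necessity_x_on_y", technique="ce_fdh")


def _diff(mean, se, p):
    z = mean / se if se else float("nan")
    return BootstrapDifferenceResult(
        mean_diff=mean, se_diff=se, z=z, p=p, n_bootstrap=10_000, seed=0,
        plugin_diff=mean, se_zero=(se == 0), differences=None)


class TestInterpretation:
    def test_equal_degrees_with_guard(self):
        """Both directions significant, difference flat: the association is
        read as equally necessary and sufficient."""
        interp, guard, notes = interpret_pattern(
            _perm(0.121, 0.0005), _perm(0.137, 0.008), _diff(0.000, 0.033, 0.991))
        assert interp == "equal_degrees" and guard
        # significant reverse-direction necessity contradicts nec-but-not-suf
        assert any("contradicts" in n for n in notes)

    def test_necessity_dominant(self):
        interp, guard, _ = interpret_pattern(
            _perm(0.117, 0.003), _perm(0.032, 0.474), _diff(0.088, 0.021, 0.0005))
        assert interp == "necessity_dominant" and guard

    def test_sufficiency_dominant(self):
        interp, guard, _ = interpret_pattern(
            _perm(0.03, 0.6), _perm(0.2, 0.001), _diff(-0.17, 0.03, 1e-6))
        assert interp == "sufficiency_dominant" and guard

    def test_no_nonrandomness_when_neither_significant(self):
        interp, guard, _ = interpret_pattern(
            _perm(0.05, 0.6), _perm(0.04, 0.7), _diff(0.01, 0.02, 0.01))
        assert interp == "no_nonrandomness"
        assert not guard

    def test_guard_warns_on_uninterpretable_difference(self):
        # larger effect not significant but difference significant
        interp, guard, notes = interpret_pattern(
            _perm(0.05, 0.01), _perm(0.30, 0.20), _diff(-0.25, 0.05, 1e-4))
        assert not guard
        assert any("do not interpret" in n for n in notes)


# ---------------------------------------------------------------------------
# Orchestrator
# ---------------------------------------------------------------------------

class TestRunExtendedNca:
    def test_four_corner_report(self, four_corners):
        rep = run_extended_nca(four_corners, n_permutations=100,
                               n_bootstrap=100, seed=0)
        assert rep.necessity.d == 0.0 and rep.sufficiency.d == 0.0
        assert rep.necessity_p.p == 1.0 and rep.sufficiency_p.p == 1.0
        assert rep.interpretation == "no_nonrandomness"

    def test_composition_matches_parts(self, five_point):
        rep = run_extended_nca(five_point, n_permutations=200,
                               n_bootstrap=200, seed=21)
        assert rep.necessity.d == necessity_effect(five_point).d
        assert rep.sufficiency.d == sufficiency_effect(five_point).d
        perm_ss, boot_ss = np.random.SeedSequence(21).spawn(2)
        assert rep.necessity_p.p == permutation_p(
            five_point, "necessity_x_on_y", "ce_fdh", 200, perm_ss).p
        assert rep.sufficiency_p.p == permutation_p(
            five_point, "sufficiency_x_on_y", "ce_fdh", 200, perm_ss).p
        assert rep.difference.mean_diff == bootstrap_difference(
            five_point, "ce_fdh", 200, boot_ss).mean_diff

    def test_bit_identical_given_seed(self):
        rng = np.random.default_rng(8)
        s = random_sample(rng, n=30)
        a = run_extended_nca(s, n_permutations=150, n_bootstrap=150, seed=4)
        b = run_extended_nca(s, n_permutations=150, n_bootstrap=150, seed=4)
        assert dataclasses.asdict(a)["necessity_p"] == dataclasses.asdict(b)["necessity_p"]
        assert a.difference.mean_diff == b.difference.mean_diff
        assert a.difference.se_diff == b.difference.se_diff
        assert np.array_equal(a.difference.differences, b.difference.differences)

    def test_axis_swap_equivariance(self):
        """Swapping the input axes exchanges the necessity and sufficiency
        blocks and negates the bootstrap difference exactly."""
        rng = np.random.default_rng(14)
        s = random_sample(rng, n=25)
        a = run_extended_nca(s, n_permutations=200, n_bootstrap=200, seed=6)
        b = run_extended_nca(s.swapped(), n_permutations=200, n_bootstrap=200, seed=6)
        assert b.necessity.d == a.sufficiency.d
        assert b.sufficiency.d == a.necessity.d
        assert b.necessity_p.p == a.sufficiency_p.p
        assert b.sufficiency_p.p == a.necessity_p.p
        assert b.difference.mean_diff == -a.difference.mean_diff
        assert b.difference.z == pytest.approx(-a.difference.z)
        assert b.difference.p == a.difference.p
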