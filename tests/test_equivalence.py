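import math

import numpy as np
import pytest

from irtcalib import (
    CalibrationDesign,
    Interval,
    Item,
    check_optimality,
    compute_c_star,
    directional_derivative,
    min_dirderiv,
    unrestricted_d_optimal,
)
from irtcalib.equivalence import (
    _c_star_from_envelope,
    directional_derivative_from_matrix,
)

ITEM1 = Item(1.0, 0.5, "item1")


class TestDirectionalDerivative:
    def test_approaches_two_in_the_tails(self, solved):
        # the GLM weight kills the quadratic term as |theta| grows
        d = solved.design(["item1"], 0.1)
        for theta in (-15.0, 15.0):
            assert directional_derivative(d, theta, 0) == pytest.approx(2.0, abs=1e-3)

    def test_below_two_everywhere_finite(self, solved):
        d = solved.design(["item1"], 0.1)
        theta = np.linspace(-10, 10, 501)
        assert np.all(directional_derivative(d, theta, 0) < 2.0)

    def test_zero_at_unrestricted_support_points(self):
        # general-equivalence-theorem condition for the two-point optimum
        pd = unrestricted_d_optimal(ITEM1)
        M = pd.information_matrix(0)
        for theta in pd.points_by_item[0]:
            assert directional_derivative_from_matrix(ITEM1, M, theta) == pytest.approx(
                0.0, abs=1e-4
            )

    def test_singular_matrix_raises_with_item_name(self, g):
        d = CalibrationDesign([ITEM1, Item(1.5, -1.2, "item2")], [[Interval(-1, 1)], []],
                              g.mass(-1, 1), g)
        with pytest.raises(np.linalg.LinAlgError, match="item2"):
            directional_derivative(d, 0.0, 1)


class TestLowerEnvelope:
    def test_single_item_envelope_equals_curve(self, solved):
        d = solved.design(["item1"], 0.1)
        theta = np.linspace(-4, 4, 101)
        np.testing.assert_allclose(
            min_dirderiv(d, theta), directional_derivative(d, theta, 0), rtol=1e-12
        )

    def test_envelope_below_each_curve(self, solved):
        d = solved.design(["item1", "item3"], 0.5)
        theta = np.linspace(-5, 5, 301)
        env = min_dirderiv(d, theta)
        for i in range(2):
            assert np.all(env <= directional_derivative(d, theta, i) + 1e-12)

    def test_curves_cross_at_competing_boundary(self, solved):
        # the two items' directional derivatives coincide where their upper
        # sampling intervals abut (theta ~ 1.511)
        d = solved.design(["item1", "item3"], 0.5)
        boundary = d.intervals_by_item[0][-1].hi
        f1 = directional_derivative(d, boundary, 0)
        f3 = directional_derivative(d, boundary, 1)
        assert f1 == pytest.approx(f3, abs=5e-3)


class TestThreshold:
    def test_whole_population_has_no_threshold(self, solved):
        d = solved.design(["item2", "item3"], 1.0)
        assert math.isinf(compute_c_star(d))

    def test_curve_equals_threshold_at_interval_endpoints(self, solved):
        # all four finite endpoints of the two-interval optimum lie on the
        # same reference level c*
        d = solved.design(["item1"], 0.1)
        c = compute_c_star(d)
        for iv in d.intervals_by_item[0]:
            for b in (iv.lo, iv.hi):
                assert directional_derivative(d, b, 0) == pytest.approx(c, abs=5e-3)

    def test_sublevel_mass_matches_proportion(self, solved):
        d = solved.design(["item1"], 0.1)
        c = compute_c_star(d)
        theta = np.linspace(*d.g.support, 20001)
        env = min_dirderiv(d, theta)
        mids = 0.5 * (theta[:-1] + theta[1:])
        w = np.diff(np.concatenate(([0.0], np.asarray(d.g.cdf(mids)), [1.0])))
        assert float(w[env <= c].sum()) == pytest.approx(d.s, abs=2e-3)

    def test_threshold_nondecreasing_in_proportion(self, solved):
        d = solved.design(["item1"], 0.1)
        theta = np.linspace(*d.g.support, 4001)
        env = np.atleast_1d(min_dirderiv(d, theta))
        mids = 0.5 * (theta[:-1] + theta[1:])
        w = np.diff(np.concatenate(([0.0], np.asarray(d.g.cdf(mids)), [1.0])))
        cs = [_c_star_from_envelope(env, w, s) for s in np.arange(0.1, 0.91, 0.1)]
        assert np.all(np.diff(cs) >= -1e-12)


class TestVerifier:
    def test_optimum_passes(self, solved):
        report = solved.design(["item1"], 0.1).report
        assert report.passed
        assert report.max_violation <= report.tolerance

    def test_ability_blind_allocation_fails(self, g):
        # sampling one central band of mass s ignores where the item is
        # informative and cannot satisfy the threshold structure
        lo, hi = g.quantile(0.45), g.quantile(0.55)
        naive = CalibrationDesign([ITEM1], [[Interval(lo, hi)]], 0.1, g)
        report = check_optimality(naive)
        assert not report.passed
        assert report.max_violation > 0.1

    def test_perturbed_optimum_fails(self, solved, g):
        d = solved.design(["item1"], 0.1)
        iv1, iv2 = d.intervals_by_item[0]
        # shift the upper interval inward by 0.1 and rebalance its mass
        lo2 = iv2.lo - 0.1
        from scipy.optimize import brentq

        hi2 = brentq(lambda t: g.mass(lo2, t) - g.mass(iv2.lo, iv2.hi), lo2 + 1e-6, 9.0)
        perturbed = CalibrationDesign([ITEM1], [[iv1, Interval(lo2, hi2)]], d.s, g)
        report = check_optimality(perturbed)
        assert not report.passed

    def test_report_format(self, solved):
        report = solved.design(["item1"], 0.1).report
        text = str(report)
        assert "optimal" in text and "c*" in text
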