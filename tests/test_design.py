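import math
import warnings

import numpy as np
import pytest
from scipy.optimize import brentq

from _oracle import midpoint_information
from irtcalib import (
    CalibrationDesign,
    Interval,
    Item,
    PointDesign,
    SymmetricOverlap,
    d_optimal_offset,
    glm_weight,
    information_interval_design,
    information_point_design,
    log_det_criterion,
    random_design,
    symmetric_design,
    unrestricted_d_optimal,
)

ITEM1 = Item(1.0, 0.5, "item1")
ITEM2 = Item(1.5, -1.2, "item2")
ITEM3 = Item(1.6, 2.0, "item3")


class TestPointInformation:
    def test_single_point_is_singular(self):
        M = information_point_design(ITEM1, [0.3], [0.7])
        assert np.linalg.det(M) == pytest.approx(0.0, abs=1e-15)

    def test_symmetric_design_has_zero_offdiagonal(self):
        M = information_point_design(Item(1.0, 0.0), [-1.543, 1.543], [0.5, 0.5])
        assert M[0, 1] == pytest.approx(0.0, abs=1e-15)

    def test_determinant_by_direct_arithmetic(self):
        # det = (nu * c^2 / ... ) for the symmetric two-point design: the
        # matrix is diag(nu c^2, nu a^2) with nu evaluated at +-c
        c = 1.543
        nu = glm_weight(Item(1.0, 0.0), c)
        M = information_point_design(Item(1.0, 0.0), [-c, c], [0.5, 0.5])
        assert np.linalg.det(M) == pytest.approx(nu * c**2 * nu, rel=1e-12)
        assert np.linalg.det(M) == pytest.approx(0.05008, abs=5e-5)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            information_point_design(ITEM1, [0.0, 1.0], [0.5, -0.1])


class TestIntervalInformation:
    def test_offdiagonal_vanishes_for_symmetric_intervals(self, g):
        s = g.mass(-2.0, -1.0) + g.mass(1.0, 2.0)
        d = CalibrationDesign(
            [Item(1.3, 0.0)], [[Interval(-2.0, -1.0), Interval(1.0, 2.0)]], s=s, g=g
        )
        M = information_interval_design(d, 0)
        assert M[0, 1] == pytest.approx(0.0, abs=1e-8)

    def test_against_midpoint_oracle_randomized(self, g):
        rng = np.random.default_rng(7)
        for _ in range(20):
            pts = np.sort(rng.uniform(-3.5, 3.5, 4))
            bounds = [(pts[0], pts[1]), (pts[2], pts[3])]
            s = sum(g.mass(a, b) for a, b in bounds)
            if s < 1e-3:
                continue
            d = CalibrationDesign([ITEM1], [[Interval(*b) for b in bounds]], s, g)
            M = information_interval_design(d, 0)
            M_ref = midpoint_information(ITEM1, bounds, s)
            assert np.max(np.abs(M - M_ref)) < 1e-6

    def test_shrinking_intervals_converge_to_point_design(self, g):
        # intervals of width -> 0 around the unrestricted points with mass
        # s/2 each approach the two-point information matrix
        pd = unrestricted_d_optimal(ITEM1)
        pts = pd.points_by_item[0]
        s = 1e-4
        halves = [
            brentq(lambda d_, p=p: g.mass(p - d_, p + d_) - s / 2, 1e-9, 1.0) for p in pts
        ]
        d = CalibrationDesign(
            [ITEM1],
            [[Interval(p - h, p + h) for p, h in zip(pts, halves)]],
            s,
            g,
        )
        M = information_interval_design(d, 0)
        M_pt = information_point_design(ITEM1, pts, [0.5, 0.5])
        assert np.max(np.abs(M - M_pt)) < 1e-4

    def test_empty_interval_list_gives_zero_matrix(self, g):
        d = CalibrationDesign([ITEM1, ITEM2], [[Interval(-1, 1)], []], g.mass(-1, 1), g)
        assert np.all(information_interval_design(d, 1) == 0.0)


class TestUnrestrictedOptimum:
    @pytest.mark.parametrize(
        "item, expected",
        [
            (ITEM1, (-1.043, 2.043)),
            (ITEM2, (-2.229, -0.171)),
            (ITEM3, (1.035, 2.965)),
        ],
    )
    def test_reference_design_points(self, item, expected):
        pd = unrestricted_d_optimal(item)
        np.testing.assert_allclose(pd.points_by_item[0], expected, atol=1e-3)

    def test_offset_invariance_in_item_parameters(self):
        c = d_optimal_offset()
        for item in (ITEM1, ITEM2, ITEM3):
            pd = unrestricted_d_optimal(item)
            offset = (pd.points_by_item[0][1] - item.b) * item.a
            assert abs(offset - 1.543) <= 1e-3
            assert offset == pytest.approx(c, rel=1e-12)

    def test_beats_random_two_point_designs(self):
        pd = unrestricted_d_optimal(ITEM2)
        best = np.linalg.det(pd.information_matrix(0))
        rng = np.random.default_rng(11)
        for _ in range(1000):
            pts = np.sort(rng.uniform(-6, 6, 2))
            if pts[1] - pts[0] < 1e-9:
                continue
            M = information_point_design(ITEM2, pts, [0.5, 0.5])
            assert np.linalg.det(M) <= best + 1e-12


class TestRandomDesign:
    def test_single_item_equals_full_population_information(self, g):
        whole = CalibrationDesign([ITEM1], [[Interval(-math.inf, math.inf)]], 1.0, g)
        M_full = information_interval_design(whole, 0)
        for s in (0.1, 0.5, 1.0):
            (M,) = random_design([ITEM1], s, g)
            assert np.max(np.abs(M - M_full)) < 1e-10

    def test_identical_items_get_identical_blocks(self, g):
        Ms = random_design([ITEM2, Item(1.5, -1.2, "copy")], 0.4, g)
        assert np.max(np.abs(Ms[0] - Ms[1])) == 0.0

    def test_blocks_scale_inversely_with_item_count(self, g):
        (M1,) = random_design([ITEM1], 0.3, g)
        M2 = random_design([ITEM1, ITEM2], 0.3, g)[0]
        assert np.max(np.abs(M1 / 2 - M2)) < 1e-12


class TestSymmetricDesign:
    def test_overlap_failure_for_hard_item(self, g):
        res = symmetric_design([ITEM3], 0.35, g)
        assert isinstance(res, SymmetricOverlap)
        assert not res
        assert "overlaps" in str(res)

    def test_valid_at_smaller_proportion(self, g):
        res = symmetric_design([ITEM3], 0.2, g)
        assert isinstance(res, CalibrationDesign)
        res.validate()

    def test_halfwidths_match_bisection_oracle(self, g):
        res = symmetric_design([ITEM1], 0.1, g)
        pts = unrestricted_d_optimal(ITEM1).points_by_item[0]
        for iv, p in zip(res.intervals_by_item[0], pts):
            assert g.mass(iv.lo, iv.hi) == pytest.approx(0.05, abs=1e-9)
            d_ref = brentq(lambda d: g.mass(p - d, p + d) - 0.05, 1e-9, 5.0, xtol=1e-12)
            assert iv.hi - iv.lo == pytest.approx(2 * d_ref, abs=1e-6)
            assert 0.5 * (iv.lo + iv.hi) == pytest.approx(p, abs=1e-9)


class TestCriterion:
    def test_log_det_identity(self, g, solved):
        d = solved.design(["item1"], 0.1)
        dets = [np.linalg.det(M) for M in d.information_matrices()]
        assert log_det_criterion(d) == pytest.approx(-math.log(np.prod(dets)), abs=1e-10)

    def test_restricted_det_below_unrestricted_maximum(self, g, solved):
        d = solved.design(["item1"], 0.1)
        det_restricted = np.linalg.det(d.information_matrix(0))
        det_unrestricted = np.linalg.det(unrestricted_d_optimal(ITEM1).information_matrix(0))
        assert det_restricted < det_unrestricted

    def test_singular_block_yields_infinity_with_warning(self, g):
        d = CalibrationDesign([ITEM1, ITEM2], [[Interval(-1, 1)], []], g.mass(-1, 1), g)
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            assert log_det_criterion(d) == math.inf
        assert any("item2" in str(w.message) for w in rec)


class TestDesignValidation:
    def test_overlapping_intervals_rejected(self, g):
        d = CalibrationDesign(
            [ITEM1, ITEM2], [[Interval(-1, 0.5)], [Interval(0.0, 1.0)]], 0.5, g
        )
        with pytest.raises(ValueError, match="overlap"):
            d.validate()

    def test_mass_mismatch_rejected(self, g):
        d = CalibrationDesign([ITEM1], [[Interval(-1, 1)]], 0.9, g)
        with pytest.raises(ValueError, match="mass"):
            d.validate()

    def test_point_design_weights_must_total_one(self):
        with pytest.raises(ValueError, match="total weight"):
            PointDesign([ITEM1], [np.array([-1.0, 1.0])], [np.array([0.5, 0.2])])
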