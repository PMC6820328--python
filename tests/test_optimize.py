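import math
import warnings

import numpy as np
import pytest

from irtcalib import (
    CalibrationDesign,
    Item,
    PointDesign,
    SolverConfig,
    enumerate_orderings,
    optimize_multi_item,
    optimize_one_item,
    tail_anchored_optimize,
    unrestricted_d_optimal,
)
from irtcalib.optimize import _pad_solution, _solve_ordering


class TestOrderings:
    @pytest.mark.parametrize("n, K, count", [(2, 2, 6), (2, 1, 2), (2, 3, 20), (3, 2, 90)])
    def test_counts(self, n, K, count):
        orderings = enumerate_orderings(n, K)
        assert len(orderings) == count
        assert len(set(orderings)) == count

    def test_each_item_appears_K_times(self):
        for seq in enumerate_orderings(3, 2):
            assert len(seq) == 6
            assert all(seq.count(i) == 2 for i in range(3))

    def test_cap_respected(self):
        assert len(enumerate_orderings(3, 3, cap=50)) == 50


class TestOneItem:
    def test_item1_reference_intervals(self, solved):
        d = solved.design(["item1"], 0.1)
        (iv1, iv2) = d.intervals_by_item[0]
        assert iv1.lo == pytest.approx(-1.215, abs=0.02)
        assert iv1.hi == pytest.approx(-0.984, abs=0.02)
        assert iv2.lo == pytest.approx(1.600, abs=0.02)
        assert iv2.hi == pytest.approx(2.577, abs=0.02)
        masses = 100 * d.masses_by_item()[0]
        np.testing.assert_allclose(masses, [5.0, 5.0], atol=0.15)

    def test_item2_reference_masses(self, solved):
        d = solved.design(["item2"], 0.25)
        masses = 100 * d.masses_by_item()[0]
        np.testing.assert_allclose(masses, [11.48, 13.52], atol=0.15)
        assert d.intervals_by_item[0][1].lo == pytest.approx(-0.061, abs=0.02)
        assert d.intervals_by_item[0][1].hi == pytest.approx(0.282, abs=0.02)

    def test_symmetric_problem_gives_mirrored_intervals(self, g):
        d = optimize_one_item(Item(1.2, 0.0), 0.3, g)
        (iv1, iv2) = d.intervals_by_item[0]
        assert iv1.lo == pytest.approx(-iv2.hi, abs=1e-3)
        assert iv1.hi == pytest.approx(-iv2.lo, abs=1e-3)

    def test_s_zero_returns_unrestricted_point_design(self, g):
        d = optimize_one_item(Item(1.0, 0.5), 0.0, g)
        assert isinstance(d, PointDesign)
        ref = unrestricted_d_optimal(Item(1.0, 0.5))
        np.testing.assert_allclose(d.points_by_item[0], ref.points_by_item[0])

    def test_mass_constraint_and_verification(self, solved):
        for s in (0.1, 0.25, 0.35):
            d = solved.design(["item3"], s) if s == 0.35 else solved.design(["item1"], s)
            assert d.total_mass() == pytest.approx(d.s, abs=1e-6)
            assert d.report.passed


class TestMultiItem:
    def test_non_competing_items(self, solved):
        d = solved.design(["item1", "item2"], 0.1)
        m1 = 100 * d.masses_by_item()[0]
        m2 = 100 * d.masses_by_item()[1]
        np.testing.assert_allclose(m1, [2.52, 2.51], atol=0.15)
        np.testing.assert_allclose(m2, [2.47, 2.50], atol=0.15)
        iv = d.intervals_by_item[0][0]
        assert iv.lo == pytest.approx(-1.114, abs=0.02)
        assert iv.hi == pytest.approx(-1.004, abs=0.02)

    def test_competing_items_share_boundary(self, solved):
        d = solved.design(["item1", "item3"], 0.5)
        hi_item1 = d.intervals_by_item[0][-1].hi
        lo_item3 = d.intervals_by_item[1][-1].lo
        assert hi_item1 == pytest.approx(1.511, abs=0.02)
        assert hi_item1 == pytest.approx(lo_item3, abs=1e-6)

    def test_escalation_reaches_three_intervals(self, solved):
        d = solved.design(["item2", "item3"], 0.8)
        assert d.K == 3
        assert all(len(ivs) == 3 for ivs in d.intervals_by_item)
        assert d.report.passed

    def test_criterion_not_worse_with_extra_interval_slot(self, g):
        # a K-interval optimum embeds into any compatible K+1 ordering, so
        # re-solving with the padded start can never do worse
        items = [Item(1.0, 0.5, "item1"), Item(1.6, 2.0, "item3")]
        cfg = SolverConfig()
        rng = np.random.default_rng(0)
        best2 = math.inf
        best = None
        for seq in enumerate_orderings(2, 2):
            val, u = _solve_ordering(items, seq, 0.5, g, cfg, rng)
            if val < best2:
                best2, best = val, (seq, u)
        seq3 = tuple(np.insert(np.array(best[0]), 0, [0, 1]))  # prepend one slot of each
        padded = _pad_solution(best[0], best[1], seq3)
        assert padded is not None
        val3, _ = _solve_ordering(items, seq3, 0.5, g, cfg, rng, extra_starts=[padded])
        assert val3 <= best2 + 1e-6

    def test_multi_item_rejects_single_item(self, g):
        with pytest.raises(ValueError, match="n >= 2"):
            optimize_multi_item([Item(1.0, 0.0)], 0.5, g)


class TestWholePopulation:
    def test_two_items_reference_masses(self, solved):
        d = solved.design(["item2", "item3"], 1.0)
        m2 = 100 * d.masses_by_item()[0]
        m3 = 100 * d.masses_by_item()[1]
        np.testing.assert_allclose(m2, [30.98, 23.28], atol=0.25)
        np.testing.assert_allclose(m3, [22.27, 23.47], atol=0.25)
        # unbounded tails belong to the item with the smaller discrimination
        assert d.intervals_by_item[0][0].lo == -math.inf

    def test_single_item_gets_everyone(self, g):
        d = tail_anchored_optimize([Item(1.0, 0.5, "item1")], g)
        assert d.total_mass() == pytest.approx(1.0, abs=1e-9)
        assert len(d.intervals_by_item[0]) == 1

    def test_discrimination_tie_warns(self, g):
        items = [Item(1.0, -0.5, "lo1"), Item(1.0, 0.5, "lo2")]
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            tail_anchored_optimize(items, g)
        assert any("tie" in str(w.message) for w in rec)

    def test_total_mass_is_one(self, solved):
        d = solved.design(["item2", "item3"], 1.0)
        assert d.total_mass() == pytest.approx(1.0, abs=1e-6)
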