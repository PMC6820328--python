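"""Relative D-efficiency, sample-size gain and blocked scale-up.

The relative D-efficiency of design 1 versus design 2 over the same n items
is the 2n-th root of the ratio of the products of the per-item information
determinants.  A value below 1 means design 2 is better; design 1 then needs
approximately (1/RE - 1)*100 % more examinees for the same precision.

For a large bank of new items split into blocks (each examinee calibrates
one item per block), the overall efficiency of a benchmark versus the
blocked optimal design is the geometric mean of the per-block efficiencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .design import CalibrationDesign, random_design
from .model import AbilityDensity, Item

__all__ = [
    "EfficiencyResult",
    "relative_efficiency",
    "sample_size_gain",
    "blocked_efficiency",
    "allitems_design_comparison",
]


@dataclass
class EfficiencyResult:
    """Relative D-efficiency and its sample-size interpretation."""

    re_d: float
    re_ss_percent: float
    n_items: int
    block_res: list[float] | None = None

    def __str__(self) -> str:
        return f"RE_D = {self.re_d:.4f} (needs {self.re_ss_percent:.2f}% more examinees)"


def _block_determinants(design, n_expected: int | None = None) -> list[float]:
    """Per-item determinants from a CalibrationDesign or a matrix list."""
    if isinstance(design, CalibrationDesign):
        mats = design.information_matrices()
    else:
        mats = [np.asarray(M, dtype=float) for M in design]
    dets = [float(M[0, 0] * M[1, 1] - M[0, 1] ** 2) for M in mats]
    if any(d <= 0 for d in dets):
        bad = [i for i, d in enumerate(dets) if d <= 0]
        raise ValueError(f"singular information block(s) at index {bad}")
    if n_expected is not None and len(dets) != n_expected:
        raise ValueError("designs must cover the same item list")
    return dets


def relative_efficiency(design1, design2) -> EfficiencyResult:
    """RE_D(design1, design2) = [prod det M_i^(1) / prod det M_i^(2)]^(1/2n).

    Both arguments may be :class:`CalibrationDesign` objects or lists of 2x2
    information matrices over the same items, in the same order.
    """
    if (
        isinstance(design1, CalibrationDesign)
        and isinstance(design2, CalibrationDesign)
        and [
            (it.a, it.b) for it in design1.items
        ]
        != [(it.a, it.b) for it in design2.items]
    ):
        raise ValueError("designs must be built for the same item list")
    d1 = _block_determinants(design1)
    d2 = _block_determinants(design2, n_expected=len(d1))
    n = len(d1)
    log_re = (sum(map(math.log, d1)) - sum(map(math.log, d2))) / (2 * n)
    re_d = math.exp(log_re)
    return EfficiencyResult(re_d=re_d, re_ss_percent=sample_size_gain(re_d), n_items=n)


def sample_size_gain(re_d: float) -> float:
    """Extra sample size (percent) implied by a relative efficiency."""
    if not re_d > 0:
        raise ValueError(f"relative efficiency must be positive, got {re_d}")
    return (1.0 / re_d - 1.0) * 100.0


def blocked_efficiency(block_re_list: Sequence[float]) -> float:
    """Geometric mean of per-block relative efficiencies."""
    vals = list(block_re_list)
    if not vals:
        raise ValueError("need at least one block efficiency")
    if any(v <= 0 for v in vals):
        raise ValueError("block efficiencies must be positive")
    return float(np.exp(np.mean(np.log(vals))))


def allitems_design_comparison(
    items: Sequence[Item],
    g: AbilityDensity,
    optimal: CalibrationDesign | None = None,
    config=None,
) -> float:
    """Information ratio of giving every item to every examinee versus the
    restricted optimum at s = 1.

    Administering all n items to everyone yields n times the information of
    the ability-blind random allocation, so the ratio equals
    n * RE_D(random, optimal) = n / (1 + RE_SS/100).
    """
    items = list(items)
    n = len(items)
    if optimal is None:
        if n == 1:
            from .optimize import tail_anchored_optimize

            optimal = tail_anchored_optimize(items, g, config)
        else:
            from .optimize import optimize_multi_item

            optimal = optimize_multi_item(items, 1.0, g, config)
    rnd = random_design(items, 1.0, g)
    re = relative_efficiency(rnd, optimal)
    return n * re.re_d
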