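"""High-level modelling surface: a calibration problem and its fitted results.

This mirrors the familiar statsmodels shape: an :class:`ItemCalibration`
object collects the inputs (items, population density, sampling proportion,
solver configuration); ``fit()`` runs the restricted D-optimal interval
optimization and returns a :class:`CalibrationResults` carrying the design,
its equivalence-theorem report, efficiency comparisons, a ``summary()``
table and a directional-derivative plot.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .design import (
    CalibrationDesign,
    SymmetricOverlap,
    log_det_criterion,
    random_design,
    symmetric_design,
    unrestricted_d_optimal,
)
from .efficiency import EfficiencyResult, relative_efficiency
from .equivalence import OptimalityReport
from .model import AbilityDensity, Item
from .optimize import SolverConfig, optimize_multi_item, optimize_one_item

__all__ = ["ItemCalibration", "CalibrationResults"]


class ItemCalibration:
    """Restricted D-optimal calibration design problem.

    Parameters
    ----------
    items : sequence of Item (or (a, b) / (a, b, label) tuples)
    s : sampling proportion of the examinee population, in (0, 1].
    population : AbilityDensity, standard normal when omitted.
    config : SolverConfig, defaults when omitted.
    """

    def __init__(
        self,
        items: Sequence[Item | tuple],
        s: float = 0.1,
        population: AbilityDensity | None = None,
        config: SolverConfig | None = None,
    ) -> None:
        self.items = [it if isinstance(it, Item) else Item(*it) for it in items]
        if not self.items:
            raise ValueError("need at least one item")
        self.s = float(s)
        self.population = population or AbilityDensity.standard_normal()
        self.config = config or SolverConfig()

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        s: float = 0.1,
        population: AbilityDensity | None = None,
        config: SolverConfig | None = None,
    ) -> "ItemCalibration":
        """Build from a DataFrame with columns ``a``, ``b`` and optional ``label``."""
        items = [
            Item(float(r["a"]), float(r["b"]), str(r.get("label", f"item{k + 1}")))
            for k, (_, r) in enumerate(frame.iterrows())
        ]
        return cls(items, s=s, population=population, config=config)

    def fit(self) -> "CalibrationResults":
        if len(self.items) == 1:
            design = optimize_one_item(self.items[0], self.s, self.population, self.config)
        else:
            design = optimize_multi_item(self.items, self.s, self.population, self.config)
        return CalibrationResults(self, design)


class CalibrationResults:
    """Fitted restricted design with diagnostics and comparisons."""

    def __init__(self, problem: ItemCalibration, design: CalibrationDesign) -> None:
        self.problem = problem
        self.design = design
        self.report: OptimalityReport = design.report
        self.K = design.K
        self.criterion = (
            design.criterion
            if design.criterion is not None
            else log_det_criterion(design)
        )

    # ------------------------------------------------------------------
    def intervals_frame(self) -> pd.DataFrame:
        """Tidy table of the sampling intervals, one row per interval."""
        rows = []
        for i, (item, ivs) in enumerate(
            zip(self.design.items, self.design.intervals_by_item)
        ):
            for j, iv in enumerate(ivs):
                rows.append(
                    {
                        "item": item.label or f"item{i + 1}",
                        "interval": j + 1,
                        "lo": iv.lo,
                        "hi": iv.hi,
                        "mass_percent": 100.0 * self.design.g.mass(iv.lo, iv.hi),
                    }
                )
        return pd.DataFrame(rows, columns=["item", "interval", "lo", "hi", "mass_percent"])

    def efficiency_vs_random(self) -> EfficiencyResult:
        rnd = random_design(self.design.items, self.design.s, self.design.g)
        return relative_efficiency(rnd, self.design)

    def efficiency_vs_symmetric(self) -> EfficiencyResult | SymmetricOverlap:
        sym = symmetric_design(self.design.items, self.design.s, self.design.g)
        if isinstance(sym, SymmetricOverlap):
            return sym
        return relative_efficiency(sym, self.design)

    # ------------------------------------------------------------------
    def summary(self) -> str:
        d = self.design
        lines = []
        lines.append("Restricted locally D-optimal calibration design")
        lines.append("=" * 64)
        lines.append(f"population: {d.g.name or 'custom density'}   s = {d.s:g}")
        items_txt = ", ".join(
            f"{it.label or f'item{i + 1}'}(a={it.a:g}, b={it.b:g})"
            for i, it in enumerate(d.items)
        )
        lines.append(f"items: {items_txt}")
        if self.K is not None:
            lines.append(f"intervals per item (K): {self.K}")
        lines.append(f"criterion -sum log det M_i: {self.criterion:.6f}")
        if self.report is not None:
            lines.append(str(self.report))
        lines.append("-" * 64)
        frame = self.intervals_frame()
        with pd.option_context("display.float_format", lambda v: f"{v:.3f}"):
            lines.append(frame.to_string(index=False))
        lines.append("-" * 64)
        eff_r = self.efficiency_vs_random()
        lines.append(f"random benchmark:    {eff_r}")
        eff_s = self.efficiency_vs_symmetric()
        if isinstance(eff_s, SymmetricOverlap):
            lines.append(f"symmetric benchmark: {eff_s}")
        else:
            lines.append(f"symmetric benchmark: {eff_s}")
        return "\n".join(lines)

    # ------------------------------------------------------------------
    def plot_directional_derivatives(self, ax=None, theta_range: tuple[float, float] | None = None):
        """Directional-derivative curves with the c* line and shaded sampling
        regions; the visual form of the equivalence-theorem check."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        rep = self.report
        grid, F = rep.theta_grid, rep.dirderiv
        if theta_range is None:
            theta_range = (-4.0, 4.0)
        sel = (grid >= theta_range[0]) & (grid <= theta_range[1])
        for i, item in enumerate(self.design.items):
            ax.plot(grid[sel], F[sel, i], label=item.label or f"item{i + 1}")
        if math.isfinite(rep.c_star):
            ax.axhline(rep.c_star, color="tab:blue", ls="--", lw=1, label="c*")
        for i, ivs in enumerate(self.design.intervals_by_item):
            for iv in ivs:
                lo = max(iv.lo, theta_range[0])
                hi = min(iv.hi, theta_range[1])
                if hi > lo:
                    ax.axvspan(lo, hi, alpha=0.15, color=f"C{i}")
        ax.set_xlabel(r"ability $\theta$")
        ax.set_ylabel(r"$F_D(h, \theta, i)$")
        ax.legend(loc="best", fontsize=8)
        return ax
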