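"""Design representations and their standardized information matrices.

Two families of designs appear in item calibration:

* *Point designs* place probability mass on finitely many abilities; the
  unrestricted locally D-optimal design for a single 2PL item is the
  classical two-point design at ``b +- c/a`` with equal weights, where the
  standardized offset ``c`` (about 1.543) is recomputed numerically once and
  cached.

* *Interval (restricted) designs* sample every available examinee whose
  ability falls into item-specific intervals; the sub-density assigned to
  item ``i`` is ``g`` restricted to its intervals, and the standardized
  information matrix divides by the total sampling proportion ``s``.

Benchmark designs (random and symmetric) used in efficiency comparisons are
also built here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .model import AbilityDensity, Item, glm_weight

__all__ = [
    "Interval",
    "PointDesign",
    "CalibrationDesign",
    "SymmetricOverlap",
    "information_point_design",
    "information_interval_design",
    "interval_information",
    "unrestricted_d_optimal",
    "d_optimal_offset",
    "random_design",
    "symmetric_design",
    "log_det_criterion",
]


@dataclass(frozen=True)
class Interval:
    """Closed ability interval; endpoints may be infinite."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.hi < self.lo:
            raise ValueError(f"interval endpoints out of order: ({self.lo}, {self.hi})")

    @property
    def width(self) -> float:
        return self.hi - self.lo

    def contains(self, theta: float) -> bool:
        return self.lo <= theta <= self.hi

    def __str__(self) -> str:
        fmt = lambda x: "-inf" if x == -math.inf else ("inf" if x == math.inf else f"{x:.3f}")
        return f"({fmt(self.lo)}, {fmt(self.hi)})"


@dataclass
class PointDesign:
    """Finite-support design: per-item ability points with sampling weights."""

    items: list[Item]
    points_by_item: list[np.ndarray]
    weights_by_item: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.items) != len(self.points_by_item) or len(self.items) != len(self.weights_by_item):
            raise ValueError("items, points and weights must have equal lengths")
        self.points_by_item = [np.asarray(p, dtype=float) for p in self.points_by_item]
        self.weights_by_item = [np.asarray(w, dtype=float) for w in self.weights_by_item]
        for pts, w in zip(self.points_by_item, self.weights_by_item):
            if np.any(w < 0):
                raise ValueError("point-design weights must be non-negative")
            if np.any(np.diff(pts) <= 0):
                raise ValueError("points within an item must be strictly increasing")
        total = sum(float(np.sum(w)) for w in self.weights_by_item)
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"total weight across items must be 1, got {total}")

    def information_matrix(self, item_index: int) -> np.ndarray:
        return information_point_design(
            self.items[item_index],
            self.points_by_item[item_index],
            self.weights_by_item[item_index],
        )


@dataclass
class CalibrationDesign:
    """Restricted interval design: per-item disjoint intervals plus proportion s.

    The sub-density of item ``i`` equals ``g`` on its intervals and 0
    elsewhere; intervals are pairwise disjoint across *all* items, and the
    total mass equals ``s``.
    """

    items: list[Item]
    intervals_by_item: list[list[Interval]]
    s: float
    g: AbilityDensity
    # optimizer metadata, filled by the optimize module
    K: int | None = None
    criterion: float | None = None
    report: object | None = None
    converged: bool = True

    def validate(self, tol: float = 1e-6) -> None:
        if not 0 < self.s <= 1:
            raise ValueError(f"sampling proportion s must be in (0, 1], got {self.s}")
        if len(self.items) != len(self.intervals_by_item):
            raise ValueError("one interval list required per item")
        flat = [
            (iv.lo, iv.hi, i)
            for i, ivs in enumerate(self.intervals_by_item)
            for iv in ivs
        ]
        flat.sort()
        for (lo1, hi1, i1), (lo2, hi2, i2) in zip(flat, flat[1:]):
            if lo2 < hi1 - 1e-9:
                raise ValueError(
                    f"intervals overlap: item {self.items[i1].label or i1} ({lo1:.4f}, {hi1:.4f}) "
                    f"and item {self.items[i2].label or i2} ({lo2:.4f}, {hi2:.4f})"
                )
        total = self.total_mass()
        if abs(total - self.s) > tol:
            raise ValueError(f"design mass {total:.8f} differs from s={self.s}")

    def masses_by_item(self) -> list[np.ndarray]:
        return [
            np.array([self.g.mass(iv.lo, iv.hi) for iv in ivs])
            for ivs in self.intervals_by_item
        ]

    def total_mass(self) -> float:
        return float(sum(m.sum() for m in self.masses_by_item()))

    def information_matrix(self, item_index: int, nodes: int = 201) -> np.ndarray:
        return information_interval_design(self, item_index, nodes=nodes)

    def information_matrices(self, nodes: int = 201) -> list[np.ndarray]:
        return [self.information_matrix(i, nodes=nodes) for i in range(len(self.items))]


@dataclass
class SymmetricOverlap:
    """Structured failure value: the symmetric benchmark is undefined because
    intervals around two unrestricted design points intersect."""

    colliding: list[tuple[str, Interval, str, Interval]]

    def __bool__(self) -> bool:  # a failure is falsy as a design
        return False

    def __str__(self) -> str:
        parts = [
            f"{l1} {iv1} overlaps {l2} {iv2}" for l1, iv1, l2, iv2 in self.colliding
        ]
        return "symmetric design undefined: " + "; ".join(parts)


# ---------------------------------------------------------------------------
# information matrices


@lru_cache(maxsize=8)
def _gl(nodes: int) -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.legendre.leggauss(nodes)
    return x, w


def information_point_design(item: Item, points, weights) -> np.ndarray:
    """Standardized information of a finite design for one 2PL item.

    M = sum_j w_j nu(theta_j) u(theta_j) u(theta_j)^T with u = (theta-b, -a).
    Weights are the proportions allotted to this item; they need not sum to 1.
    """
    pts = np.asarray(points, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    nu = glm_weight(item, pts)
    c = w * nu
    d = pts - item.b
    m11 = float(np.sum(c * d * d))
    m12 = float(np.sum(-item.a * c * d))
    m22 = float(np.sum(c)) * item.a**2
    return np.array([[m11, m12], [m12, m22]])


def interval_information(
    item: Item,
    bounds: Sequence[tuple[float, float]],
    g: AbilityDensity,
    s: float,
    nodes: int = 201,
) -> np.ndarray:
    """Information matrix of ``g`` restricted to ``bounds`` for one item.

    M = (1/s) * sum over intervals of int nu(theta) u u^T g(theta) dtheta,
    by fixed-order Gauss-Legendre quadrature per interval.  Intervals are
    clipped to the truncated support; empty intervals contribute zero.
    """
    x, wq = _gl(nodes)
    lo_s, hi_s = g.support
    M = np.zeros((2, 2))
    for lo, hi in bounds:
        lo = max(float(lo), lo_s)
        hi = min(float(hi), hi_s)
        if not hi > lo:
            continue
        mid = 0.5 * (lo + hi)
        half = 0.5 * (hi - lo)
        t = mid + half * x
        c = wq * glm_weight(item, t) * g.pdf(t) * (half / s)
        d = t - item.b
        M[0, 0] += float(np.sum(c * d * d))
        M[0, 1] += float(np.sum(-item.a * c * d))
        M[1, 1] += float(np.sum(c)) * item.a**2
    M[1, 0] = M[0, 1]
    return M


def information_interval_design(
    design: CalibrationDesign, item_index: int, nodes: int = 201
) -> np.ndarray:
    """Standardized information matrix of one item in a restricted design.

    Normalization divides by the *total* sampling proportion ``s``, not the
    item's own mass.  An item with no intervals gets the zero matrix.
    """
    ivs = design.intervals_by_item[item_index]
    bounds = [(iv.lo, iv.hi) for iv in ivs]
    return interval_information(design.items[item_index], bounds, design.g, design.s, nodes=nodes)


# ---------------------------------------------------------------------------
# reference designs


@lru_cache(maxsize=1)
def d_optimal_offset() -> float:
    """Standardized offset c of the unrestricted two-point D-optimal design.

    For a symmetric equally weighted two-point design at ``b +- c/a`` the
    determinant of the 2PL information matrix is ``(nu(c) * c)**2 * a**2`` in
    standardized units, so the optimal c maximizes ``nu(c) * c``.  The value
    (~1.543) is invariant in (a, b) and computed once at a=1, b=0.
    """
    ref = Item(a=1.0, b=0.0)
    res = minimize_scalar(
        lambda c: -glm_weight(ref, c) * c,
        bounds=(0.1, 5.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def unrestricted_d_optimal(item: Item) -> PointDesign:
    """Two-point locally D-optimal design b +- c/a with weights 1/2 each."""
    c = d_optimal_offset()
    pts = np.array([item.b - c / item.a, item.b + c / item.a])
    return PointDesign([item], [pts], [np.array([0.5, 0.5])])


def random_design(
    items: Sequence[Item], s: float, g: AbilityDensity, nodes: int = 201, panels: int = 8
) -> list[np.ndarray]:
    """Information matrices of the ability-blind benchmark h_i = s*g/n.

    The standardization by s cancels: M_i = (1/n) * int nu u u^T g dtheta over
    the whole support, identical for items with identical parameters.  The
    support is split into panels to keep fixed-order quadrature accurate over
    the long integration range.
    """
    n = len(items)
    if n < 1:
        raise ValueError("need at least one item")
    lo, hi = g.support
    edges = np.linspace(lo, hi, panels + 1)
    bounds = list(zip(edges[:-1], edges[1:]))
    return [interval_information(item, bounds, g, s=float(n), nodes=nodes) for item in items]


def symmetric_design(
    items: Sequence[Item], s: float, g: AbilityDensity
) -> CalibrationDesign | SymmetricOverlap:
    """Benchmark sampling s/m around each of the m = 2n unrestricted points.

    For each unrestricted point ``theta*`` a half-width d solves
    ``g-mass(theta* - d, theta* + d) = s/m``.  If any two of the resulting
    intervals intersect, the design is undefined and a structured
    :class:`SymmetricOverlap` is returned instead of a design.
    """
    if not 0 < s <= 1:
        raise ValueError(f"s must be in (0, 1], got {s}")
    m = 2 * len(items)
    target = s / m
    labeled: list[tuple[str, Interval, int]] = []
    per_item: list[list[Interval]] = []
    for i, item in enumerate(items):
        pd = unrestricted_d_optimal(item)
        ivs = []
        for theta_star in pd.points_by_item[0]:
            f = lambda d: g.mass(theta_star - d, theta_star + d) - target
            d = brentq(f, 1e-12, 60.0, xtol=1e-12)
            iv = Interval(theta_star - d, theta_star + d)
            ivs.append(iv)
            labeled.append((items[i].label or f"item{i + 1}", iv, i))
        per_item.append(ivs)
    labeled.sort(key=lambda t: t[1].lo)
    colliding = []
    for (l1, iv1, _), (l2, iv2, _) in zip(labeled, labeled[1:]):
        if iv2.lo < iv1.hi - 1e-12:
            colliding.append((l1, iv1, l2, iv2))
    if colliding:
        return SymmetricOverlap(colliding)
    return CalibrationDesign(list(items), per_item, s, g)


def log_det_criterion(design: CalibrationDesign, nodes: int = 201) -> float:
    """D-criterion -sum_i log det M_i(h_i); +inf if any block is singular."""
    total = 0.0
    for i, item in enumerate(design.items):
        M = design.information_matrix(i, nodes=nodes)
        det = M[0, 0] * M[1, 1] - M[0, 1] ** 2
        if det <= 0:
            warnings.warn(
                f"singular information block for item {item.label or i}",
                RuntimeWarning,
                stacklevel=2,
            )
            return math.inf
        total -= math.log(det)
    return total
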