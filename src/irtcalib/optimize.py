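"""Constrained optimization of restricted interval designs.

The decision variables are interval boundaries expressed on the *probability
scale* ``u = G(theta)`` (G the population cdf).  On that scale both the mass
equality constraint ``sum of interval masses = s`` and the left-to-right
ordering constraints are linear, which suits sequential quadratic programming
(scipy's SLSQP) well; abilities are recovered through the quantile function.

For a single item a two-interval design is optimal, so one ordered block of
four boundaries suffices.  For n >= 2 items, each item is allowed K intervals
and every left-to-right interleaving ("ordering") of the n*K interval slots
is solved separately; the best solution is kept and verified against the
equivalence theorem.  If verification fails, K is increased (K-escalation).

When the whole population is used (s = 1) there is no non-sampling region:
the support is partitioned into contiguous segments and the two unbounded
tails are anchored to the item with the lowest discrimination, which is the
known structure of the optimum in that case.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, minimize
from scipy.special import expit

from .design import (
    CalibrationDesign,
    Interval,
    d_optimal_offset,
    interval_information,
    unrestricted_d_optimal,
)
from .model import AbilityDensity, Item

logger = logging.getLogger(__name__)

__all__ = [
    "SolverConfig",
    "enumerate_orderings",
    "optimize_one_item",
    "optimize_multi_item",
    "tail_anchored_optimize",
]

_MASS_PRUNE = 1e-4  # intervals below this mass are dropped when reporting
_MERGE_GAP = 1e-6  # u-gap below which adjacent same-item intervals merge


@dataclass
class SolverConfig:
    """Solver and verification settings.

    K_max : largest number of intervals tried per item before giving up.
    multistart : number of starting points per interval ordering.
    seed : seed for the random perturbation starts (all randomness).
    nodes / final_nodes : Gauss-Legendre order inside the optimizer loop and
        for final reporting/verification.
    ordering_cap : hard cap on the number of orderings enumerated.
    """

    K_max: int = 4
    multistart: int = 8
    seed: int = 0
    tolerance: float = 1e-8
    max_iterations: int = 120
    nodes: int = 61
    final_nodes: int = 201
    ordering_cap: int = 500
    equivalence_tolerance: float = 5e-3
    grid_size: int = 4001

    def __post_init__(self) -> None:
        if self.K_max < 2:
            raise ValueError("K_max must be >= 2")
        if self.tolerance <= 0 or self.equivalence_tolerance <= 0:
            raise ValueError("tolerances must be positive")


def enumerate_orderings(n: int, K: int, cap: int | None = None) -> list[tuple[int, ...]]:
    """All distinct left-to-right interleavings of n items' K interval slots.

    Each ordering is a tuple of item indices of length n*K in which every
    item appears exactly K times; for n = 2 there are binomial(2K, K) of
    them.  Enumeration stops at ``cap`` orderings if given.
    """
    if n < 1 or K < 1:
        raise ValueError("need n >= 1 and K >= 1")
    out: list[tuple[int, ...]] = []
    def rec(slots: list[int], remaining: list[int]) -> None:
        if cap is not None and len(out) >= cap:
            return
        if not any(remaining):
            out.append(tuple(slots))
            return
        for i in range(n):
            if remaining[i] > 0:
                remaining[i] -= 1
                slots.append(i)
                rec(slots, remaining)
                slots.pop()
                remaining[i] += 1

    rec([], [K] * n)
    return out


# ---------------------------------------------------------------------------
# objective machinery (u-space)


def _objective_from_bounds(items, seq, s, g, nodes):
    """Vectorized -sum log det M_i as a function of interval bounds.

    Returns a callable taking (lo, hi) arrays of length len(seq) on the
    ability scale; all intervals are integrated in one Gauss-Legendre pass
    (the objective sits in the SQP inner loop and per-interval Python
    overhead would dominate otherwise).
    """
    from .design import _gl

    n = len(items)
    x, wq = _gl(nodes)
    a = np.array([items[si].a for si in seq])
    b = np.array([items[si].b for si in seq])
    item_idx = np.asarray(seq)
    lo_s, hi_s = g.support

    def from_bounds(lo: np.ndarray, hi: np.ndarray) -> float:
        lo = np.clip(lo, lo_s, hi_s)
        hi = np.clip(hi, lo_s, hi_s)
        mid = 0.5 * (lo + hi)
        half = np.maximum(0.5 * (hi - lo), 0.0)
        t = mid[:, None] + half[:, None] * x[None, :]
        p = expit(a[:, None] * (t - b[:, None]))
        c = (wq[None, :] * p * (1.0 - p) * g.pdf(t)) * (half[:, None] / s)
        d = t - b[:, None]
        i11 = (c * d * d).sum(axis=1)
        i12 = -a * (c * d).sum(axis=1)
        i22 = a * a * c.sum(axis=1)
        total = 0.0
        for i in range(n):
            sel = item_idx == i
            m11 = i11[sel].sum()
            m12 = i12[sel].sum()
            m22 = i22[sel].sum()
            det = m11 * m22 - m12 * m12
            total -= math.log(det) if det > 1e-300 else math.log(1e-300)
        return total

    return from_bounds


def _objective_intervals(items, seq, s, g, nodes):
    """Objective -sum log det M_i for interval designs given boundary vector u.

    ``u`` has length 2*len(seq); interval j occupies [u[2j], u[2j+1]] on the
    probability scale and belongs to item seq[j].
    """
    from_bounds = _objective_from_bounds(items, seq, s, g, nodes)

    def fun(u: np.ndarray) -> float:
        theta = g.quantile(np.clip(u, 0.0, 1.0))
        return from_bounds(theta[0::2], theta[1::2])

    return fun


def _objective_partition(items, seq, g, nodes):
    """Objective for s = 1 partitions; u are the interior cut points."""
    from_bounds = _objective_from_bounds(items, seq, 1.0, g, nodes)

    def fun(u: np.ndarray) -> float:
        edges = np.concatenate(([0.0], np.clip(u, 0.0, 1.0), [1.0]))
        theta = g.quantile(edges)
        return from_bounds(theta[:-1], theta[1:])

    return fun


def _monotone_constraints(dim: int) -> list[dict]:
    """Linear inequality constraints u[k+1] - u[k] >= 0."""
    A = np.zeros((dim - 1, dim))
    for k in range(dim - 1):
        A[k, k] = -1.0
        A[k, k + 1] = 1.0
    return [{"type": "ineq", "fun": lambda u, A=A: A @ u, "jac": lambda u, A=A: A}]


def _mass_constraint(seq_len: int, s: float) -> dict:
    c = np.tile([-1.0, 1.0], seq_len)

    return {
        "type": "eq",
        "fun": lambda u, c=c: float(c @ u) - s,
        "jac": lambda u, c=c: c,
    }


def _fix_monotone(u: np.ndarray) -> np.ndarray:
    return np.maximum.accumulate(np.clip(u, 0.0, 1.0))


def _anchored_start(items, seq, s, g) -> np.ndarray | None:
    """Start with each interval slot centered at an unrestricted design point.

    Item slots (in left-to-right order of appearance) are matched to the
    item's unrestricted points spread as b + c/a * linspace(-1, 1, K).  If
    the resulting centers are far from monotone the ordering is geometrically
    implausible and no anchored start is produced.
    """
    n = len(items)
    m = len(seq)
    counts = [seq.count(i) for i in range(n)]
    offs = d_optimal_offset()
    targets = []
    for i, item in enumerate(items):
        K = counts[i]
        spread = np.linspace(-1.0, 1.0, K) if K > 1 else np.array([0.0])
        targets.append(list(item.b + offs / item.a * spread))
    ptr = [0] * n
    centers = []
    for si in seq:
        centers.append(targets[si][ptr[si]])
        ptr[si] += 1
    centers = np.asarray(centers)
    if np.any(np.diff(centers) < -1.5):
        return None
    uc = np.asarray(g.cdf(np.sort(centers)))
    half = s / (2 * m)
    u = np.empty(2 * m)
    u[0::2] = uc - half
    u[1::2] = uc + half
    return _fix_monotone(u)


def _spread_start(m: int, s: float) -> np.ndarray:
    """Equal-mass intervals separated by equal-mass gaps."""
    u = np.empty(2 * m)
    gap = (1.0 - s) / (m + 1)
    lo = gap
    for j in range(m):
        u[2 * j] = lo
        u[2 * j + 1] = lo + s / m
        lo = u[2 * j + 1] + gap
    return u


def _gap_starts(s: float) -> list[np.ndarray]:
    """Deterministic two-interval starts for a single item.

    At larger sampling proportions the optimum often leaves most of the
    non-sampled mass at one end of the ability range plus a narrow interior
    gap; plain multistart finds such configurations unreliably.  Enumerate
    starts over the fraction r of non-sampled mass placed below the design
    and the relative position p of the interior gap within the sampled mass.
    """
    out = []
    w = 1.0 - s
    for r in (0.0, 0.5, 0.9):
        for p in (0.3, 0.5, 0.7):
            left_out = r * w
            gap = 0.9 * (1.0 - r) * w
            u = np.array(
                [left_out, left_out + p * s, left_out + p * s + gap, left_out + s + gap]
            )
            out.append(_fix_monotone(u))
    return out


def _random_start(rng: np.random.Generator, m: int, s: float) -> np.ndarray:
    masses = rng.dirichlet(np.ones(m)) * s
    gaps = rng.dirichlet(np.ones(m + 1)) * (1.0 - s)
    u = np.empty(2 * m)
    pos = 0.0
    for j in range(m):
        pos += gaps[j]
        u[2 * j] = pos
        pos += masses[j]
        u[2 * j + 1] = pos
    return u


def _solve_ordering(items, seq, s, g, config, rng, extra_starts=()) -> tuple[float, np.ndarray]:
    """Best SLSQP solution over multistarts for one interval ordering."""
    m = len(seq)
    fun = _objective_intervals(items, seq, s, g, config.nodes)
    cons = _monotone_constraints(2 * m) + [_mass_constraint(m, s)]
    starts: list[np.ndarray] = []
    a = _anchored_start(items, seq, s, g)
    if a is not None:
        starts.append(a)
    starts.append(_spread_start(m, s))
    if m == 2:
        starts.extend(_gap_starts(s))
    starts.extend(np.asarray(e, dtype=float) for e in extra_starts)
    while len(starts) < config.multistart:
        starts.append(_random_start(rng, m, s))
    best_val, best_u = math.inf, starts[0]
    for x0 in starts:
        res = minimize(
            fun,
            x0,
            method="SLSQP",
            bounds=[(0.0, 1.0)] * (2 * m),
            constraints=cons,
            options={"maxiter": config.max_iterations, "ftol": config.tolerance},
        )
        if not np.all(np.isfinite(res.x)):
            continue
        u = _fix_monotone(res.x)
        # keep only mass-feasible solutions
        mass = float(np.sum(u[1::2] - u[0::2]))
        if abs(mass - s) > 1e-6:
            continue
        val = fun(u)
        if val < best_val:
            best_val, best_u = val, u
    return best_val, best_u


def _solve_partition(items, seq, g, config, rng, extra_starts=()) -> tuple[float, np.ndarray]:
    """Best SLSQP solution for an s = 1 partition with segment ordering seq."""
    m = len(seq)
    fun = _objective_partition(items, seq, g, config.nodes)
    dim = m - 1
    cons = _monotone_constraints(dim) if dim > 1 else []
    starts: list[np.ndarray] = [np.linspace(0.0, 1.0, m + 1)[1:-1]]
    starts.extend(np.asarray(e, dtype=float) for e in extra_starts)
    while len(starts) < config.multistart:
        starts.append(np.sort(rng.uniform(0.0, 1.0, dim)))
    best_val, best_u = math.inf, starts[0]
    for x0 in starts:
        res = minimize(
            fun,
            x0,
            method="SLSQP",
            bounds=[(0.0, 1.0)] * dim,
            constraints=cons,
            options={"maxiter": config.max_iterations, "ftol": config.tolerance},
        )
        if not np.all(np.isfinite(res.x)):
            continue
        u = _fix_monotone(res.x)
        val = fun(u)
        if val < best_val:
            best_val, best_u = val, u
    return best_val, best_u


# ---------------------------------------------------------------------------
# design assembly


def _build_design(items, seq, u, s, g) -> CalibrationDesign:
    """Turn a boundary vector into a pruned, merged CalibrationDesign.

    Zero-mass intervals are dropped, adjacent intervals of the same item with
    (numerically) coinciding boundaries are merged, and boundaries within
    1e-6 mass of the support edge are rendered as +-infinity.
    """
    m = len(seq)
    u = _fix_monotone(np.asarray(u, dtype=float))
    raw: list[tuple[int, float, float]] = []  # (item, u_lo, u_hi)
    for j, si in enumerate(seq):
        raw.append((si, u[2 * j], u[2 * j + 1]))
    merged: list[tuple[int, float, float]] = []
    for si, ulo, uhi in raw:
        if merged and merged[-1][0] == si and ulo - merged[-1][2] < _MERGE_GAP:
            merged[-1] = (si, merged[-1][1], uhi)
        else:
            merged.append((si, ulo, uhi))
    per_item: list[list[Interval]] = [[] for _ in items]
    for si, ulo, uhi in merged:
        if uhi - ulo < _MASS_PRUNE:
            continue
        lo = -math.inf if ulo < 1e-6 else float(g.quantile(ulo))
        hi = math.inf if uhi > 1 - 1e-6 else float(g.quantile(uhi))
        per_item[si].append(Interval(lo, hi))
    return CalibrationDesign(list(items), per_item, s, g)


def _build_partition_design(items, seq, cuts, g) -> CalibrationDesign:
    m = len(seq)
    edges = np.concatenate(([0.0], _fix_monotone(np.asarray(cuts, dtype=float)), [1.0]))
    u = np.empty(2 * m)
    u[0::2] = edges[:-1]
    u[1::2] = edges[1:]
    return _build_design(items, seq, u, 1.0, g)


def _exchange_polish(
    design: CalibrationDesign, config: SolverConfig, max_iter: int = 30
) -> CalibrationDesign:
    """Refine a near-optimal design by solving its first-order conditions.

    The D-criterion is second-order flat in the boundary positions at the
    optimum, so an SQP solve leaves boundaries off by O(sqrt(ftol)) even
    when the criterion is converged — enough to fail the sharp directional-
    derivative check.  At the optimum every finite boundary satisfies a
    scalar equation: a boundary shared by two items sits where their
    directional-derivative curves cross, and a boundary against the
    non-sampled region sits where the owner's curve equals the threshold c,
    with the total sampled mass equal to s.  Keeping the interval structure
    fixed, this polish solves that square nonlinear system (boundaries and
    threshold jointly, information blocks recomputed inside the residual)
    with a Newton-type root finder; plain best-response iteration is not an
    option because the fixed point can be linearly unstable when two items
    compete for the same ability range.  If the solve fails or degrades the
    criterion, the input design is returned unchanged.
    """
    from scipy.optimize import root as _root
    from scipy.special import expit

    g = design.g
    items = design.items
    n = len(items)
    s = design.s
    lo_s, hi_s = g.support
    flat = sorted(
        (float(iv.lo), float(iv.hi), i)
        for i, ivs in enumerate(design.intervals_by_item)
        for iv in ivs
    )
    if not flat:
        return design
    # merge adjacent intervals of the same item separated by a negligible
    # gap: if left split, the pair would contribute a degenerate "crossing"
    # equation F_i - F_i = 0 and make the Newton system singular
    merged: list[tuple[float, float, int]] = []
    for lo, hi, i in flat:
        if merged and merged[-1][2] == i and g.mass(merged[-1][1], lo) < 1e-3:
            merged[-1] = (merged[-1][0], hi, i)
        else:
            merged.append((lo, hi, i))
    flat = merged
    m = len(flat)
    owners = [t[2] for t in flat]
    x0 = np.empty(2 * m)
    for k, (lo, hi, _) in enumerate(flat):
        x0[2 * k] = max(lo, lo_s)
        x0[2 * k + 1] = min(hi, hi_s)
    # classify the 2m boundary slots: fixed support edges, crossings shared
    # with the neighbouring interval (negligible gap), or level boundaries
    kind = ["level"] * (2 * m)
    if g.cdf(x0[0]) < 1e-9:
        kind[0] = "edge"
    if g.cdf(x0[2 * m - 1]) > 1 - 1e-9:
        kind[2 * m - 1] = "edge"
    cross_gaps = []  # gap index k: interval k abuts interval k+1
    for k in range(m - 1):
        if g.mass(x0[2 * k + 1], x0[2 * k + 2]) < 1e-3:
            cross_gaps.append(k)
            kind[2 * k + 1] = kind[2 * k + 2] = "cross"
    level_slots = [k for k in range(2 * m) if kind[k] == "level"]
    with_threshold = s < 1.0 - 1e-12 and bool(level_slots)

    def build_x(z: np.ndarray) -> np.ndarray:
        x = x0.copy()
        pos = 0
        for k in level_slots:
            x[k] = z[pos]
            pos += 1
        for k in cross_gaps:
            x[2 * k + 1] = x[2 * k + 2] = z[pos]
            pos += 1
        return x

    def curves(x: np.ndarray):
        per_item = [[] for _ in items]
        for k in range(m):
            per_item[owners[k]].append((min(x[2 * k], x[2 * k + 1]), max(x[2 * k], x[2 * k + 1])))
        coef = []
        for i, item in enumerate(items):
            M = interval_information(item, per_item[i], g, s, nodes=config.final_nodes)
            det = M[0, 0] * M[1, 1] - M[0, 1] ** 2
            if det <= 0:
                return None
            coef.append((item.a, item.b, M[1, 1] / det, -M[0, 1] / det, M[0, 0] / det))

        def F(th, i):
            a, b, m00, m01, m11 = coef[i]
            d = th - b
            nu = expit(a * d) * expit(-a * d)
            return 2.0 - nu * (m00 * d * d - 2.0 * m01 * d * a + m11 * a * a)

        return F

    def residual(z: np.ndarray) -> np.ndarray:
        x = build_x(z)
        F = curves(x)
        if F is None:
            return np.full(len(z), 1e3)
        c = z[-1] if with_threshold else 0.0
        res = []
        for k in level_slots:
            res.append(F(x[k], owners[k // 2]) - c)
        for k in cross_gaps:
            res.append(F(x[2 * k + 1], owners[k]) - F(x[2 * k + 1], owners[k + 1]))
        if with_threshold:
            mass = sum(g.mass(min(x[2 * k], x[2 * k + 1]), max(x[2 * k], x[2 * k + 1])) for k in range(m))
            res.append(mass - s)
        return np.asarray(res)

    z0 = [x0[k] for k in level_slots] + [x0[2 * k + 1] for k in cross_gaps]
    if with_threshold:
        # initial threshold: median directional-derivative value at the level
        # boundaries of the current design
        F0 = curves(x0)
        if F0 is None:
            return design
        z0.append(float(np.median([F0(x0[k], owners[k // 2]) for k in level_slots])))
    z0 = np.asarray(z0)
    if len(z0) == 0:
        return design
    sol = _root(residual, z0, method="hybr", options={"xtol": 1e-12})
    x_fin = build_x(sol.x)
    if np.any(np.diff(x_fin) < -1e-9) or np.max(np.abs(x_fin - x0)) > 0.5:
        return design
    x_fin = np.maximum.accumulate(x_fin)
    per_item: list[list[Interval]] = [[] for _ in items]
    for k in range(m):
        per_item[owners[k]].append(Interval(x_fin[2 * k], x_fin[2 * k + 1]))
    polished = CalibrationDesign(list(items), per_item, s, g)
    old_val = _criterion_value(design, config)
    new_val = _criterion_value(polished, config)
    if not math.isfinite(new_val) or new_val > old_val + 1e-6:
        logger.debug("polish rejected: criterion %.9f -> %.9f", old_val, new_val)
        return design
    return _tidy(polished)


def _criterion_value(design: CalibrationDesign, config: SolverConfig) -> float:
    total = 0.0
    for i in range(len(design.items)):
        M = design.information_matrix(i, nodes=config.final_nodes)
        det = M[0, 0] * M[1, 1] - M[0, 1] ** 2
        if det <= 0:
            return math.inf
        total -= math.log(det)
    return total


def _tidy(design: CalibrationDesign) -> CalibrationDesign:
    """Prune negligible intervals and render support-edge boundaries infinite."""
    g = design.g
    per_item: list[list[Interval]] = []
    for ivs in design.intervals_by_item:
        kept = []
        for iv in ivs:
            if g.mass(iv.lo, iv.hi) < _MASS_PRUNE:
                continue
            lo = -math.inf if g.cdf(iv.lo) < 1e-6 else iv.lo
            hi = math.inf if g.cdf(iv.hi) > 1 - 1e-6 else iv.hi
            kept.append(Interval(lo, hi))
        per_item.append(kept)
    return CalibrationDesign(design.items, per_item, design.s, g)


def _structure_step(
    design: CalibrationDesign, config: SolverConfig
) -> CalibrationDesign | None:
    """Rebuild a design from its own directional-derivative curves.

    Takes the sub-level set of the lower envelope with population mass s
    (grid resolution) and assigns each ability to the item attaining the
    minimum.  The result reveals the interval structure the current curves
    actually support — e.g. a third interval the boundary optimizer's
    ordering collapsed — and is meant to be refined by the Newton polish;
    masses and boundaries are only grid-accurate here.
    """
    g = design.g
    items = design.items
    n = len(items)
    s = design.s
    lo_s, hi_s = g.support
    grid = np.linspace(lo_s, hi_s, 8001)
    Ms = design.information_matrices(nodes=config.final_nodes)
    coef = []
    for item, M in zip(items, Ms):
        det = M[0, 0] * M[1, 1] - M[0, 1] ** 2
        if det <= 0:
            return None
        coef.append((item.a, item.b, M[1, 1] / det, -M[0, 1] / det, M[0, 0] / det))

    def F(th, i):
        a, b, m00, m01, m11 = coef[i]
        d = th - b
        nu = expit(a * d) * expit(-a * d)
        return 2.0 - nu * (m00 * d * d - 2.0 * m01 * d * a + m11 * a * a)

    Fgrid = np.column_stack([F(grid, i) for i in range(n)])
    Lgrid = Fgrid.min(axis=1)
    if s >= 1.0 - 1e-12:
        inside = np.ones(len(grid), dtype=bool)
    else:
        mids = 0.5 * (grid[:-1] + grid[1:])
        ce = np.asarray(g.cdf(np.concatenate(([lo_s], mids, [hi_s]))))
        ce[0], ce[-1] = 0.0, 1.0
        w = np.diff(ce)
        order = np.argsort(Lgrid)
        k = min(int(np.searchsorted(np.cumsum(w[order]), s)), len(order) - 1)
        inside = Lgrid <= float(Lgrid[order[k]])
    owner = np.where(inside, np.argmin(Fgrid, axis=1), -1)
    change = np.flatnonzero(np.diff(owner)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(grid)]))
    per_item: list[list[Interval]] = [[] for _ in items]
    for s0, e0 in zip(starts, ends):
        o = int(owner[s0])
        if o >= 0 and e0 - 1 > s0:
            per_item[o].append(Interval(float(grid[s0]), float(grid[e0 - 1])))
    if any(not ivs for ivs in per_item):
        return None
    return CalibrationDesign(list(items), per_item, s, g)


def _rescue(design: CalibrationDesign, config: SolverConfig) -> CalibrationDesign | None:
    """Structure discovery followed by Newton refinement and verification."""
    step = _structure_step(design, config)
    if step is None:
        return None
    cand = _exchange_polish(step, config)
    cand.K = max(len(ivs) for ivs in cand.intervals_by_item)
    cand.criterion = _criterion_value(cand, config)
    cand.report = _verify(cand, config)
    return cand


def _verify(design: CalibrationDesign, config: SolverConfig):
    from .equivalence import check_optimality

    return check_optimality(
        design,
        tolerance=config.equivalence_tolerance,
        grid_size=config.grid_size,
        nodes=config.final_nodes,
    )


# ---------------------------------------------------------------------------
# public optimizers


def optimize_one_item(
    item: Item, s: float, g: AbilityDensity, config: SolverConfig | None = None
) -> CalibrationDesign | "PointDesign":
    """Locally D-optimal restricted design for a single item.

    Maximizes det M over ordered boundaries theta_1L <= theta_1U <= theta_2L
    <= theta_2U subject to total mass s; the two intervals collapse to one
    when the interior boundaries merge.  ``s = 0`` is accepted as a limiting
    request and returns the unrestricted two-point design.
    """
    config = config or SolverConfig()
    if s == 0:
        return unrestricted_d_optimal(item)
    if not 0 < s <= 1:
        raise ValueError(f"s must be in (0, 1], got {s}")
    if s >= 1.0:
        design = CalibrationDesign([item], [[Interval(-math.inf, math.inf)]], 1.0, g)
        design.K = 1
        design.criterion = _objective_intervals([item], (0, 0), 1.0, g, config.final_nodes)(
            np.array([0.0, 1.0, 1.0, 1.0])
        )
        design.report = _verify(design, config)
        return design
    rng = np.random.default_rng(config.seed)
    seq = (0, 0)
    val, u = _solve_ordering([item], seq, s, g, config, rng)
    if not math.isfinite(val):
        raise RuntimeError("one-item solver failed to find a feasible design")
    design = _exchange_polish(_build_design([item], seq, u, s, g), config)
    design.K = max(len(design.intervals_by_item[0]), 1)
    design.criterion = _criterion_value(design, config)
    design.report = _verify(design, config)
    if not design.report.passed:
        rescued = _rescue(design, config)
        if (
            rescued is not None
            and rescued.report.passed
            and rescued.criterion <= design.criterion + 1e-6
        ):
            rescued.K = max(len(rescued.intervals_by_item[0]), 1)
            return rescued
        design.converged = False
        warnings.warn(
            f"equivalence check failed for item {item.label or ''} at s={s}: "
            f"max violation {design.report.max_violation:.2e}",
            RuntimeWarning,
            stacklevel=2,
        )
    return design


def optimize_multi_item(
    items: Sequence[Item], s: float, g: AbilityDensity, config: SolverConfig | None = None
) -> CalibrationDesign:
    """Joint locally D-optimal restricted design for n >= 2 items.

    For K = 2, ..., K_max every interval ordering is solved and the best
    kept; the K-escalation stops as soon as the equivalence verifier passes.
    The best K-1 solution (padded with zero-width slots) seeds level K, so
    the criterion cannot get worse as K grows.  If no K passes, the best
    design is returned flagged ``converged=False``.
    """
    config = config or SolverConfig()
    items = list(items)
    n = len(items)
    if n < 2:
        raise ValueError("optimize_multi_item needs n >= 2 items")
    if s >= 1.0:
        return tail_anchored_optimize(items, g, config)
    if not 0 < s < 1:
        raise ValueError(f"s must be in (0, 1], got {s}")
    rng = np.random.default_rng(config.seed)
    best_overall: tuple[float, tuple[int, ...], np.ndarray] | None = None
    prev_best: tuple[tuple[int, ...], np.ndarray] | None = None
    for K in range(2, config.K_max + 1):
        orderings = enumerate_orderings(n, K, cap=config.ordering_cap)
        results_K: list[tuple[float, tuple[int, ...], np.ndarray]] = []
        for oi, seq in enumerate(orderings):
            extra = []
            if prev_best is not None:
                padded = _pad_solution(prev_best[0], prev_best[1], seq)
                if padded is not None:
                    extra.append(padded)
            val, u = _solve_ordering(items, seq, s, g, config, rng, extra_starts=extra)
            logger.info("K=%d ordering %d/%d %s criterion %.6f", K, oi + 1, len(orderings), seq, val)
            results_K.append((val, seq, u))
        results_K.sort(key=lambda t: t[0])
        best_K = results_K[0]
        if best_overall is None or best_K[0] < best_overall[0] + 1e-12:
            best_overall = best_K
        # the SQP values of near-tied orderings are only converged to ~ftol,
        # so polish and verify the few best instead of the top one alone
        for val, seq, u in results_K[: min(3, len(results_K))]:
            if val > best_K[0] + 1e-3:
                break
            design = _exchange_polish(_build_design(items, seq, u, s, g), config)
            design.K = max(len(ivs) for ivs in design.intervals_by_item)
            design.criterion = _criterion_value(design, config)
            design.report = _verify(design, config)
            if design.report.passed:
                return design
            rescued = _rescue(design, config)
            if (
                rescued is not None
                and rescued.report.passed
                and rescued.criterion <= design.criterion + 1e-6
            ):
                return rescued
        prev_best = (best_K[1], best_K[2])
        logger.info("K=%d rejected by equivalence check (violation %.3e)", K, design.report.max_violation)
    design = _exchange_polish(_build_design(items, best_overall[1], best_overall[2], s, g), config)
    design.K = max(len(ivs) for ivs in design.intervals_by_item)
    design.criterion = _criterion_value(design, config)
    design.report = _verify(design, config)
    design.converged = False
    warnings.warn(
        f"no K <= {config.K_max} passed the equivalence check; returning best design found",
        RuntimeWarning,
        stacklevel=2,
    )
    return design


def _pad_solution(
    seq_prev: tuple[int, ...], u_prev: np.ndarray, seq_new: tuple[int, ...]
) -> np.ndarray | None:
    """Embed a K-1 solution into a K ordering by adding zero-width slots.

    Greedy left-to-right matching of the previous slots into the new
    ordering; unmatched new slots become zero-width intervals at the position
    of the previous boundary.  Returns None if the orderings are not
    compatible under greedy matching.
    """
    u_new = np.empty(2 * len(seq_new))
    p = 0
    last = 0.0
    for j, si in enumerate(seq_new):
        if p < len(seq_prev) and seq_prev[p] == si:
            u_new[2 * j] = u_prev[2 * p]
            u_new[2 * j + 1] = u_prev[2 * p + 1]
            last = u_prev[2 * p + 1]
            p += 1
        else:
            u_new[2 * j] = last
            u_new[2 * j + 1] = last
    if p != len(seq_prev):
        return None
    return _fix_monotone(u_new)


def tail_anchored_optimize(
    items: Sequence[Item], g: AbilityDensity, config: SolverConfig | None = None
) -> CalibrationDesign:
    """Whole-population (s = 1) optimum with tails anchored to the weakest
    discriminator.

    The support is partitioned into contiguous segments; the two unbounded
    tail segments belong to the item with the smallest discrimination, and
    the interior segment ordering (each item K times) is enumerated.  Ties in
    the smallest ``a`` break deterministically by item order.
    """
    config = config or SolverConfig()
    items = list(items)
    n = len(items)
    if n == 1:
        design = CalibrationDesign(items, [[Interval(-math.inf, math.inf)]], 1.0, g)
        design.K = 1
        design.criterion = _objective_partition(items, (0,), g, config.final_nodes)(np.array([]))
        design.report = _verify(design, config)
        return design
    a_vals = [it.a for it in items]
    i_low = int(np.argmin(a_vals))
    if a_vals.count(min(a_vals)) > 1:
        warnings.warn(
            "tie in smallest discrimination; tails assigned to the first such item",
            RuntimeWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(config.seed)
    best_overall: tuple[float, tuple[int, ...], np.ndarray] | None = None
    prev_best: tuple[tuple[int, ...], np.ndarray] | None = None
    for K in range(2, config.K_max + 1):
        interiors = enumerate_orderings(n, K, cap=config.ordering_cap)
        results_K: list[tuple[float, tuple[int, ...], np.ndarray]] = []
        for oi, interior in enumerate(interiors):
            seq = (i_low,) + interior + (i_low,)
            extra = []
            if prev_best is not None and _embeds(prev_best[0], seq):
                padded = _pad_cuts(prev_best[0], prev_best[1], seq)
                if padded is not None:
                    extra.append(padded)
            val, u = _solve_partition(items, seq, g, config, rng, extra_starts=extra)
            logger.info(
                "s=1 K=%d ordering %d/%d %s criterion %.6f", K, oi + 1, len(interiors), seq, val
            )
            results_K.append((val, seq, u))
        results_K.sort(key=lambda t: t[0])
        best_K = results_K[0]
        if best_overall is None or best_K[0] < best_overall[0] + 1e-12:
            best_overall = best_K
        for val, seq, u in results_K[: min(3, len(results_K))]:
            if val > best_K[0] + 1e-3:
                break
            design = _exchange_polish(_build_partition_design(items, seq, u, g), config)
            design.K = max(len(ivs) for ivs in design.intervals_by_item)
            design.criterion = _criterion_value(design, config)
            design.report = _verify(design, config)
            if design.report.passed:
                return design
            rescued = _rescue(design, config)
            if (
                rescued is not None
                and rescued.report.passed
                and rescued.criterion <= design.criterion + 1e-6
            ):
                return rescued
        prev_best = (best_K[1], best_K[2])
    design = _exchange_polish(
        _build_partition_design(items, best_overall[1], best_overall[2], g), config
    )
    design.K = max(len(ivs) for ivs in design.intervals_by_item)
    design.criterion = _criterion_value(design, config)
    design.report = _verify(design, config)
    design.converged = False
    warnings.warn(
        f"no K <= {config.K_max} passed the equivalence check; returning best design found",
        RuntimeWarning,
        stacklevel=2,
    )
    return design


def _embeds(seq_prev: tuple[int, ...], seq_new: tuple[int, ...]) -> bool:
    p = 0
    for si in seq_new:
        if p < len(seq_prev) and seq_prev[p] == si:
            p += 1
    return p == len(seq_prev)


def _pad_cuts(
    seq_prev: tuple[int, ...], cuts_prev: np.ndarray, seq_new: tuple[int, ...]
) -> np.ndarray | None:
    edges_prev = np.concatenate(([0.0], np.asarray(cuts_prev, dtype=float), [1.0]))
    edges_new = np.empty(len(seq_new) + 1)
    edges_new[0] = 0.0
    p = 0
    for j, si in enumerate(seq_new):
        if p < len(seq_prev) and seq_prev[p] == si:
            edges_new[j + 1] = edges_prev[p + 1]
            p += 1
        else:
            edges_new[j + 1] = edges_new[j]
    if p != len(seq_prev):
        return None
    return _fix_monotone(edges_new[1:-1])
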