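"""Independent numerical oracles used only by the tests.

These deliberately avoid the package's Gauss-Legendre quadrature and SQP
machinery: information matrices are accumulated by dense midpoint /
trapezoid rules on fine grids, and one-item optimal designs are found by
exhaustive search over boundary grids with the mass constraint eliminated
analytically through the last boundary.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm


def midpoint_information(item, bounds, s, nodes_total=1_000_000):
    """Midpoint-rule information matrix for a standard normal population."""
    total_len = sum(hi - lo for lo, hi in bounds)
    M = np.zeros((2, 2))
    for lo, hi in bounds:
        n = max(int(nodes_total * (hi - lo) / total_len), 10)
        edges = np.linspace(lo, hi, n + 1)
        t = 0.5 * (edges[:-1] + edges[1:])
        h = (hi - lo) / n
        p = 1.0 / (1.0 + np.exp(-item.a * (t - item.b)))
        nu = p * (1 - p)
        c = nu * norm.pdf(t) * h / s
        d = t - item.b
        M[0, 0] += np.sum(c * d * d)
        M[0, 1] += np.sum(-item.a * c * d)
        M[1, 1] += np.sum(c) * item.a**2
    M[1, 0] = M[0, 1]
    return M


def one_item_grid_search(item, s, lo=-4.0, hi=4.0, step=0.05):
    """Best log-det over two-interval designs with boundaries on a grid.

    Boundaries theta_1L <= theta_1U <= theta_2L run over the grid; theta_2U
    is solved from the mass constraint (infinite when the remaining mass
    fits in the upper tail).  Returns the maximal log det M.
    """
    tg = np.linspace(-9.0, 9.0, 360001)
    p = 1.0 / (1.0 + np.exp(-item.a * (tg - item.b)))
    nu = p * (1 - p)
    gp = norm.pdf(tg)
    dt = tg[1] - tg[0]
    d = tg - item.b
    C11 = np.concatenate(([0.0], np.cumsum(nu * d * d * gp) * dt))
    C12 = np.concatenate(([0.0], np.cumsum(-item.a * nu * d * gp) * dt))
    C22 = np.concatenate(([0.0], np.cumsum(item.a**2 * nu * gp) * dt))
    tgrid = np.concatenate((tg, [tg[-1] + dt]))

    def cums(theta):
        return (
            np.interp(theta, tgrid, C11),
            np.interp(theta, tgrid, C12),
            np.interp(theta, tgrid, C22),
        )

    B = np.arange(lo, hi + 1e-9, step)
    U = norm.cdf(B)
    best = -np.inf
    c11_B, c12_B, c22_B = cums(B)
    for i1 in range(len(B)):
        for i2 in range(i1, len(B)):
            m1 = U[i2] - U[i1]
            if m1 > s + 1e-12:
                break
            rem = s - m1
            j = np.arange(i2, len(B))
            u4 = U[j] + rem
            valid = u4 <= 1.0 - 1e-14
            t4 = np.where(valid, norm.ppf(np.clip(u4, 0.0, 1.0 - 1e-16)), 9.0)
            a11, a12, a22 = cums(t4)
            m11 = (c11_B[i2] - c11_B[i1]) + (a11 - c11_B[j])
            m12 = (c12_B[i2] - c12_B[i1]) + (a12 - c12_B[j])
            m22 = (c22_B[i2] - c22_B[i1]) + (a22 - c22_B[j])
            det = (m11 * m22 - m12 * m12) / s**2
            det = det[det > 0]
            if det.size:
                best = max(best, float(np.max(np.log(det))))
    return best
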