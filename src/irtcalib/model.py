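"""Two-parameter logistic (2PL) item response model and ability populations.

The 2PL model gives the probability that an examinee with latent ability
``theta`` answers an item correctly,

    p(theta) = 1 / (1 + exp(-a * (theta - b))),

where ``a > 0`` is the item's discrimination and ``b`` its difficulty.
Calibration designs are built from three ingredients defined here: the
response probability, the GLM weight ``nu = p * (1 - p)`` entering the Fisher
information, and the gradient of the logit link with respect to ``(a, b)``.

The examinee population is described by a continuous ability density ``g``
(standard normal by default).  Any density can be supplied through
:class:`AbilityDensity` as long as pdf, cdf and quantile are available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.special import expit

__all__ = [
    "Item",
    "AbilityDensity",
    "prob_correct",
    "glm_weight",
    "link_gradient",
    "density_mass",
]


@dataclass(frozen=True)
class Item:
    """Best-guess parameters of one 2PL item.

    Parameters
    ----------
    a : float
        Discrimination, must be strictly positive.
    b : float
        Difficulty, on the ability scale; must be finite.
    label : str
        Identifier used in tables and plots.
    """

    a: float
    b: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.a > 0 and math.isfinite(self.a)):
            raise ValueError(f"discrimination a must be positive and finite, got {self.a}")
        if not math.isfinite(self.b):
            raise ValueError(f"difficulty b must be finite, got {self.b}")


class AbilityDensity:
    """Continuous ability density with mass and quantile queries.

    The support is truncated to a finite window ``[lo, hi]`` for numerical
    work; the mass outside the window must be negligible (< 1e-10 for the
    shipped standard normal window of [-10, 10]).
    """

    def __init__(
        self,
        pdf: Callable[[np.ndarray], np.ndarray],
        cdf: Callable[[np.ndarray], np.ndarray],
        quantile: Callable[[np.ndarray], np.ndarray],
        support: tuple[float, float] = (-10.0, 10.0),
        name: str = "",
    ) -> None:
        self._pdf = pdf
        self._cdf = cdf
        self._quantile = quantile
        lo, hi = float(support[0]), float(support[1])
        if not lo < hi:
            raise ValueError("support bounds must satisfy lo < hi")
        self.support = (lo, hi)
        self.name = name

    # thin call-through wrappers keep the callables duck-typed
    def pdf(self, theta):
        return self._pdf(np.asarray(theta, dtype=float))

    def cdf(self, theta):
        return self._cdf(np.asarray(theta, dtype=float))

    def quantile(self, p):
        return self._quantile(np.asarray(p, dtype=float))

    def mass(self, lo: float, hi: float) -> float:
        """Probability mass of the interval [lo, hi]; infinite ends allowed."""
        if hi < lo:
            raise ValueError(f"interval endpoints out of order: ({lo}, {hi})")
        clo = 0.0 if lo == -math.inf else float(self.cdf(lo))
        chi = 1.0 if hi == math.inf else float(self.cdf(hi))
        return max(chi - clo, 0.0)

    @classmethod
    def normal(cls, mean: float = 0.0, sd: float = 1.0, half_width_sd: float = 10.0) -> "AbilityDensity":
        """Normal ability population truncated (numerically) at mean +- 10 sd.

        Implemented on the ndtr/ndtri ufuncs rather than a frozen scipy
        distribution: the density sits in the optimizer's inner loop and the
        frozen-distribution call overhead dominates otherwise.
        """
        from scipy.special import ndtr, ndtri

        inv_norm = 1.0 / (sd * math.sqrt(2.0 * math.pi))

        def pdf(theta):
            z = (theta - mean) / sd
            return inv_norm * np.exp(-0.5 * z * z)

        return cls(
            pdf=pdf,
            cdf=lambda theta: ndtr((theta - mean) / sd),
            quantile=lambda p: mean + sd * ndtri(p),
            support=(mean - half_width_sd * sd, mean + half_width_sd * sd),
            name=f"normal({mean:g}, {sd:g})",
        )

    @classmethod
    def standard_normal(cls) -> "AbilityDensity":
        return cls.normal(0.0, 1.0)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"AbilityDensity({self.name or 'custom'}, support={self.support})"


def prob_correct(item: Item, theta) -> np.ndarray | float:
    """2PL probability of a correct response, overflow-safe for any eta."""
    theta = np.asarray(theta, dtype=float)
    out = expit(item.a * (theta - item.b))
    return out if out.ndim else float(out)


def glm_weight(item: Item, theta) -> np.ndarray | float:
    """GLM weight nu(theta) = p(1-p); maximal (= 1/4) exactly at theta = b."""
    theta = np.asarray(theta, dtype=float)
    eta = item.a * (theta - item.b)
    # p(1-p) = expit(eta) * expit(-eta), stable in both tails
    out = expit(eta) * expit(-eta)
    return out if out.ndim else float(out)


def link_gradient(item: Item, theta) -> np.ndarray:
    """Gradient of the logit link eta = a(theta-b) in (a, b): (theta-b, -a).

    Returns an array with last axis of length 2.
    """
    theta = np.asarray(theta, dtype=float)
    grad = np.empty(theta.shape + (2,), dtype=float)
    grad[..., 0] = theta - item.b
    grad[..., 1] = -item.a
    return grad


def density_mass(g: AbilityDensity, interval) -> float:
    """Mass of ``interval`` (any object with lo/hi or a 2-sequence) under g."""
    lo, hi = _interval_bounds(interval)
    return g.mass(lo, hi)


def _interval_bounds(interval) -> tuple[float, float]:
    if hasattr(interval, "lo") and hasattr(interval, "hi"):
        return float(interval.lo), float(interval.hi)
    lo, hi = interval
    return float(lo), float(hi)
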