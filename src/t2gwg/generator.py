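"""Generic odds-ratio generator: any outer cdf R over any baseline H.

The generator composes an "outer transformer" R (a cdf on (0, inf)) with
the exponentiated odds ratio of an "inner driver" baseline::

    F(x) = R( alpha * (H(x)/Hbar(x))**beta )

Choosing R as the Type 2 Gumbel cdf ``R(t) = exp(-lambda * t**(-delta))``
with lambda = delta = 1 and the scale reparameterised recovers the T2GWG
family implemented in :mod:`t2gwg.core`; other outer choices (uniform,
Weibull, Lomax, Frechet, ...) yield further families.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict

import numpy as np

from .baselines import Baseline

__all__ = [
    "OuterTransformer",
    "OUTER_REGISTRY",
    "register_outer",
    "get_outer",
    "ComposedDistribution",
    "compose",
    "composed_cdf_grid_check",
]


@dataclass(frozen=True)
class OuterTransformer:
    """An outer cdf R on (0, inf) with its density r."""

    name: str
    params: tuple
    cdf_fn: Callable[[np.ndarray], np.ndarray]
    pdf_fn: Callable[[np.ndarray], np.ndarray]


OUTER_REGISTRY: Dict[str, Callable[..., OuterTransformer]] = {}


def register_outer(name: str):
    def deco(factory):
        OUTER_REGISTRY[name] = factory
        return factory
    return deco


def get_outer(name: str, *params: float) -> OuterTransformer:
    try:
        factory = OUTER_REGISTRY[name]
    except KeyError:
        valid = ", ".join(sorted(OUTER_REGISTRY))
        raise ValueError(f"unknown outer transformer {name!r}; valid: {valid}") from None
    return factory(*params)


def _pos(**kw):
    for k, v in kw.items():
        if not np.isfinite(v) or v <= 0:
            raise ValueError(f"outer parameter {k!r} must be positive, got {v!r}")


@register_outer("uniform")
def uniform_outer(theta: float) -> OuterTransformer:
    """R(t) = t/theta on (0, theta)."""
    _pos(theta=theta)
    return OuterTransformer(
        "uniform", (theta,),
        cdf_fn=lambda t: np.clip(np.asarray(t, float) / theta, 0.0, 1.0),
        pdf_fn=lambda t: np.where((np.asarray(t, float) > 0) & (np.asarray(t, float) < theta),
                                  1.0 / theta, 0.0),
    )


@register_outer("weibull")
def weibull_outer(lam: float, k: float) -> OuterTransformer:
    """R(t) = 1 - exp(-(t/lam)^k)."""
    _pos(lam=lam, k=k)

    def cdf(t):
        t = np.maximum(np.asarray(t, float), 0.0)
        return -np.expm1(-np.power(t / lam, k))

    def pdf(t):
        t = np.asarray(t, float)
        ts = np.maximum(t, 1e-320)
        return np.where(t > 0, (k / lam) * np.power(ts / lam, k - 1.0)
                        * np.exp(-np.power(ts / lam, k)), 0.0)

    return OuterTransformer("weibull", (lam, k), cdf, pdf)


@register_outer("lomax")
def lomax_outer(lam: float, k: float) -> OuterTransformer:
    """R(t) = 1 - (1 + lam*t)^(-k)."""
    _pos(lam=lam, k=k)

    def cdf(t):
        t = np.maximum(np.asarray(t, float), 0.0)
        return -np.expm1(-k * np.log1p(lam * t))

    def pdf(t):
        t = np.asarray(t, float)
        return np.where(t > 0, k * lam * np.power(1.0 + lam * np.maximum(t, 0.0), -k - 1.0), 0.0)

    return OuterTransformer("lomax", (lam, k), cdf, pdf)


@register_outer("frechet")
def frechet_outer(lam: float, gamma: float) -> OuterTransformer:
    """R(t) = exp(-lam * t^(-gamma))."""
    _pos(lam=lam, gamma=gamma)

    def cdf(t):
        t = np.asarray(t, float)
        with np.errstate(divide="ignore", over="ignore"):
            return np.where(t > 0, np.exp(-lam * np.power(np.maximum(t, 1e-320), -gamma)), 0.0)

    def pdf(t):
        t = np.asarray(t, float)
        ts = np.maximum(t, 1e-320)
        with np.errstate(over="ignore"):
            return np.where(t > 0, lam * gamma * np.power(ts, -gamma - 1.0)
                            * np.exp(-lam * np.power(ts, -gamma)), 0.0)

    return OuterTransformer("frechet", (lam, gamma), cdf, pdf)


@register_outer("gumbel2")
def gumbel2_outer(lam: float, delta: float) -> OuterTransformer:
    """Type 2 Gumbel: R(t) = exp(-lam * t^(-delta))."""
    _pos(lam=lam, delta=delta)

    def cdf(t):
        t = np.asarray(t, float)
        with np.errstate(over="ignore"):
            return np.where(t > 0, np.exp(-lam * np.power(np.maximum(t, 1e-320), -delta)), 0.0)

    def pdf(t):
        t = np.asarray(t, float)
        ts = np.maximum(t, 1e-320)
        with np.errstate(over="ignore"):
            return np.where(t > 0, lam * delta * np.power(ts, -delta - 1.0)
                            * np.exp(-lam * np.power(ts, -delta)), 0.0)

    return OuterTransformer("gumbel2", (lam, delta), cdf, pdf)


class ComposedDistribution:
    """F(x) = R(alpha * (H/Hbar)^beta) with the chain-rule density.

    At points where the baseline survival vanishes (upper support bound of
    a bounded baseline) the odds ratio diverges and the cdf takes its limit
    value R(inf) = 1, with density 0.
    """

    def __init__(self, outer: OuterTransformer, baseline: Baseline,
                 alpha: float, beta: float):
        if alpha <= 0 or beta <= 0:
            raise ValueError("alpha and beta must be positive")
        self.outer = outer
        self.baseline = baseline
        self.alpha = float(alpha)
        self.beta = float(beta)

    @property
    def support(self) -> tuple:
        return self.baseline.support

    def _t(self, x):
        lo = self.baseline.logcdf(x) - self.baseline.logsf(x)
        with np.errstate(over="ignore"):
            return self.alpha * np.exp(self.beta * lo)

    def cdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        t = self._t(x)
        lower, upper = self.support
        out = np.where(np.isfinite(t), self.outer.cdf_fn(np.where(np.isfinite(t), t, 1.0)), 1.0)
        out = np.where(x <= lower, 0.0, out)
        return np.where(x >= upper, 1.0, out)

    def pdf(self, x) -> np.ndarray:
        # f = r(t) * dt/dx, dt/dx = alpha*beta*(H/Hbar)^(beta-1) * h/Hbar^2
        x = np.asarray(x, dtype=float)
        t = self._t(x)
        lH = self.baseline.logcdf(x)
        lS = self.baseline.logsf(x)
        lh = self.baseline.logpdf(x)
        with np.errstate(over="ignore", invalid="ignore"):
            dtdx = np.exp(np.log(self.alpha * self.beta) + lh
                          + (self.beta - 1.0) * lH - (self.beta + 1.0) * lS)
            val = self.outer.pdf_fn(np.where(np.isfinite(t), t, 1.0)) * dtdx
        lower, upper = self.support
        outside = (x <= lower) | (x >= upper) | ~np.isfinite(t) | ~np.isfinite(dtdx)
        return np.where(outside, 0.0, val)


def compose(outer: OuterTransformer, baseline: Baseline,
            alpha: float, beta: float) -> ComposedDistribution:
    """Compose an outer transformer with a baseline's exponentiated odds ratio."""
    return ComposedDistribution(outer, baseline, alpha, beta)


def composed_cdf_grid_check(composed: ComposedDistribution, n_points: int = 10_000) -> dict:
    """Grid diagnostics: monotonicity violation and limit values of the cdf.

    Returns a dict with the largest negative increment of the cdf over an
    ``n_points`` grid spanning the support, plus the cdf values just inside
    the support endpoints.
    """
    lower, upper = composed.support
    if np.isinf(upper):
        # map the grid through the baseline quantile so it covers the mass
        ps = np.linspace(1e-15, 1.0 - 1e-15, n_points)
        grid = composed.baseline.quantile(ps)
    else:
        eps = (upper - lower) * 1e-9
        grid = np.linspace(lower + eps, upper - eps, n_points)
    vals = composed.cdf(grid)
    increments = np.diff(vals)
    return {
        "max_violation": float(max(0.0, -np.min(increments, initial=0.0))),
        "cdf_at_lower": float(vals[0]),
        "cdf_at_upper": float(vals[-1]),
    }
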