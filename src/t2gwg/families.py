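"""Parametric families available to the estimation front-end.

Each family knows how to build a distribution object from a parameter
vector, how to map parameters to and from an unconstrained optimisation
scale (log transform for positive shapes; data-dependent maps for
support-boundary parameters), and how to pick heuristic starting values.

The lead members are the three T2GWG special cases (exponential, uniform
and Pareto baselines).  The comparison set used in model-selection tables
— exponentiated Gumbel type-2 (EGT), Weibull generalized-exponential
(WGE), Lomax Gumbel type-2 (LGT), Type 2 Gumbel (T2G), Weibull and gamma
— is implemented as fit targets only, from the standard literature forms.
"""

from __future__ import annotations

import abc
from typing import Dict, Type

import numpy as np
from scipy import special, stats

from .baselines import Exponential, Pareto, Uniform
from .core import T2GWG

__all__ = ["Family", "get_family", "FAMILY_REGISTRY", "register_family"]

# Relative guard for support-boundary parameters (T2GWU gamma > max(x),
# T2GWP theta < min(x)).  For beta < 1 the T2GWU likelihood is unbounded as
# gamma approaches the sample maximum, so the guard sets the resolution of
# boundary estimates; 1e-12 keeps (gamma - x_max)/gamma exactly
# representable in double precision.
_BOUND_EPS = 1e-12


class Family(abc.ABC):
    name: str = ""
    param_names: tuple = ()
    #: whether make() returns an object with analytic parameter gradients
    analytic_grad: bool = False

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @abc.abstractmethod
    def make(self, params: np.ndarray):
        """Build a distribution exposing cdf/logpdf (and grads if analytic)."""

    @abc.abstractmethod
    def init_params(self, data: np.ndarray) -> np.ndarray:
        ...

    # -- unconstrained reparameterisation (default: elementwise log) ---------
    def to_eta(self, params: np.ndarray, data: np.ndarray) -> np.ndarray:
        return np.log(np.asarray(params, dtype=float))

    def from_eta(self, eta: np.ndarray, data: np.ndarray) -> np.ndarray:
        return np.exp(np.asarray(eta, dtype=float))

    def eta_jacobian(self, eta: np.ndarray, data: np.ndarray) -> np.ndarray:
        """Diagonal of d(params)/d(eta) at eta."""
        return np.exp(np.asarray(eta, dtype=float))


# --------------------------------------------------------------------------
# T2GWG special cases
# --------------------------------------------------------------------------

class T2GWEFamily(Family):
    """T2GW-exponential: params (alpha, beta, gamma), support (0, inf)."""

    name = "t2gwe"
    param_names = ("alpha", "beta", "gamma")
    analytic_grad = True

    def make(self, params):
        a, b, g = params
        return T2GWG(a, b, Exponential(g))

    def init_params(self, data):
        # gamma ~ 1/mean is the exponential-rate heuristic; unit shapes
        return np.array([1.0, 1.0, 1.0 / float(np.mean(data))])


class T2GWUFamily(Family):
    """T2GW-uniform: gamma is the upper support bound, constrained above max(x).

    Real fits place gamma at (or numerically on) the sample maximum, so it
    is parameterised as gamma = M*(1 + exp(eta)) with M just above max(x).
    """

    name = "t2gwu"
    param_names = ("alpha", "beta", "gamma")
    analytic_grad = True

    @staticmethod
    def _bound(data):
        return float(np.max(data)) * (1.0 + _BOUND_EPS)

    def make(self, params):
        a, b, g = params
        return T2GWG(a, b, Uniform(g))

    def init_params(self, data):
        return np.array([1.0, 1.0, self._bound(data) * 1.5])

    def to_eta(self, params, data):
        params = np.asarray(params, dtype=float)
        M = self._bound(data)
        if params[2] <= M:
            raise ValueError("t2gwu gamma must exceed the sample maximum")
        return np.array([np.log(params[0]), np.log(params[1]),
                         np.log(params[2] / M - 1.0)])

    def from_eta(self, eta, data):
        eta = np.asarray(eta, dtype=float)
        M = self._bound(data)
        return np.array([np.exp(eta[0]), np.exp(eta[1]),
                         M * (1.0 + np.exp(np.minimum(eta[2], 700.0)))])

    def eta_jacobian(self, eta, data):
        eta = np.asarray(eta, dtype=float)
        M = self._bound(data)
        return np.array([np.exp(eta[0]), np.exp(eta[1]),
                         M * np.exp(np.minimum(eta[2], 700.0))])


class T2GWPFamily(Family):
    """T2GW-Pareto: theta is the lower support bound, constrained below min(x)."""

    name = "t2gwp"
    param_names = ("alpha", "beta", "theta", "k")
    analytic_grad = True

    @staticmethod
    def _bound(data):
        return float(np.min(data)) * (1.0 - _BOUND_EPS)

    def make(self, params):
        a, b, th, k = params
        return T2GWG(a, b, Pareto(th, k))

    def init_params(self, data):
        return np.array([1.0, 1.0, self._bound(data) * 0.9, 1.0])

    def to_eta(self, params, data):
        params = np.asarray(params, dtype=float)
        m = self._bound(data)
        if not (0.0 < params[2] < m):
            raise ValueError("t2gwp theta must lie in (0, min(data))")
        return np.array([np.log(params[0]), np.log(params[1]),
                         special.logit(params[2] / m), np.log(params[3])])

    def from_eta(self, eta, data):
        eta = np.asarray(eta, dtype=float)
        m = self._bound(data)
        return np.array([np.exp(eta[0]), np.exp(eta[1]),
                         m * special.expit(eta[2]), np.exp(eta[3])])

    def eta_jacobian(self, eta, data):
        eta = np.asarray(eta, dtype=float)
        m = self._bound(data)
        s = special.expit(eta[2])
        return np.array([np.exp(eta[0]), np.exp(eta[1]),
                         m * s * (1.0 - s), np.exp(eta[3])])


# --------------------------------------------------------------------------
# comparison families (fit targets only; no analytic parameter gradients)
# --------------------------------------------------------------------------

class _SimpleDist:
    """cdf/logpdf pair for a gradient-free fit target."""

    def __init__(self, cdf, logpdf, support=(0.0, np.inf)):
        self._cdf = cdf
        self._logpdf = logpdf
        self.support = support

    def cdf(self, x):
        return self._cdf(np.asarray(x, dtype=float))

    def logpdf(self, x):
        return self._logpdf(np.asarray(x, dtype=float))

    def pdf(self, x):
        return np.exp(self.logpdf(x))


class WeibullFamily(Family):
    """Weibull(k, lam): F = 1 - exp(-(x/lam)^k)."""

    name = "weibull"
    param_names = ("k", "lam")

    def make(self, params):
        k, lam = params
        if k <= 0 or lam <= 0:
            raise ValueError("weibull parameters must be positive")

        def cdf(x):
            return np.where(x > 0, -np.expm1(-np.power(np.maximum(x, 0) / lam, k)), 0.0)

        def logpdf(x):
            xs = np.maximum(x, 1e-320)
            return np.where(x > 0, np.log(k / lam) + (k - 1) * np.log(xs / lam)
                            - np.power(xs / lam, k), -np.inf)

        return _SimpleDist(cdf, logpdf)

    def init_params(self, data):
        m = float(np.mean(data))
        cv = float(np.std(data)) / m if m > 0 else 1.0
        k0 = np.clip(cv, 0.1, 10.0) ** -1.086  # Justus moment approximation
        return np.array([k0, m])


class GammaFamily(Family):
    """Gamma(a, b) with rate b: f = b^a x^(a-1) e^(-b x) / Gamma(a)."""

    name = "gamma"
    param_names = ("a", "b")

    def make(self, params):
        a, b = params
        if a <= 0 or b <= 0:
            raise ValueError("gamma parameters must be positive")
        frozen = stats.gamma(a, scale=1.0 / b)
        return _SimpleDist(frozen.cdf, frozen.logpdf)

    def init_params(self, data):
        m, v = float(np.mean(data)), float(np.var(data))
        v = max(v, 1e-12)
        return np.array([max(m * m / v, 1e-3), max(m / v, 1e-6)])


class T2GFamily(Family):
    """Type 2 Gumbel(a, nu): F = exp(-a * x^(-nu))."""

    name = "t2g"
    param_names = ("a", "nu")

    def make(self, params):
        a, nu = params
        if a <= 0 or nu <= 0:
            raise ValueError("t2g parameters must be positive")

        def cdf(x):
            xs = np.maximum(x, 1e-320)
            with np.errstate(over="ignore"):
                return np.where(x > 0, np.exp(-a * np.power(xs, -nu)), 0.0)

        def logpdf(x):
            xs = np.maximum(x, 1e-320)
            return np.where(x > 0, np.log(a * nu) - (nu + 1) * np.log(xs)
                            - a * np.power(xs, -nu), -np.inf)

        return _SimpleDist(cdf, logpdf)

    def init_params(self, data):
        med = float(np.median(data))
        nu0 = 1.0
        return np.array([np.log(2.0) * med**nu0, nu0])


class EGTFamily(Family):
    """Exponentiated Gumbel type-2 (a, phi, theta): F = 1 - (1 - e^(-a x^-phi))^theta."""

    name = "egt"
    param_names = ("a", "phi", "theta")

    def make(self, params):
        a, phi, theta = params
        if min(a, phi, theta) <= 0:
            raise ValueError("egt parameters must be positive")

        def _g(x):  # Gumbel type-2 cdf e^(-a x^-phi)
            xs = np.maximum(x, 1e-320)
            with np.errstate(over="ignore"):
                return np.where(x > 0, np.exp(-a * np.power(xs, -phi)), 0.0)

        def cdf(x):
            return np.where(x > 0, -np.expm1(theta * np.log1p(-_g(x))), 0.0)

        def logpdf(x):
            xs = np.maximum(x, 1e-320)
            g = _g(x)
            with np.errstate(divide="ignore", invalid="ignore"):
                return np.where(
                    (x > 0) & (g > 0) & (g < 1),
                    np.log(theta * a * phi) - (phi + 1) * np.log(xs)
                    - a * np.power(xs, -phi) + (theta - 1) * np.log1p(-g),
                    -np.inf)

        return _SimpleDist(cdf, logpdf)

    def init_params(self, data):
        med = float(np.median(data))
        return np.array([med, 1.0, 1.0])


class WGEFamily(Family):
    """Weibull generalized-exponential (a, theta, gamma).

    Weibull-G composition (unit Weibull shape) over a generalized
    exponential driver G = (1 - e^(-gamma x))^theta:
        F = 1 - exp(-a * G/(1-G)).
    """

    name = "wge"
    param_names = ("a", "theta", "gamma")

    def make(self, params):
        a, theta, gamma = params
        if min(a, theta, gamma) <= 0:
            raise ValueError("wge parameters must be positive")

        def _logG(x):
            xs = np.maximum(x, 1e-320)
            with np.errstate(divide="ignore"):
                return theta * np.log(-np.expm1(-gamma * xs))

        def cdf(x):
            lg = _logG(x)
            G = np.exp(lg)
            odds = np.where(G < 1.0, G / np.maximum(1.0 - G, 1e-320), np.inf)
            return np.where(x > 0, np.where(np.isfinite(odds), -np.expm1(-a * odds), 1.0), 0.0)

        def logpdf(x):
            xs = np.maximum(x, 1e-320)
            lg = _logG(x)
            G = np.exp(lg)
            one_m = np.maximum(1.0 - G, 1e-320)
            # g = theta*gamma*e^(-gamma x)*(1-e^(-gamma x))^(theta-1)
            log_g = (np.log(theta * gamma) - gamma * xs
                     + (theta - 1.0) * np.log(-np.expm1(-gamma * xs)))
            return np.where(x > 0, np.log(a) + log_g - 2.0 * np.log(one_m)
                            - a * G / one_m, -np.inf)

        return _SimpleDist(cdf, logpdf)

    def init_params(self, data):
        return np.array([1.0, 1.0, 1.0 / float(np.mean(data))])


class LGTFamily(Family):
    """Lomax Gumbel type-2 (a, b, theta, k).

    Lomax outer over the odds of a Gumbel type-2 driver P = e^(-theta x^-k):
        F = 1 - (1 + a * P/(1-P))^(-b).
    """

    name = "lgt"
    param_names = ("a", "b", "theta", "k")

    def make(self, params):
        a, b, theta, k = params
        if min(a, b, theta, k) <= 0:
            raise ValueError("lgt parameters must be positive")

        def _P(x):
            xs = np.maximum(x, 1e-320)
            with np.errstate(over="ignore"):
                return np.where(x > 0, np.exp(-theta * np.power(xs, -k)), 0.0)

        def cdf(x):
            P = _P(x)
            odds = np.where(P < 1.0, P / np.maximum(1.0 - P, 1e-320), np.inf)
            out = np.where(np.isfinite(odds), -np.expm1(-b * np.log1p(a * odds)), 1.0)
            return np.where(x > 0, out, 0.0)

        def logpdf(x):
            xs = np.maximum(x, 1e-320)
            P = _P(x)
            one_m = np.maximum(1.0 - P, 1e-320)
            odds = P / one_m
            # dP/dx = theta*k*x^(-k-1)*P ; d(odds)/dx = dP/dx / (1-P)^2
            log_dodds = (np.log(theta * k) - (k + 1) * np.log(xs) + np.log(np.maximum(P, 1e-320))
                         - 2.0 * np.log(one_m))
            return np.where((x > 0) & (P > 0) & (P < 1),
                            np.log(a * b) - (b + 1.0) * np.log1p(a * odds) + log_dodds,
                            -np.inf)

        return _SimpleDist(cdf, logpdf)

    def init_params(self, data):
        med = float(np.median(data))
        return np.array([1.0, 1.0, med, 1.0])


FAMILY_REGISTRY: Dict[str, Family] = {}


def register_family(family: Family) -> Family:
    FAMILY_REGISTRY[family.name] = family
    return family


for _fam in (T2GWEFamily(), T2GWUFamily(), T2GWPFamily(), WeibullFamily(),
             GammaFamily(), T2GFamily(), EGTFamily(), WGEFamily(), LGTFamily()):
    register_family(_fam)


def get_family(name: str) -> Family:
    try:
        return FAMILY_REGISTRY[name]
    except KeyError:
        valid = ", ".join(sorted(FAMILY_REGISTRY))
        raise ValueError(f"unknown family {name!r}; valid choices: {valid}") from None
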