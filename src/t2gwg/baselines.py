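"""Baseline lifetime distributions H(x, psi) used as inner drivers.

The odds-ratio generator is baseline-agnostic: any distribution exposing a
cdf ``H``, density ``h``, survival function, quantile, and parameter
gradients can drive it.  Three baselines are built in — exponential,
uniform on (0, gamma), and Pareto — and further ones can be registered at
run time with :func:`register_baseline`.

Survival functions are evaluated in their closed form (``exp(-gamma*x)``,
``(theta/x)**k``, ...) rather than as ``1 - H`` so that the deep right tail
keeps full relative precision.
"""

from __future__ import annotations

import abc
from typing import Callable, Dict, Type

import numpy as np

__all__ = [
    "Baseline",
    "Exponential",
    "Uniform",
    "Pareto",
    "get_baseline",
    "register_baseline",
    "BASELINE_REGISTRY",
]


def _check_positive(**params: float) -> None:
    for name, value in params.items():
        if not np.isfinite(value) or value <= 0:
            raise ValueError(f"baseline parameter {name!r} must be a positive finite "
                             f"number, got {value!r}")


class Baseline(abc.ABC):
    """A baseline distribution H(x, psi) on a (half-open) interval support.

    Subclasses provide vectorised cdf/pdf/survival/quantile plus the
    parameter gradients ``cdf_param_grad`` and ``pdf_param_grad`` required
    by every estimation criterion.
    """

    name: str = ""
    param_names: tuple = ()

    #: support as (lower, upper); upper may be ``np.inf``
    @property
    @abc.abstractmethod
    def support(self) -> tuple:
        ...

    @property
    def params(self) -> np.ndarray:
        return np.array([getattr(self, p) for p in self.param_names], dtype=float)

    def with_params(self, psi) -> "Baseline":
        """Return a copy of this baseline with parameter vector ``psi``."""
        psi = np.atleast_1d(np.asarray(psi, dtype=float))
        if psi.shape != (len(self.param_names),):
            raise ValueError(f"{self.name} baseline expects {len(self.param_names)} "
                             f"parameters, got {psi.shape}")
        return type(self)(*psi)

    # -- distribution surface ------------------------------------------------
    @abc.abstractmethod
    def cdf(self, x):
        ...

    @abc.abstractmethod
    def pdf(self, x):
        ...

    @abc.abstractmethod
    def sf(self, x):
        """Survival function, computed from its closed form."""

    @abc.abstractmethod
    def logcdf(self, x):
        ...

    @abc.abstractmethod
    def logsf(self, x):
        ...

    @abc.abstractmethod
    def logpdf(self, x):
        ...

    @abc.abstractmethod
    def quantile(self, p):
        ...

    # -- parameter derivatives ----------------------------------------------
    @abc.abstractmethod
    def cdf_param_grad(self, x) -> np.ndarray:
        """dH/dpsi_k, shape ``(n_params,) + x.shape``; zero off-support."""

    @abc.abstractmethod
    def pdf_param_grad(self, x) -> np.ndarray:
        """dh/dpsi_k, same shape convention as :meth:`cdf_param_grad`."""

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        ps = ", ".join(f"{k}={getattr(self, k):g}" for k in self.param_names)
        return f"{type(self).__name__}({ps})"


class Exponential(Baseline):
    """Exponential baseline: h(x) = gamma * exp(-gamma*x), support (0, inf)."""

    name = "exponential"
    param_names = ("gamma",)

    def __init__(self, gamma: float):
        _check_positive(gamma=gamma)
        self.gamma = float(gamma)

    @property
    def support(self):
        return (0.0, np.inf)

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        return np.where(x > 0, -np.expm1(-self.gamma * np.maximum(x, 0.0)), 0.0)

    def sf(self, x):
        x = np.asarray(x, dtype=float)
        return np.where(x > 0, np.exp(-self.gamma * np.maximum(x, 0.0)), 1.0)

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        return np.where(x > 0, self.gamma * np.exp(-self.gamma * np.maximum(x, 0.0)), 0.0)

    def logcdf(self, x):
        x = np.asarray(x, dtype=float)
        with np.errstate(divide="ignore"):
            return np.where(x > 0,
                            np.log(-np.expm1(-self.gamma * np.maximum(x, 1e-320))),
                            -np.inf)

    def logsf(self, x):
        x = np.asarray(x, dtype=float)
        return np.where(x > 0, -self.gamma * x, 0.0)

    def logpdf(self, x):
        x = np.asarray(x, dtype=float)
        return np.where(x > 0, np.log(self.gamma) - self.gamma * x, -np.inf)

    def quantile(self, p):
        p = np.asarray(p, dtype=float)
        if np.any((p <= 0) | (p >= 1)):
            raise ValueError("quantile argument must lie strictly in (0, 1)")
        return -np.log1p(-p) / self.gamma

    def cdf_param_grad(self, x):
        x = np.asarray(x, dtype=float)
        g = np.where(x > 0, x * np.exp(-self.gamma * np.maximum(x, 0.0)), 0.0)
        return g[np.newaxis, ...]

    def pdf_param_grad(self, x):
        x = np.asarray(x, dtype=float)
        e = np.exp(-self.gamma * np.maximum(x, 0.0))
        g = np.where(x > 0, e * (1.0 - self.gamma * x), 0.0)
        return g[np.newaxis, ...]


class Uniform(Baseline):
    """Uniform baseline on (0, gamma): h = 1/gamma, H = x/gamma.

    The survival function vanishes at x = gamma, so the composed lifetime
    distribution has bounded support; the cdf clamps to 1 at x >= gamma.
    """

    name = "uniform"
    param_names = ("gamma",)

    def __init__(self, gamma: float):
        _check_positive(gamma=gamma)
        self.gamma = float(gamma)

    @property
    def support(self):
        return (0.0, self.gamma)

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        return np.clip(x / self.gamma, 0.0, 1.0)

    def sf(self, x):
        x = np.asarray(x, dtype=float)
        return np.clip((self.gamma - x) / self.gamma, 0.0, 1.0)

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        return np.where((x > 0) & (x < self.gamma), 1.0 / self.gamma, 0.0)

    def logcdf(self, x):
        with np.errstate(divide="ignore"):
            return np.log(self.cdf(x))

    def logsf(self, x):
        with np.errstate(divide="ignore"):
            return np.log(self.sf(x))

    def logpdf(self, x):
        x = np.asarray(x, dtype=float)
        return np.where((x > 0) & (x < self.gamma), -np.log(self.gamma), -np.inf)

    def quantile(self, p):
        p = np.asarray(p, dtype=float)
        if np.any((p <= 0) | (p >= 1)):
            raise ValueError("quantile argument must lie strictly in (0, 1)")
        return p * self.gamma

    def cdf_param_grad(self, x):
        x = np.asarray(x, dtype=float)
        g = np.where((x > 0) & (x < self.gamma), -x / self.gamma**2, 0.0)
        return g[np.newaxis, ...]

    def pdf_param_grad(self, x):
        x = np.asarray(x, dtype=float)
        g = np.where((x > 0) & (x < self.gamma), -1.0 / self.gamma**2, 0.0)
        return g[np.newaxis, ...]


class Pareto(Baseline):
    """Pareto baseline: H(x) = 1 - (theta/x)^k on (theta, inf)."""

    name = "pareto"
    param_names = ("theta", "k")

    def __init__(self, theta: float, k: float):
        _check_positive(theta=theta, k=k)
        self.theta = float(theta)
        self.k = float(k)

    @property
    def support(self):
        return (self.theta, np.inf)

    def _ratio_pow(self, x):
        # (theta/x)^k, safe for x <= theta
        x = np.asarray(x, dtype=float)
        return np.exp(self.k * (np.log(self.theta) - np.log(np.maximum(x, self.theta))))

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        return np.where(x > self.theta, -np.expm1(self.k * (np.log(self.theta) -
                        np.log(np.maximum(x, self.theta)))), 0.0)

    def sf(self, x):
        x = np.asarray(x, dtype=float)
        return np.where(x > self.theta, self._ratio_pow(x), 1.0)

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        return np.where(x > self.theta, self.k * self._ratio_pow(x) / np.maximum(x, self.theta), 0.0)

    def logcdf(self, x):
        with np.errstate(divide="ignore"):
            return np.log(self.cdf(x))

    def logsf(self, x):
        x = np.asarray(x, dtype=float)
        return np.where(x > self.theta,
                        self.k * (np.log(self.theta) - np.log(np.maximum(x, self.theta))),
                        0.0)

    def logpdf(self, x):
        x = np.asarray(x, dtype=float)
        xs = np.maximum(x, self.theta)
        return np.where(x > self.theta,
                        np.log(self.k) + self.k * np.log(self.theta) - (self.k + 1) * np.log(xs),
                        -np.inf)

    def quantile(self, p):
        p = np.asarray(p, dtype=float)
        if np.any((p <= 0) | (p >= 1)):
            raise ValueError("quantile argument must lie strictly in (0, 1)")
        return self.theta * np.exp(-np.log1p(-p) / self.k)

    def cdf_param_grad(self, x):
        x = np.asarray(x, dtype=float)
        inside = x > self.theta
        r = self._ratio_pow(x)
        logr = np.log(self.theta) - np.log(np.maximum(x, self.theta))
        d_theta = np.where(inside, -self.k * r / self.theta, 0.0)
        d_k = np.where(inside, -r * logr, 0.0)
        return np.stack([d_theta, d_k])

    def pdf_param_grad(self, x):
        x = np.asarray(x, dtype=float)
        inside = x > self.theta
        xs = np.maximum(x, self.theta)
        h = self.k * self._ratio_pow(x) / xs
        logr = np.log(self.theta) - np.log(xs)
        d_theta = np.where(inside, h * self.k / self.theta, 0.0)
        d_k = np.where(inside, h * (1.0 / self.k + logr), 0.0)
        return np.stack([d_theta, d_k])


BASELINE_REGISTRY: Dict[str, Type[Baseline]] = {}


def register_baseline(cls: Type[Baseline]) -> Type[Baseline]:
    """Register a :class:`Baseline` subclass under its ``name``."""
    if not cls.name:
        raise ValueError("baseline class must define a non-empty 'name'")
    BASELINE_REGISTRY[cls.name] = cls
    return cls


for _cls in (Exponential, Uniform, Pareto):
    register_baseline(_cls)


def get_baseline(name: str, *psi: float) -> Baseline:
    """Construct a registered baseline by name with positional parameters."""
    try:
        cls = BASELINE_REGISTRY[name]
    except KeyError:
        valid = ", ".join(sorted(BASELINE_REGISTRY))
        raise ValueError(f"unknown baseline {name!r}; valid choices: {valid}") from None
    return cls(*psi)
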