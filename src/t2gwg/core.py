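"""The Type 2 Gumbel Weibull-G (T2GWG) distribution surface.

A T2GWG lifetime distribution applies the Type 2 Gumbel cdf to the
exponentiated odds ratio of a baseline H::

    F(x) = exp( -alpha * (H(x)/Hbar(x))**(-beta) ),   alpha, beta > 0

where ``Hbar = 1 - H`` is the baseline survival function.  The density,
hazard, reverse hazard, quantile and sampling routines are all expressed
through the log odds ratio ``log H - log Hbar`` so that both tails keep
full floating-point precision.

Differentiating F gives

    f(x) = alpha*beta * h(x) * H(x)**(-beta-1) * Hbar(x)**(beta-1) * F(x)

(the exponent on the survival factor is ``beta - 1``: this is the unique
sign choice for which f = dF/dx, and it matches the log-likelihood term
``(beta - 1) * sum(log(1 - H))`` used by the estimators).
"""

from __future__ import annotations

from typing import Optional, Union

import numpy as np

from .baselines import Baseline, Exponential, Pareto, Uniform, get_baseline

__all__ = ["T2GWG", "t2gwe", "t2gwu", "t2gwp"]


class T2GWG:
    """A concrete member of the T2GWG family: shapes (alpha, beta) + baseline.

    Parameters
    ----------
    alpha, beta : float
        Positive shape parameters.  ``alpha`` controls the usual stochastic
        order (larger alpha -> stochastically larger lifetimes); ``beta``
        controls tail weight.
    baseline : Baseline
        The inner driver H(x, psi).  The support of the composed
        distribution equals the baseline support.
    """

    def __init__(self, alpha: float, beta: float, baseline: Baseline):
        if not np.isfinite(alpha) or alpha <= 0:
            raise ValueError(f"alpha must be positive and finite, got {alpha!r}")
        if not np.isfinite(beta) or beta <= 0:
            raise ValueError(f"beta must be positive and finite, got {beta!r}")
        self.alpha = float(alpha)
        self.beta = float(beta)
        self.baseline = baseline

    @property
    def support(self) -> tuple:
        return self.baseline.support

    @property
    def params(self) -> np.ndarray:
        """(alpha, beta, psi...) as a flat vector."""
        return np.concatenate([[self.alpha, self.beta], self.baseline.params])

    def with_params(self, delta) -> "T2GWG":
        delta = np.asarray(delta, dtype=float)
        return T2GWG(delta[0], delta[1], self.baseline.with_params(delta[2:]))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"T2GWG(alpha={self.alpha:g}, beta={self.beta:g}, baseline={self.baseline!r})"

    # -- odds ratio ----------------------------------------------------------
    def log_odds(self, x) -> np.ndarray:
        """log(H/Hbar); -inf below the support, +inf at/above an upper bound."""
        return self.baseline.logcdf(x) - self.baseline.logsf(x)

    # -- distribution surface -------------------------------------------------
    def logcdf(self, x) -> np.ndarray:
        # -alpha * exp(-beta * log_odds); the limits are handled by the
        # log-odds infinities (exp(-inf) = 0, exp(+inf) overflows to +inf).
        lo = self.log_odds(x)
        with np.errstate(over="ignore"):
            return -self.alpha * np.exp(-self.beta * lo)

    def cdf(self, x) -> np.ndarray:
        return np.exp(self.logcdf(x))

    def sf(self, x) -> np.ndarray:
        # 1 - exp(logcdf), accurate when the cdf is close to 1
        return -np.expm1(self.logcdf(x))

    def logpdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        lH = self.baseline.logcdf(x)
        lS = self.baseline.logsf(x)
        lh = self.baseline.logpdf(x)
        with np.errstate(over="ignore", invalid="ignore"):
            val = (np.log(self.alpha) + np.log(self.beta) + lh
                   - (self.beta + 1.0) * lH + (self.beta - 1.0) * lS
                   - self.alpha * np.exp(-self.beta * (lH - lS)))
        lower, upper = self.support
        outside = (x <= lower) | (x >= upper)
        return np.where(outside | ~np.isfinite(lh), -np.inf, val)

    def pdf(self, x) -> np.ndarray:
        return np.exp(self.logpdf(x))

    def hazard(self, x) -> np.ndarray:
        """Hazard rate f/(1-F); +inf where the cdf has reached 1."""
        lp = self.logpdf(x)
        s = self.sf(x)
        with np.errstate(divide="ignore", over="ignore"):
            out = np.exp(lp - np.log(np.where(s > 0, s, np.nan)))
        return np.where(s > 0, out, np.where(np.isfinite(lp), np.inf, 0.0))

    def reverse_hazard(self, x) -> np.ndarray:
        """Reverse hazard f/F = alpha*beta*h*H^(-beta-1)*Hbar^(beta-1).

        The exponential factor cancels between numerator and denominator,
        so this is evaluated without it.
        """
        x = np.asarray(x, dtype=float)
        lH = self.baseline.logcdf(x)
        lS = self.baseline.logsf(x)
        lh = self.baseline.logpdf(x)
        with np.errstate(over="ignore", invalid="ignore"):
            val = np.exp(np.log(self.alpha) + np.log(self.beta) + lh
                         - (self.beta + 1.0) * lH + (self.beta - 1.0) * lS)
        lower, upper = self.support
        outside = (x <= lower) | (x >= upper)
        return np.where(outside, 0.0, val)

    def quantile(self, p) -> np.ndarray:
        """Inverse cdf: solve H(x) = 1 / (1 + (-log(p)/alpha)**(1/beta))."""
        p = np.asarray(p, dtype=float)
        if np.any((p <= 0) | (p >= 1)):
            raise ValueError("quantile argument must lie strictly in (0, 1)")
        t = np.power(-np.log(p) / self.alpha, 1.0 / self.beta)
        q = 1.0 / (1.0 + t)
        # p within one ulp of 1 makes q round to exactly 1; keep it interior
        q = np.clip(q, np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0))
        return self.baseline.quantile(q)

    ppf = quantile  # scipy-flavoured alias

    def rvs(self, n: int, seed: Optional[Union[int, np.random.Generator]] = None) -> np.ndarray:
        """Draw ``n`` i.i.d. lifetimes by inverse-transform sampling."""
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = np.random.default_rng(seed)
        u = rng.uniform(size=int(n))
        # keep strictly inside (0, 1); the generator can emit exact 0.0
        u = np.clip(u, np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0))
        return self.quantile(u)

    # -- parameter derivatives (used by every estimation criterion) -----------
    def cdf_param_grad(self, x) -> np.ndarray:
        """dF/d(alpha, beta, psi...), shape ``(2 + n_psi,) + x.shape``.

        With t = H/Hbar:
            dF/dalpha = -t^(-beta) F
            dF/dbeta  =  alpha * log(t) * t^(-beta) * F
            dF/dpsi_k =  alpha*beta * H^(-beta-1) Hbar^(beta-1) * dH/dpsi_k * F
        """
        x = np.asarray(x, dtype=float)
        lH = self.baseline.logcdf(x)
        lS = self.baseline.logsf(x)
        lo = lH - lS
        with np.errstate(over="ignore", invalid="ignore"):
            tmb = np.exp(-self.beta * lo)                      # t^(-beta)
            F = np.exp(-self.alpha * tmb)
            dF_da = -tmb * F
            dF_db = self.alpha * lo * tmb * F
            kern = np.exp(np.log(self.alpha) + np.log(self.beta)
                          - (self.beta + 1.0) * lH + (self.beta - 1.0) * lS) * F
        dH = self.baseline.cdf_param_grad(x)
        with np.errstate(invalid="ignore", over="ignore"):
            grads = [dF_da, dF_db] + [kern * dH[i] for i in range(dH.shape[0])]
        out = np.stack([np.where(np.isfinite(g), g, 0.0) for g in grads])
        lower, upper = self.support
        outside = (x <= lower) | (x >= upper)
        return np.where(outside, 0.0, out)

    def logpdf_param_grad(self, x) -> np.ndarray:
        """d(log f)/d(alpha, beta, psi...) at interior points.

        dl/dalpha = 1/alpha - t^(-beta)
        dl/dbeta  = 1/beta - log H + log Hbar + alpha * t^(-beta) * log t
        dl/dpsi_k = h'/h - (beta+1) H'/H - (beta-1) H'/Hbar * (-1)
                    + alpha*beta H^(-beta-1) Hbar^(beta-1) H'
        """
        x = np.asarray(x, dtype=float)
        lH = self.baseline.logcdf(x)
        lS = self.baseline.logsf(x)
        lo = lH - lS
        with np.errstate(over="ignore", invalid="ignore"):
            tmb = np.exp(-self.beta * lo)
            d_da = 1.0 / self.alpha - tmb
            d_db = 1.0 / self.beta - lH + lS + self.alpha * tmb * lo
            kern = np.exp(np.log(self.alpha) + np.log(self.beta)
                          - (self.beta + 1.0) * lH + (self.beta - 1.0) * lS)
        H = np.exp(lH)
        S = np.exp(lS)
        h = self.baseline.pdf(x)
        dH = self.baseline.cdf_param_grad(x)
        dh = self.baseline.pdf_param_grad(x)
        grads = [d_da, d_db]
        with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
            for i in range(dH.shape[0]):
                grads.append(dh[i] / h - (self.beta + 1.0) * dH[i] / H
                             - (self.beta - 1.0) * dH[i] / S + kern * dH[i])
        return np.stack(grads)


def t2gwe(alpha: float, beta: float, gamma: float) -> T2GWG:
    """Type 2 Gumbel Weibull-exponential: F(x) = exp(-alpha*(e^(gamma x)-1)^(-beta))."""
    return T2GWG(alpha, beta, Exponential(gamma))


def t2gwu(alpha: float, beta: float, gamma: float) -> T2GWG:
    """Type 2 Gumbel Weibull-uniform: F(x) = exp(-alpha*(x/(gamma-x))^(-beta)) on (0, gamma)."""
    return T2GWG(alpha, beta, Uniform(gamma))


def t2gwp(alpha: float, beta: float, theta: float, k: float) -> T2GWG:
    """Type 2 Gumbel Weibull-Pareto: F(x) = exp(-alpha*((x/theta)^k - 1)^(-beta)) on (theta, inf)."""
    return T2GWG(alpha, beta, Pareto(theta, k))
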