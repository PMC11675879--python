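"""Goodness of fit, information criteria, model comparison, diagnostics.

Covers the statistics used in lifetime model-comparison tables
(-2logL, AIC/BIC/CAIC/HQIC, Cramer-von Mises W, Anderson-Darling A,
Kolmogorov-Smirnov with asymptotic p-value) plus the scaled total time
on test (TTT), Kaplan-Meier and empirical cdf diagnostics.

Conventions: CAIC is the small-sample corrected AIC,
AIC + 2k(k+1)/(n-k-1).  W and A are reported raw; the small-sample
modified versions W* = W (1 + 0.5/n) and A* = A (1 + 0.75/n + 2.25/n^2)
are also computed and the report records which convention a field holds.
The K-S p-value uses the asymptotic Kolmogorov distribution of sqrt(n) D
with no parameter-estimation correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimation import FitResult, fit, nll
from .families import get_family

__all__ = [
    "InformationCriteria",
    "information_criteria",
    "ks_test",
    "cvm_stat",
    "ad_stat",
    "cvm_stat_modified",
    "ad_stat_modified",
    "GofReport",
    "gof_report",
    "StepFunction",
    "ecdf",
    "km_curve",
    "ttt_scaled",
    "compare_models",
]


class InformationCriteria(NamedTuple):
    aic: float
    bic: float
    caic: float
    hqic: float


def information_criteria(neg2logl: float, k: int, n: int) -> InformationCriteria:
    """AIC/BIC/CAIC/HQIC from -2logL, parameter count k and sample size n.

    CAIC (corrected AIC) is undefined for n <= k + 1 and returned as NaN.
    """
    aic = neg2logl + 2.0 * k
    bic = neg2logl + k * np.log(n)
    hqic = neg2logl + 2.0 * k * np.log(np.log(n))
    if n > k + 1:
        caic = aic + 2.0 * k * (k + 1.0) / (n - k - 1.0)
    else:
        caic = np.nan
    return InformationCriteria(aic=aic, bic=bic, caic=caic, hqic=hqic)


def _sorted_u(data, fitted_cdf) -> np.ndarray:
    x = np.sort(np.asarray(data, dtype=float).ravel())
    return np.asarray(fitted_cdf(x), dtype=float)


def ks_test(data, fitted_cdf: Callable) -> tuple:
    """One-sample Kolmogorov-Smirnov statistic and asymptotic p-value.

    D = max_i max(i/n - u_(i), u_(i) - (i-1)/n); p from the Kolmogorov
    distribution of sqrt(n) * D.
    """
    u = _sorted_u(data, fitted_cdf)
    n = len(u)
    i = np.arange(1, n + 1)
    d = float(np.max(np.maximum(i / n - u, u - (i - 1) / n)))
    d = max(d, 0.0)
    p = float(stats.kstwobign.sf(np.sqrt(n) * d)) if d > 0 else 1.0
    return d, min(max(p, 0.0), 1.0)


def cvm_stat(data, fitted_cdf: Callable) -> float:
    """Raw Cramer-von Mises statistic W = 1/(12n) + sum (u_(i) - (2i-1)/(2n))^2."""
    u = _sorted_u(data, fitted_cdf)
    n = len(u)
    i = np.arange(1, n + 1)
    return float(1.0 / (12.0 * n) + np.sum((u - (2.0 * i - 1.0) / (2.0 * n)) ** 2))


def ad_stat(data, fitted_cdf: Callable) -> float:
    """Raw Anderson-Darling statistic A = -n - (1/n) sum (2i-1)[log u_(i) + log(1-u_(n+1-i))]."""
    u = np.clip(_sorted_u(data, fitted_cdf), 1e-300, 1.0 - 1e-16)
    n = len(u)
    i = np.arange(1, n + 1)
    return float(-n - np.sum((2.0 * i - 1.0) * (np.log(u) + np.log1p(-u[::-1]))) / n)


def cvm_stat_modified(data, fitted_cdf: Callable) -> float:
    """Small-sample modified W* = W (1 + 0.5/n)."""
    n = len(np.asarray(data).ravel())
    return cvm_stat(data, fitted_cdf) * (1.0 + 0.5 / n)


def ad_stat_modified(data, fitted_cdf: Callable) -> float:
    """Small-sample modified A* = A (1 + 0.75/n + 2.25/n^2)."""
    n = len(np.asarray(data).ravel())
    return ad_stat(data, fitted_cdf) * (1.0 + 0.75 / n + 2.25 / n ** 2)


@dataclass(frozen=True)
class GofReport:
    """Goodness-of-fit summary for one fitted model on one dataset.

    ``w_stat`` and ``a_stat`` hold the raw (unmodified) statistics;
    ``statistic_convention`` records that choice.  The modified values are
    available through ``w_stat_modified`` / ``a_stat_modified``.
    """

    neg2logl: float
    w_stat: float
    a_stat: float
    w_stat_modified: float
    a_stat_modified: float
    aic: float
    bic: float
    caic: float
    hqic: float
    ks_stat: float
    ks_pvalue: float
    n: int
    k_params: int
    statistic_convention: str = "raw"


def gof_report(data, fitted_cdf: Callable, neg2logl: float, k_params: int) -> GofReport:
    data = np.asarray(data, dtype=float).ravel()
    n = len(data)
    ic = information_criteria(neg2logl, k_params, n)
    d, p = ks_test(data, fitted_cdf)
    return GofReport(
        neg2logl=float(neg2logl),
        w_stat=cvm_stat(data, fitted_cdf),
        a_stat=ad_stat(data, fitted_cdf),
        w_stat_modified=cvm_stat_modified(data, fitted_cdf),
        a_stat_modified=ad_stat_modified(data, fitted_cdf),
        aic=ic.aic, bic=ic.bic, caic=ic.caic, hqic=ic.hqic,
        ks_stat=d, ks_pvalue=p, n=n, k_params=k_params,
    )


# --------------------------------------------------------------------------
# diagnostics: ECDF, Kaplan-Meier, TTT
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StepFunction:
    """Right-continuous step function with jumps at sorted unique ``x``."""

    x: np.ndarray
    y: np.ndarray
    y0: float  # value left of the first jump

    def __call__(self, q) -> np.ndarray:
        idx = np.searchsorted(self.x, np.asarray(q, dtype=float), side="right")
        vals = np.concatenate([[self.y0], self.y])
        return vals[idx]


def ecdf(data) -> StepFunction:
    """Empirical cdf as a step function."""
    x = np.sort(np.asarray(data, dtype=float).ravel())
    n = len(x)
    xs, counts = np.unique(x, return_counts=True)
    return StepFunction(x=xs, y=np.cumsum(counts) / n, y0=0.0)


def km_curve(data) -> StepFunction:
    """Kaplan-Meier survival curve for fully observed (uncensored) data.

    With no censoring the product-limit estimator collapses to
    1 - ECDF at every step.
    """
    x = np.sort(np.asarray(data, dtype=float).ravel())
    n = len(x)
    xs, deaths = np.unique(x, return_counts=True)
    at_risk = n - np.concatenate([[0], np.cumsum(deaths)[:-1]])
    surv = np.cumprod(1.0 - deaths / at_risk)
    return StepFunction(x=xs, y=surv, y0=1.0)


def ttt_scaled(data) -> tuple:
    """Scaled total time on test transform of a positive sample.

    Returns ``(r, G)`` polyline vertices with r_i = i/n and
    G_i = [sum_{j<=i} x_(j) + (n-i) x_(i)] / sum_j x_(j), prefixed by the
    origin (0, 0).  A convex-then-concave curve about the diagonal flags a
    bathtub hazard; concave alone flags an increasing hazard.
    """
    x = np.sort(np.asarray(data, dtype=float).ravel())
    n = len(x)
    if n < 2:
        raise ValueError("ttt requires n >= 2")
    if np.any(x <= 0):
        raise ValueError("ttt requires strictly positive data")
    csum = np.cumsum(x)
    total = csum[-1]
    i = np.arange(1, n + 1)
    g = (csum + (n - i) * x) / total
    return np.concatenate([[0.0], i / n]), np.concatenate([[0.0], g])


# --------------------------------------------------------------------------
# model comparison
# --------------------------------------------------------------------------

def compare_models(data,
                   families: Sequence[str],
                   method: str = "mle",
                   seed: Optional[int] = None,
                   n_restarts: int = 5) -> pd.DataFrame:
    """Fit several families to one dataset and rank them by AIC.

    Each row carries the parameter estimates (and SEs when available), the
    -2logL evaluated at the fitted parameters, the information criteria,
    and the distance statistics; families whose optimiser did not converge
    are flagged, never dropped.
    """
    if len(families) < 2:
        raise ValueError("compare_models needs at least two families")
    data = np.asarray(data, dtype=float).ravel()
    rows = []
    for name in families:
        fam = get_family(name)
        try:
            result = fit(data, family=name, method=method, seed=seed,
                         n_restarts=n_restarts)
            model = fam.make(result.estimates)
            n2ll = 2.0 * nll(model, data)
            rep = gof_report(data, model.cdf, n2ll, fam.n_params)
            row = {
                "family": name,
                "converged": result.converged,
                "estimates": result.params,
                "se": None if result.se is None else dict(
                    zip(fam.param_names, map(float, result.se))),
                "neg2logl": rep.neg2logl,
                "aic": rep.aic, "caic": rep.caic, "bic": rep.bic,
                "hqic": rep.hqic, "w_stat": rep.w_stat, "a_stat": rep.a_stat,
                "ks_stat": rep.ks_stat, "ks_pvalue": rep.ks_pvalue,
            }
        except (ValueError, FloatingPointError) as exc:
            row = {"family": name, "converged": False, "estimates": None,
                   "se": None, "neg2logl": np.nan, "aic": np.nan,
                   "caic": np.nan, "bic": np.nan, "hqic": np.nan,
                   "w_stat": np.nan, "a_stat": np.nan, "ks_stat": np.nan,
                   "ks_pvalue": np.nan, "error": str(exc)}
        rows.append(row)
    df = pd.DataFrame(rows).sort_values("aic", na_position="last")
    return df.reset_index(drop=True)


def comparison_table_text(df: pd.DataFrame) -> str:
    """Fixed-width text rendering of a comparison table, 4-decimal rounding."""
    cols = ["family", "neg2logl", "aic", "caic", "bic", "hqic",
            "w_stat", "a_stat", "ks_stat", "ks_pvalue"]
    out = df.copy()
    est = ["" if e is None else " ".join(f"{v:.4f}" for v in e.values())
           for e in out["estimates"]]
    out = out[cols]
    out.insert(1, "estimates", est)
    return out.to_string(index=False, float_format=lambda v: f"{v:.4f}")
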