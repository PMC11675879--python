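"""Parameter estimation for T2GWG-type lifetime families.

Six criteria are implemented, all as minimisation objectives over the
model parameter vector Delta = (alpha, beta, psi...):

``mle``
    negative log-likelihood;
``ls`` / ``wls``
    (weighted) least squares between fitted cdf values at the order
    statistics and the plotting positions i/(n+1), with WLS weights
    (n+1)^2 (n+2) / [i (n - i + 1)];
``mps``
    negated mean log spacing of the fitted cdf (maximum product spacing);
``cvm``
    the Cramer-von Mises distance 1/(12 n^2) + (1/n) sum (F_i - (2i-1)/(2n))^2;
``ad``
    the Anderson-Darling distance
    -n - (1/n) sum (2i-1) [log F_(i) + log(1 - F_(n+1-i))].

Analytic gradients are available whenever the family provides parameter
derivatives of its cdf and log-density (the T2GWG special cases do);
comparison families fall back to finite differences.

Optimisation runs on an unconstrained scale (log-transformed positive
parameters; boundary parameters mapped through the family's own
reparameterisation) with a quasi-Newton method, deterministic multistart
and a Nelder-Mead fallback.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import optimize

from .families import Family, get_family

__all__ = [
    "METHODS",
    "FitResult",
    "SpacingSet",
    "nll",
    "score",
    "ls_objective",
    "wls_objective",
    "mps_objective",
    "cvm_objective",
    "ad_objective",
    "fit",
]

METHODS = ("mle", "ls", "wls", "mps", "cvm", "ad")

# clamping bounds for cdf values entering logarithms
_U_LO = 1e-300
_U_HI = 1.0 - 1e-16
_BIG = 1e15


# --------------------------------------------------------------------------
# spacings
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SpacingSet:
    """cdf spacings D_1..D_{n+1} of a sorted sample under a fitted model.

    D_1 = F(x_(1)), D_i = F(x_(i)) - F(x_(i-1)), D_{n+1} = 1 - F(x_(n)).
    Exact ties produce zero spacings; those cells are replaced by the
    density value at the tied point (Cheng-Amin convention), recorded in
    ``tie_mask``.
    """

    x_sorted: np.ndarray
    spacings: np.ndarray
    tie_mask: np.ndarray

    @classmethod
    def from_model(cls, model, x_sorted: np.ndarray) -> "SpacingSet":
        u = np.clip(np.asarray(model.cdf(x_sorted), dtype=float), 0.0, 1.0)
        d = np.empty(len(x_sorted) + 1)
        d[0] = u[0]
        d[1:-1] = np.diff(u)
        d[-1] = 1.0 - u[-1]
        tie = np.zeros(len(d), dtype=bool)
        tie[1:-1] = x_sorted[1:] == x_sorted[:-1]
        if tie.any():
            dens = np.exp(model.logpdf(x_sorted[1:][tie[1:-1]]))
            d[tie] = dens
        return cls(x_sorted=x_sorted, spacings=d, tie_mask=tie)


# --------------------------------------------------------------------------
# objectives (model-level; gradients w.r.t. Delta when requested)
# --------------------------------------------------------------------------

def _sorted(data) -> np.ndarray:
    x = np.asarray(data, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty data")
    if not np.all(np.isfinite(x)):
        raise ValueError("data must be finite")
    return np.sort(x)


def nll(model, data) -> float:
    """Negative log-likelihood; +inf if any datum falls off the support."""
    lp = model.logpdf(np.asarray(data, dtype=float))
    if not np.all(np.isfinite(lp)):
        return np.inf
    return -float(np.sum(lp))


def score(model, data) -> np.ndarray:
    """Gradient of the log-likelihood w.r.t. (alpha, beta, psi...)."""
    g = model.logpdf_param_grad(np.asarray(data, dtype=float))
    return np.sum(g, axis=-1)


def _ls_like(model, x_sorted, weights, targets, want_grad):
    u = np.asarray(model.cdf(x_sorted), dtype=float)
    r = u - targets
    val = float(np.sum(weights * r * r))
    if not want_grad:
        return val, None
    dF = model.cdf_param_grad(x_sorted)
    grad = 2.0 * np.sum(weights * r * dF, axis=-1)
    return val, grad


def ls_objective(model, data, want_grad: bool = False):
    """Least squares vs plotting positions i/(n+1)."""
    x = _sorted(data)
    n = len(x)
    i = np.arange(1, n + 1)
    val, grad = _ls_like(model, x, np.ones(n), i / (n + 1.0), want_grad)
    return (val, grad) if want_grad else val


def wls_objective(model, data, want_grad: bool = False):
    """Weighted least squares with weights (n+1)^2 (n+2) / [i (n-i+1)]."""
    x = _sorted(data)
    n = len(x)
    i = np.arange(1, n + 1)
    w = (n + 1.0) ** 2 * (n + 2.0) / (i * (n - i + 1.0))
    val, grad = _ls_like(model, x, w, i / (n + 1.0), want_grad)
    return (val, grad) if want_grad else val


def cvm_objective(model, data, want_grad: bool = False):
    """Cramer-von Mises distance 1/(12 n^2) + (1/n) sum (F_i - (2i-1)/(2n))^2."""
    x = _sorted(data)
    n = len(x)
    i = np.arange(1, n + 1)
    val, grad = _ls_like(model, x, np.full(n, 1.0 / n), (2.0 * i - 1.0) / (2.0 * n),
                         want_grad)
    val += 1.0 / (12.0 * n * n)
    return (val, grad) if want_grad else val


def ad_objective(model, data, want_grad: bool = False):
    """Anderson-Darling distance of the fitted cdf on the sorted sample.

    AD = -n - (1/n) sum_i [(2i-1) log u_(i) + (2n+1-2i) log(1 - u_(i))]
    with u clamped to [1e-300, 1 - 1e-16] before the logarithms.
    """
    x = _sorted(data)
    n = len(x)
    i = np.arange(1, n + 1)
    u = np.clip(np.asarray(model.cdf(x), dtype=float), _U_LO, _U_HI)
    w1 = 2.0 * i - 1.0
    w2 = 2.0 * n + 1.0 - 2.0 * i
    val = -n - float(np.sum(w1 * np.log(u) + w2 * np.log1p(-u))) / n
    if not want_grad:
        return val
    dF = model.cdf_param_grad(x)
    grad = -np.sum((w1 / u - w2 / (1.0 - u)) * dF, axis=-1) / n
    return val, grad


def mps_objective(model, data, want_grad: bool = False):
    """Negated mean log spacing -W(Delta) = -(1/(n+1)) sum log D_i."""
    x = _sorted(data)
    if len(x) < 2:
        raise ValueError("maximum product spacing needs n >= 2")
    ss = SpacingSet.from_model(model, x)
    d = np.clip(ss.spacings, _U_LO, None)
    m = len(d)
    val = -float(np.sum(np.log(d))) / m
    if not want_grad:
        return val
    dF = model.cdf_param_grad(x)                       # (p, n)
    dD = np.empty((dF.shape[0], m))
    dD[:, 0] = dF[:, 0]
    dD[:, 1:-1] = np.diff(dF, axis=1)
    dD[:, -1] = -dF[:, -1]
    if ss.tie_mask.any():
        # tied cells carry the density convention: d log D = d log f
        dlogf = model.logpdf_param_grad(x[1:][ss.tie_mask[1:-1]])
        dD[:, ss.tie_mask] = dlogf * d[ss.tie_mask]
    grad = -np.sum(dD / d, axis=-1) / m
    return val, grad


_OBJECTIVES = {
    "mle": None,  # handled specially (nll + score)
    "ls": ls_objective,
    "wls": wls_objective,
    "mps": mps_objective,
    "cvm": cvm_objective,
    "ad": ad_objective,
}


def _objective_value_grad(method, model, x_sorted, want_grad):
    if method == "mle":
        val = nll(model, x_sorted)
        if not want_grad:
            return val, None
        if not np.isfinite(val):
            return val, None
        return val, -score(model, x_sorted)
    fn = _OBJECTIVES[method]
    if want_grad:
        return fn(model, x_sorted, want_grad=True)
    return fn(model, x_sorted), None


# --------------------------------------------------------------------------
# fit front-end
# --------------------------------------------------------------------------

@dataclass
class FitResult:
    """Outcome of one estimation run."""

    method: str
    family: str
    param_names: tuple
    estimates: np.ndarray
    objective: float
    n_obs: int
    converged: bool
    n_restarts_used: int
    se: Optional[np.ndarray] = None
    seed: Optional[int] = None
    message: str = ""

    @property
    def params(self) -> dict:
        return dict(zip(self.param_names, (float(v) for v in self.estimates)))

    @property
    def neg2logl(self) -> float:
        if self.method != "mle":
            raise ValueError("neg2logl is defined for method='mle' fits")
        return 2.0 * self.objective

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "family": self.family,
            "estimates": self.params,
            "se": None if self.se is None else dict(
                zip(self.param_names, (float(v) for v in self.se))),
            "objective": float(self.objective),
            "n_obs": int(self.n_obs),
            "converged": bool(self.converged),
            "n_restarts_used": int(self.n_restarts_used),
            "seed": self.seed,
            "message": self.message,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def _numeric_hessian_nll(fam: Family, params: np.ndarray, x_sorted: np.ndarray,
                         rel_step: float = 1e-5) -> np.ndarray:
    """Observed information: central-difference Hessian of the nll."""
    p = np.asarray(params, dtype=float)
    k = len(p)
    H = np.zeros((k, k))

    def f(q):
        try:
            return nll(fam.make(q), x_sorted)
        except (ValueError, FloatingPointError):
            return np.inf

    steps = rel_step * np.maximum(np.abs(p), 1e-8)
    f0 = f(p)
    for a in range(k):
        for b in range(a, k):
            ea = np.zeros(k); ea[a] = steps[a]
            eb = np.zeros(k); eb[b] = steps[b]
            if a == b:
                val = (f(p + ea) - 2.0 * f0 + f(p - ea)) / steps[a] ** 2
            else:
                val = (f(p + ea + eb) - f(p + ea - eb) - f(p - ea + eb)
                       + f(p - ea - eb)) / (4.0 * steps[a] * steps[b])
            H[a, b] = H[b, a] = val
    return H


def _standard_errors(fam, params, x_sorted) -> Optional[np.ndarray]:
    try:
        H = _numeric_hessian_nll(fam, params, x_sorted)
        if not np.all(np.isfinite(H)):
            return None
        cov = np.linalg.inv(H)
        d = np.diag(cov)
        if np.any(d <= 0):
            return None
        return np.sqrt(d)
    except np.linalg.LinAlgError:
        return None


def fit(data,
        family: Union[str, Family] = "t2gwe",
        method: str = "mle",
        init: Optional[Sequence[float]] = None,
        n_restarts: int = 5,
        seed: Optional[int] = None,
        tol: float = 1e-10,
        compute_se: bool = True) -> FitResult:
    """Fit a lifetime family to uncensored positive data by one criterion.

    Parameters
    ----------
    data : array-like
        Observed lifetimes (any order; sorted internally).
    family : str or Family
        Family name (``t2gwe``, ``t2gwu``, ``t2gwp``, ``egt``, ``wge``,
        ``lgt``, ``t2g``, ``weibull``, ``gamma``) or a Family instance.
    method : str
        One of ``mle``, ``ls``, ``wls``, ``mps``, ``cvm``, ``ad``.
    init : sequence, optional
        Starting parameter vector; defaults to the family's heuristic.
    n_restarts : int
        Total number of deterministic starts (first unjittered).
    seed : int, optional
        Seed for the jittered restart design.
    tol : float
        Convergence tolerance on the objective.
    compute_se : bool
        Compute observed-information standard errors (``mle`` only).
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; valid: {', '.join(METHODS)}")
    fam = get_family(family) if isinstance(family, str) else family
    x = _sorted(data)
    n = len(x)
    if method == "mps" and n < 2:
        raise ValueError("mps requires n >= 2")

    use_grad = fam.analytic_grad

    def objective(eta):
        params = fam.from_eta(eta, x)
        if not np.all(np.isfinite(params)):
            return (_BIG, np.zeros_like(eta)) if use_grad else _BIG
        try:
            model = fam.make(params)
            out = _objective_value_grad(method, model, x, use_grad)
        except (ValueError, FloatingPointError, ZeroDivisionError):
            out = (np.inf, None)
        val, grad_p = out if isinstance(out, tuple) else (out, None)
        if not np.isfinite(val):
            return (_BIG, np.zeros_like(eta)) if use_grad else _BIG
        if not use_grad:
            return val
        if grad_p is None or not np.all(np.isfinite(grad_p)):
            return val, np.zeros_like(eta)
        return val, grad_p * fam.eta_jacobian(eta, x)

    p0 = np.asarray(init if init is not None else fam.init_params(x), dtype=float)
    eta0 = fam.to_eta(p0, x)
    rng = np.random.default_rng(seed if seed is not None else 0)
    starts = [eta0] + [eta0 + rng.normal(0.0, 0.4, size=eta0.shape)
                       for _ in range(max(0, n_restarts - 1))]

    best_ok = None    # lowest objective among successful runs
    best_any = None   # lowest objective overall (fallback start point)
    n_used = 0
    for eta_start in starts:
        n_used += 1
        try:
            res = optimize.minimize(
                objective, eta_start, jac=use_grad or None, method="L-BFGS-B",
                options={"maxiter": 500, "ftol": tol, "gtol": 1e-8})
        except (ValueError, FloatingPointError):  # pragma: no cover - defensive
            continue
        ok = bool(res.success) and np.isfinite(res.fun) and res.fun < _BIG
        if best_any is None or res.fun < best_any.fun:
            best_any = res
        if ok and (best_ok is None or res.fun < best_ok.fun):
            best_ok = res

    # Nelder-Mead fallback / polish when the quasi-Newton path struggled
    if best_ok is None:
        eta_start = best_any.x if best_any is not None else eta0

        def value_only(eta):
            out = objective(eta)
            return out[0] if isinstance(out, tuple) else out

        res = optimize.minimize(value_only, eta_start, method="Nelder-Mead",
                                options={"maxiter": 4000, "fatol": tol,
                                         "xatol": 1e-10})
        if bool(res.success) and np.isfinite(res.fun) and res.fun < _BIG:
            best_ok = res
        elif best_any is None or res.fun < best_any.fun:
            best_any = res

    converged = best_ok is not None
    res = best_ok if converged else best_any
    params = fam.from_eta(res.x, x)
    out = _objective_value_grad(method, fam.make(params), x, False)
    obj_val = out[0] if isinstance(out, tuple) else out

    se = None
    if method == "mle" and compute_se and converged:
        se = _standard_errors(fam, params, x)

    return FitResult(
        method=method,
        family=fam.name,
        param_names=fam.param_names,
        estimates=params,
        objective=float(obj_val),
        n_obs=n,
        converged=converged,
        n_restarts_used=n_used,
        se=se,
        seed=seed,
        message=str(getattr(res, "message", "")),
    )
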