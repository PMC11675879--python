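# Methods notes

This document records the model, the numerical choices, and the design
decisions behind `t2gwg`, in the spirit of a statistical package's
methods appendix.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The model

For a baseline cdf H(x, ψ) with survival function H̄ = 1 − H, the odds
of failure by time x are H/H̄, increasing from 0 to ∞ across the
support.  The generic generator applies an outer cdf R on (0, ∞) to a
two-parameter power transform of the odds:

    F(x) = R( α (H/H̄)^β ).

Because the odds map is a monotone bijection onto R's support, F is a
proper cdf on the baseline support for any valid (R, H, α, β).  The
package's central family takes R as the Type 2 Gumbel cdf
R(t) = exp(−λ t^(−δ)); fixing λ = δ = 1 (to avoid over-parameterisation;
the scale is absorbed into α) gives

    F(x) = exp( −α (H/H̄)^(−β) ),
    f(x) = α β h H^(−β−1) H̄^(β−1) F(x).

The sign of the H̄ exponent is worth a note: it is β − 1, the unique
choice for which f = dF/dx (re-derived by chain rule and unit-tested
against numerical differentiation, rather than transcribed — printed
versions of this family's density are prone to sign typos in exactly
this exponent, and one reverse-hazard formula in circulation carries a
stray δ from the unreduced four-parameter form).

Interpretation of the parameters:

- **α > 0** — odds scale.  F(baseline median) = e^(−α), and α enters the
  cdf as an exponential rate in the transformed odds, so α orders the
  family stochastically: with β and baseline fixed, a larger α gives
  stochastically larger lifetimes (a likelihood-ratio ordering, hence
  hazard-rate and usual ordering).  Powers of F stay in the family
  (F^k = F with α ↦ kα), which is why order-statistic densities reduce
  to finite mixtures of rescaled members.
- **β > 0** — odds power, controlling tail weight.  For the exponential
  baseline the hazard tends to βγ at infinity and the density tail is
  ∝ e^(−βγx); for the Pareto baseline the survival tail is ∝ x^(−kβ), so
  E[X^r] exists iff r < kβ.
- **ψ** — baseline parameters: rate γ for the exponential, upper support
  bound γ for the uniform, scale/shape (θ, k) for the Pareto.

The quantile function routes through the baseline quantile:
q = 1/(1 + (−log p / α)^(1/β)), x_p = H⁻¹(q).  Sampling is inverse
transform.  (One published special-case quantile formula for the
exponential member is typographically garbled; the package derives all
special cases from the generic route and the tests verify the
closed-form reductions against it, never the other way round.)

## Numerical policy

All tail-sensitive quantities are computed in log space: the odds ratio
as `log H − log H̄` with `log H̄` from the baseline's native survival
form (`−γx`, `k log(θ/x)`, ...), never via `log(1 − H)`; the cdf as
`exp(−α exp(−β log-odds))`; the survival function as `−expm1(log F)`.
Quantile arguments are clipped one ulp inside (0, 1).

Moments, entropy and generating functions are computed by adaptive
quadrature (`scipy.integrate.quad`) over support pieces split at the
model's own quantiles, with `epsabs = 1e-12`.  The exponentiated-
generalized (EG) double-series expansions of the density, moments and
Rényi entropy are *formal*: terms alternate, individual term integrals
can diverge (any EG exponent ≤ −1 is non-integrable at the lower support
limit), and no general convergence region is known.  They are therefore
exposed as diagnostics that return an explicit convergence flag, while
quadrature is the authoritative route.  Within the density expansion the
coefficient poles at β(j+1) = k cancel against the EG power factor, so
summands are evaluated in the cancelled form; the standalone coefficient
accessor raises at an exact pole.  Generalized binomial coefficients
C(a, k) for real (possibly negative) a are evaluated as the k-term
product a(a−1)⋯(a−k+1)/k!, which carries exact signs without log-gamma
reflection.

The moment-generating function is only evaluated where the integrand
demonstrably decays (checked at a far quantile); divergence — including
Pareto-baseline moments with r ≥ kβ — is flagged, never silently
truncated.

## Estimation

Six criteria are implemented as minimisation objectives over
Δ = (α, β, ψ): negative log-likelihood; least squares and weighted least
squares of the fitted cdf at order statistics against plotting positions
i/(n+1) (WLS weights (n+1)²(n+2)/[i(n−i+1)]); negated mean log spacing
(maximum product spacing, MPS); the Cramér–von Mises distance
1/(12n²) + (1/n)Σ(F₍ᵢ₎ − (2i−1)/(2n))²; and the Anderson–Darling
distance −n − (1/n)Σ(2i−1)[log F₍ᵢ₎ + log(1 − F₍ₙ₊₁₋ᵢ₎)].  (A variant of
the AD criterion with a minus sign between the two log terms circulates
in print; it is unbounded below under minimisation — pushing all fitted
cdf values to 1 decreases it without limit once clamped — so the package
uses the standard statistic.)

Gradients: the T2GWG members supply analytic ∂F/∂Δ and ∂log f/∂Δ (with
∂F/∂α = −t^(−β)F, ∂F/∂β = α log(t) t^(−β) F, ∂F/∂ψ = αβ H^(−β−1)
H̄^(β−1) ∂H/∂ψ · F for t = H/H̄), verified against central finite
differences for every criterion; comparison families fall back to
finite-difference gradients.

Optimisation runs on an unconstrained scale: log transforms for positive
shapes, and data-dependent maps for support-boundary parameters — the
uniform baseline's upper bound as γ = M(1 + e^η) with M one part in
10¹² above max(x), the Pareto scale as θ = m·expit(η) with m just below
min(x).  A quasi-Newton method (L-BFGS-B, ftol 1e-10) runs from a
method-of-moments-flavoured start (γ₀ = 1/mean for the exponential
baseline, unit shapes) plus seeded log-normal jitters (five starts by
default), with a Nelder–Mead fallback when no quasi-Newton start
converges.  Failures are reported as a non-converged result with
diagnostics, never as a silent bad fit.

Two conventions worth flagging:

- **Boundary estimates.**  For β < 1 the uniform-baseline likelihood is
  *unbounded* as γ ↓ max(x) (the H̄^(β−1) factor at the largest
  observation diverges), so γ̂ is a boundary estimate whose reported
  log-likelihood is a function of the boundary guard's resolution.  The
  guard is set to the last double-precision-exact offset (1e-12
  relative); reported −2logL values at such boundary fits should be
  compared across implementations only with this in mind.
- **MPS ties.**  Exact ties produce zero spacings; following the
  Cheng–Amin convention each zero spacing is replaced by the density at
  the tied point.  CDF values entering logarithms (AD, MPS) are clamped
  to [1e-300, 1 − 1e-16].

Standard errors (MLE only) come from the inverse of a central-difference
observed-information matrix; a non-invertible or non-positive-definite
Hessian yields absent SEs rather than fabricated ones.

## Goodness of fit

CAIC is the small-sample corrected AIC, AIC + 2k(k+1)/(n − k − 1) — the
formula consistent with the published comparison tables this package
mirrors (some printed CAIC cells in those tables match no standard
formula and are not used as references).  W and A are reported raw; the
small-sample modified versions (1 + 0.5/n and 1 + 0.75/n + 2.25/n²
factors) are computed alongside and the report labels the convention.
The K-S p-value uses the asymptotic Kolmogorov distribution of √n·D with
no correction for estimated parameters, matching common practice in the
lifetime-distribution literature; under estimated parameters it is
conservative and is best read comparatively across models.  With fully
observed data the Kaplan–Meier curve equals 1 − ECDF; it is included for
the standard survival-analysis diagnostic panel alongside the scaled
total time on test, whose concave/convex geometry diagnoses monotone
versus bathtub hazards.

Comparison families (exponentiated Gumbel type-2, Weibull
generalized-exponential, Lomax Gumbel type-2, Type 2 Gumbel, Weibull,
gamma) are implemented from their standard literature forms as fit
targets for `compare_models` only; their own distribution theory is out
of scope.

## Monte Carlo harness

`run_mc_study` reproduces the classic bias/MSE experiment: for each
sample size, draw a fresh sample at the true parameters, refit with each
requested criterion, and average error and squared error over
replications.  Design choices:

- **Simulated family: T2GWE.**  The exponential baseline is the family's
  lead special case and its γ is a rate-like third parameter matching
  the study design (α, β, γ) = (2.5, 0.8, 1.3); this is the harness's
  central assumption and is carried in the config.
- **Seeding** is counter-based: the child stream for replication r at
  size index s is `SeedSequence([master, s, r])`, so every cell is
  reproducible in isolation and results are independent of execution
  order.
- **Failures** (non-converged fits, non-finite estimates) are excluded
  from the means with their count reported per cell; a cell losing more
  than 10% of replications is flagged unreliable.

Problem sizes: the acceptance script runs the full design cell —
R = 1000 replications at n = 1000 (about two minutes on one CPU) — while
the test suite exercises a reduced R = 200 version of the same cell and
an R = 80 trend check across n ∈ {50, 250, 1000}, sizes chosen to keep
the default test run brief while leaving Monte Carlo noise far below the
effects being asserted.

## What the synthetic data does and does not emulate

Synthetic samples are exact i.i.d. draws from the fitted families by
inverse transform: they emulate complete (uncensored), independent
lifetime data — the regime all six estimators assume.  They do not
emulate censoring, truncation, covariates, measurement rounding or
contamination; passing tests therefore certify the estimators and
statistics under the model's own assumptions, not robustness to
violations of them.  The three packaged real datasets (Aarset devices,
Meeker–Escobar running times, chemotherapy survival times — plain-text
transcriptions from the published literature) provide the
complementary real-data check; note the Meeker–Escobar values of 300
are the test horizon reached by survivors, conventionally analysed as
observed in this literature.

## Known limitations

- No censored-data likelihoods; all criteria assume complete samples.
- The EG-series diagnostics rarely converge outside small-α,
  moderate-β regions; they are cross-checks, not computational routes.
- The K-S p-value ignores parameter estimation (see above).
- Boundary estimates (uniform γ̂ at the sample maximum) have no valid
  observed-information standard errors; the package may return absent
  SEs there.
- `compare_models` ranks by AIC; it does not test nested hypotheses.
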