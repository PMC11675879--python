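# t2gwg — Type 2 Gumbel Weibull-G lifetime distributions

`t2gwg` is a Python toolkit for a family of flexible lifetime
distributions built on the **exponentiated odds ratio** of survival
analysis.  Given a baseline distribution with cdf H(x, ψ) and survival
function H̄ = 1 − H, the odds that a subject has failed by time x are
H/H̄.  Applying an outer cdf R to a power transform of these odds,

    F(x) = R( α · (H(x, ψ)/H̄(x, ψ))^β ),      α, β > 0,

turns any simple baseline into a rich shape family.  The package centres
on the branch obtained with the Type 2 Gumbel outer R(t) = exp(−t⁻¹),
the **Type 2 Gumbel Weibull-G (T2GWG) family**:

    F(x) = exp( −α · (H(x, ψ)/H̄(x, ψ))^(−β) ),

with exponential, uniform and Pareto baselines built in (T2GWE, T2GWU,
T2GWP).  The uniform-baseline member produces bathtub-shaped hazard
rates — the classic infant-mortality / useful-life / wear-out pattern of
reliability engineering that monotone-hazard families (exponential,
gamma, Weibull) cannot express.

It is aimed at reliability engineers and biostatisticians fitting
uncensored positive lifetimes: device failure times, survival times,
running times.

## What it provides

- **Distribution surface** (`t2gwg.core`): cdf, pdf, hazard, reverse
  hazard, quantile and inverse-transform sampling, all evaluated in log
  space for tail stability; pluggable baselines (`t2gwg.baselines`) and
  the generic outer-composition generator (`t2gwg.generator`).
- **Analytic properties** (`t2gwg.properties`): moments (raw,
  incomplete, conditional), mgf/cf, Rényi and Shannon entropy, order
  statistics, likelihood-ratio stochastic ordering, and the formal
  exponentiated-generalized series expansion with convergence
  diagnostics.
- **Six estimation criteria** (`t2gwg.estimation`): maximum likelihood,
  least squares, weighted least squares, maximum product spacing,
  Cramér–von Mises and Anderson–Darling minimum distance — all with
  analytic gradients for the T2GWG members, a multistart quasi-Newton
  optimiser, and observed-information standard errors for MLE.
- **Goodness of fit and model comparison** (`t2gwg.gof`): −2logL,
  AIC/BIC/CAIC/HQIC, W, A, Kolmogorov–Smirnov with asymptotic p-value,
  TTT/Kaplan–Meier/ECDF diagnostics, and `compare_models` ranking
  competing families (including EGT, WGE, LGT, Type 2 Gumbel, Weibull,
  gamma comparison fits).
- **Monte Carlo harness** (`t2gwg.simulation`): reproducible bias/MSE
  studies of all six estimators across sample sizes.
- A `t2gwg` command-line interface (`fit | compare | simulate | ttt |
  fixture`).

## Worked example

Fit the exponential-baseline member to the packaged chemotherapy
survival dataset (45 patients, survival times in years):

```python
import t2gwg as tg

data = tg.load_dataset("chemo").values
result = tg.fit(data, family="t2gwe", method="mle", seed=1)
print(result.params)
print(f"-2logL = {result.neg2logl:.4f}")

model = tg.get_family("t2gwe").make(result.estimates)
d, p = tg.ks_test(data, model.cdf)
print(f"K-S = {d:.4f} (p = {p:.4f})")
```

which prints

```
{'alpha': 1.1328256635903342, 'beta': 0.5415644424078383, 'gamma': 1.4015416977653372}
-2logL = 113.3334
K-S = 0.0756 (p = 0.9592)
```

α̂ and β̂ are the two odds-transform shapes, γ̂ the exponential baseline
rate (per year); the small K-S distance and large p-value indicate the
fitted cdf tracks the empirical one closely.  The same call with
`family="weibull"` or `"gamma"` gives −2logL of 116.25 and 116.18 — the
odds-ratio family fits this sample better even after charging for its
extra parameter (AIC 119.33 against 120.25 and 120.18).

A Monte Carlo check of estimator quality:

```python
from t2gwg.simulation import SimConfig, run_mc_study

cfg = SimConfig(true_params=(2.5, 0.8, 1.3), sample_sizes=(50, 250, 1000),
                n_reps=200, methods=("mle", "mps"), master_seed=7)
print(run_mc_study(cfg).table)
```

Bias and MSE of every parameter shrink as the sample grows, for every
criterion.

## Layout

```
src/t2gwg/        library (baselines, core, generator, properties,
                  estimation, families, gof, simulation, io, cli)
src/t2gwg/data/   three classic lifetime datasets transcribed from the
                  published literature (Aarset devices, Meeker–Escobar
                  running times, chemotherapy survival)
tests/            pytest suite
docs/methods.md   modelling and numerical methods notes
```
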