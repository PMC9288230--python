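# airtails

Superstatistical tail analysis of air-pollutant concentration time series.

Hourly concentrations of NO, NO₂, PM₂.₅ and PM₁₀ at monitoring sites are
generically heavy-tailed: their probability densities decay much more slowly
than the exponential, gamma, Weibull or log-normal laws traditionally used
to fit them. A physically motivated alternative is the **q-exponential**
distribution

```
f_{q,λ}(x) = (2 − q) λ [1 − λ(1 − q) x]^{1/(1−q)},     1 − λ(1−q)x ≥ 0, x > 0
```

where `q` (the entropic index, 0 < q < 2) controls tail heaviness — for
q > 1 the tail is a power law with exponent −1/(q−1), for q < 1 the support
is finite, and q = 1 recovers the exponential `λ e^{−λx}` — and `λ` is an
inverse-scale width parameter (larger λ ⇒ faster decay ⇒ cleaner air).

The q-exponential arises naturally from **superstatistics**: concentrations
are locally exponential with a rate λ that fluctuates on a much longer time
scale (weather regimes, traffic cycles). If the rate is Γ(a, θ)-distributed,
the long-run marginal is exactly q-exponential with

```
q = (a + 2)/(a + 1),      λ_q = θ (a + 1),
```

while the superstatistical index computed from the rate fluctuations
themselves is `q = ⟨λ²⟩/⟨λ⟩² = 1 + 1/a` — a distinct convention that the
package exposes side by side.

`airtails` implements the complete analysis pipeline for ensembles of
monitoring sites, for researchers in environmental statistics and
statistical physics:

* **QC filters** — ≥ 8760 valid hourly points (one full year), at most 15%
  of values below the detection limit (sub-LOD readings replaced by LOD/2),
  and no single repeated value covering ≥ 15% of the data (stuck sensors);
* **tail fitting** — lower cutoff at the peak of a Gaussian KDE, then
  maximum-likelihood fits of exponential, gamma, Weibull, log-normal and
  q-exponential on the shifted tail, ranked by log-likelihood;
* **ensemble summaries** — seven combined environment categories
  (traffic/industrial/background × urban/suburban/rural, with
  suburban/rural merged for traffic and industrial), Beaufort wind classes
  from co-located weather stations (Chebyshev matching < 0.1°), and
  per-group λ medians, interquartile ranges and 95% intervals;
* **a synthetic generator** of whole monitoring networks — Γ-mixed
  exponential series with seasonal modulation, detection-limit censoring,
  stuck-value corruption, site metadata and wind — with closed-form ground
  truth, so every stage is testable without external data.

## Worked example

Generate a five-year synthetic site whose rate fluctuates as Γ(a=2, θ=1)
per 168-hour window, then run the per-site pipeline:

```python
from airtails import (SuperstatConfig, gen_concentration_series, fit_site,
                      marginal_qexp)

cfg = SuperstatConfig(a=2.0, theta=1.0, window_hours=168, n_hours=43800, seed=42)
fit = fit_site(gen_concentration_series(cfg))
print(marginal_qexp(cfg.a, cfg.theta))   # the generator's ground truth
print(fit.q, fit.lam, fit.best_family)
```

Output:

```
true marginal:  q = 1.3333, lambda_q = 3.00
tail cutoff x_peak = 0.164 ug/m3, n_tail = 32245
fitted: q = 1.3205, lambda = 2.602, best family = qexponential
raw mean = 0.909, sd = 1.811  (sd/mean = 1.99 > 1: heavy tail)
  loglik exponential       -33604.9
  loglik gamma             -31286.2
  loglik weibull           -30177.3
  loglik lognormal         -30049.9
  loglik qexponential      -29071.3
```

The fitted entropic index (1.32) recovers the generator's marginal exponent
(4/3) to ~0.01; the sd/mean ratio of 1.99 flags the deviation from
exponentiality (an exponential has sd = mean); and the q-exponential beats
every classical family by hundreds of log-likelihood units. The fitted λ
(2.60) refers to the tail variable `y = x − x_peak` and is therefore
slightly below λ_q = 3 (conditioning a power-law tail shifts its scale, not
its exponent).

A command-line interface wraps the same stages:

```sh
airtails simulate --seed 1 --outdir data --n-sites 50
airtails run-all --config pipeline.yaml
```

producing `qc.csv`, `results.csv` (one row per fitted site with x_peak,
(q, λ), all five log-likelihoods and the best family), `scatter.csv`
(q vs log₁₀ λ by category), and λ-summary tables per environment category
and wind class.

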