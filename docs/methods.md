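# Methods

## Model

Concentrations at a site are modelled as locally exponential,
`x(t) ~ Exp(rate λ(t))`, with a rate that fluctuates on a time scale much
longer than the hourly sampling. Averaging the exponential density over the
rate distribution gives the stationary marginal. When the rate is
Γ(a, θ)-distributed the integral is exact:

```
∫ Γ(a,θ)(λ) · λ e^{−λx} dλ  =  a θ (1 + θx)^{−(a+1)}
                            =  (2−q) λ_q [1 − λ_q(1−q)x]^{1/(1−q)}
```

with `q = (a+2)/(a+1)` and `λ_q = θ(a+1)` — a q-exponential. Two q
conventions coexist in the superstatistics literature and both are
implemented: the *marginal exponent* above (what an MLE on the series
estimates, `marginal_qexp`) and the *rate-fluctuation index*
`⟨λ²⟩/⟨λ⟩² = 1 + 1/a` (`superstat_q`). They coincide only as a → ∞; code
and tests keep them strictly apart.

Key parameter facts used throughout: normalisability needs 0 < q < 2 and
λ > 0; the mean is `1/(λ(3−2q))`, finite for q < 1.5; the squared
coefficient of variation is `(2−q)/(4−3q)`, which the MLE inverts for its
starting value; for q > 1 the tail exponent is −1/(q−1); for q < 1 the
support ends at `1/(λ(1−q))`.

## Maximum-likelihood estimation

`qexp_mle` maximises the exact log-likelihood over (q, log λ) with
Nelder–Mead (log-likelihood tolerance 1e−8, at most 500 iterations),
started from the method-of-moments guess `q₀ = (2−4c)/(1−3c)` with
`c = CV²`, clipped to [0.7, 1.8], plus offsets q₀ ± 0.2 so the optimiser
can cross the q = 1 boundary into either regime. For q < 1 a candidate
whose finite support excludes any data point has likelihood exactly zero
and is rejected outright (hard penalty, not a soft one) — exact likelihood
semantics. Non-convergence from every start raises an error that the
pipeline records per site; failures are never silent.

The comparison families (exponential closed-form, gamma, Weibull,
log-normal) are fitted with location fixed at zero on the same shifted tail
variable, so all five log-likelihoods are comparable. Raw log-likelihood is
the selection criterion; no AIC/BIC correction is applied. Exact ties go to
the family with fewer parameters. On data that truly are exponential, every
nested two-parameter family exceeds the exponential's log-likelihood by an
O(1) sampling fluctuation, so which of them "wins" is noise — the tests
assert q̂ ≈ 1 and the nesting inequality instead of a specific winner.

## Per-site procedure

1. **QC.** Values below the detection limit (negatives included) are
   replaced by LOD/2. A site needs ≥ 8760 valid points; strictly more than
   15% below-LOD fails (boundary passes — "more than"); a modal value with
   share ≥ 15% fails (boundary fails — "at least"). The repeated-value rule
   is read as the modal value's share of all valid measurements, not
   consecutive runs. Missing values are excluded from all counts and
   denominators. Without a known LOD the LOD filter is skipped and flagged
   in the report rather than guessed. All failed filters are reported, not
   just the first.
2. **Tail cutoff.** Gaussian KDE with Scott's bandwidth on a 512-point grid
   spanning [min, max]; the cutoff `x_peak` is the grid abscissa of the
   density maximum. Kernel, bandwidth rule and grid size are configurable;
   the defaults are fixed for reproducibility.
3. **Tail fit.** Values strictly greater than `x_peak`, shifted to
   `y = x − x_peak > 0`, are fitted by all five families. The reported λ
   refers to y. For a power-law (q > 1) tail the shift changes λ
   (`λ' = λ_q / (1 + (q−1)λ_q x_peak)`) but not q, so q-recovery against
   the generator is exact in expectation while λ comparisons are
   order-preserving rather than absolute.
4. **Diagnostics.** The raw series' mean and standard deviation are kept
   (equal for an exponential; sd > mean flags a heavy tail).

## Ensemble stage

Station type × area type maps onto seven environment categories (suburban
and rural merged for traffic and industrial stations); the mapping is total
and case-insensitive. Wind grouping uses the four lowest Beaufort classes
with upper bounds 1.5 / 3.3 / 5.4 / 7.9 m/s (Beaufort 0 and 1 merged as
"calm & light air"); these m/s boundaries come from the standard scale and
are exposed in the configuration. Site-mean wind speed comes from the
nearest weather station by Chebyshev distance, matched only strictly inside
0.1°. Group λ summaries report the median, the interquartile range and the
central 95% **percentile interval** (not a bootstrap CI of the median —
a deliberate reading of the violin-plot convention), with groups ranked by
median ascending; quantiles use numpy's linear interpolation (type 7).

## Synthetic generator

`gen_lambda_process` draws one Γ(a, θ) rate per `window_hours` window
(default 168 h — one week, chosen as a plausible synoptic-weather scale; the
slow scale of real pollution dynamics is not sharply known) and holds it
constant within the window; `gen_concentration_series` draws independent
exponentials around it. Seasonality multiplies the mean concentration 1/λ
by `1 + A sin(2πt/period)` with default period 8760 h and amplitude 0.3 in
ensembles — a smooth annual cycle. Corruption: a contiguous stuck-value run
(`stuck_frac`, planted at 30% in defect tests, well above the 15%
threshold) and LOD/2 censoring (ensemble default LOD 0.1 µg/m³, small
relative to clean-category means so clean sites pass the 15% rule with a
wide margin).

`gen_site_ensemble` assigns the seven categories round-robin with
per-category (a, θ) defaults: a = 2 everywhere (marginal q = 4/3, inside
the 0.8–1.4 band typical of European sites) and θ rising from 0.02 (urban
traffic, most polluted, λ_q = 0.06) to 0.30 (rural background, λ_q = 0.90),
planting a known ordering of category λ medians. Ensemble series default to
17520 h (two years) — inside the one-to-five-year range of real archives —
and recovery sweeps use 43800 h (five years). A configurable fraction of
sites (default 80%) gets a weather station 0.05° away (matched); the rest
0.2° (unmatched). Per-site mean wind speeds cycle through 0.8/2.5/4.5/6.5
m/s so all four Beaufort classes are populated. Everything derives from one
seed via `numpy.random.SeedSequence`, making all CSV outputs byte-identical
across runs.

What the generator does **not** emulate: spatial transport and inter-site
correlation of particulate matter, wind-direction effects, diurnal traffic
cycles, autocorrelation of concentrations *within* a rate window,
calibration drift, and non-Γ rate distributions. Passing tests therefore
demonstrate correctness of the estimation machinery under the
superstatistical model, not that real concentrations follow it.

## Numerical choices and limitations

* Density/CDF/quantile closed forms are exact; quadrature oracles in the
  tests bound their error at 1e−8 (normalisation, CDF) and the Γ-mixture
  identity at 1e−10.
* The KS check of generated series against the closed-form marginal uses
  one-hour windows: with long windows consecutive hours share a rate, and
  the iid KS null would not apply even though the marginal is exact.
* Distributional acceptance sweeps are sized for a single CPU: 2 seeds ×
  4 generator settings at n = 43800 for parameter recovery, 100 replicates
  at n = 10⁴ for model selection, 50-site networks for the end-to-end runs.
* The LOD/2 substitution biases λ̂ upward for sites with non-negligible
  censoring; the 15% cap bounds the effect but does not remove it.
* For q near 2 the likelihood surface flattens (tail exponent → ∞); the
  optimiser bounds q at 2 − 10⁻³ and such fits should be treated with
  caution. Real-data λ values spanning orders of magnitude are handled by
  optimising in log λ.
* No time-varying q(t) or λ(t) inference, no Bayesian estimation, and no
  cross-pollutant correlation analysis — the unit of analysis is one
  site/pollutant series.
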