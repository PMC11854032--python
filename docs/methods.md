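# Methods

## Model

The NL-G family composes a baseline cdf G with the exponentiated
reciprocal hazard (Mills-ratio power) of a Lomax distribution,
`W(x) = ((x + λ)/θ)^c`, giving `F(x) = G(W(x))` on the support
`[−λ, ∞)`. The Lomax location λ is unconstrained in sign — the fitted
support endpoint may sit below zero (gauge-length and score data fit
with negative λ̂) — while θ > 0 and c > 0 are scale and shape. The
Weibull baseline `G(t) = 1 − exp(−α t^β)` gives the NLW member

    F(x) = 1 − exp(−α ((x + λ)/θ)^{cβ}).

Two support statements circulate for this construction (`x > 0` versus
`x ≥ −λ`); the package adopts `[−λ, ∞)` uniformly, which is the set on
which the cdf is nondegenerate and is required by the negative fitted
λ̂ values on real data. Below-support evaluation returns cdf 0 and pdf 0
rather than raising, so empirical-cdf comparisons never crash.

### Identifiability

The cdf depends on (α, β, θ, c) only through `k = cβ` and
`s = α/θ^k`: the NLW is a three-parameter Weibull with location −λ,
shape k and scale `s^{−1/k}`. The raw five-parameter vector therefore
lies on a two-dimensional ridge of equal likelihood. Consequences drawn
throughout the package:

- every `FitResult` reports the identifiable triple (λ, k, s);
- parameter-recovery checks and the Monte Carlo acceptance checks are
  stated on the functionals, not the raw parameters (raw trajectories
  depend on optimizer details);
- observed-information standard errors use a pseudo-inverse and flag
  flat directions; the reported 95% interval lengths are `2·1.96·SE`.

## Numerical design

- **logpdf is the primitive**; `pdf = exp(logpdf)`. Likelihoods and
  Anderson–Darling sums need log-space stability at extreme parameters.
  At `x = −λ` the density diverges for `k < 1`; `pdf` returns the `+inf`
  sentinel there and the likelihood guards against data exactly at −λ̂.
- **The survival function is computed directly** from its closed form
  (never `1 − cdf`) to preserve tail precision in K-S/A-D; the cdf uses
  `−expm1`, the quantile `−log1p`.
- **Sampling is inverse-transform only**: `x = θ(−ln(1−u)/α)^{1/k} − λ`
  with uniforms from `numpy.random.default_rng(seed)`; the simulation
  harness derives per-replicate child seeds from one `SeedSequence`
  spawn, so results are reproducible and independent of which subset of
  methods is requested.
- **Quadrature first.** Every expectation (moments, MGF/CF, PWM,
  Shannon entropy) is an adaptive `scipy.integrate.quad` after the
  unit-exponential substitution `w = α((x+λ)/θ)^k`, under which
  `f(x)dx = e^{−w}dw` — a half-line integral with a known light weight.
  Near-critical MGF arguments keep `t·x − w` inside a single exponent to
  avoid overflow. The Rényi cross-check integrates `f^u` in x-space
  (split at the 1−10⁻¹³ quantile) because for `u < 1` the w-space
  integrand diverges at the endpoint.
- **Series are secondary.** The binomial expansions of the raw moments
  and PWMs expand `(1 + x/λ)^{k−1}` and converge only in restricted
  domains (they are finite, hence exact, when k is a positive integer —
  the case used to validate them). The series path requires λ > 0,
  stops on a two-successive-increments Cauchy criterion and raises
  `SeriesConvergenceError` otherwise. Quadrature is authoritative
  whenever the two disagree.
- **Rényi entropy closed form** was re-derived via the same
  substitution: `RE(u) = (1/(1−u))[u log(αβc/θ) + log(θ/k) − κ log(uα)
  + log Γ(κ)]` with `κ = (uk − u + 1)/k`, finite iff κ > 0; it is
  validated against quadrature in the tests.
- **MGF existence**: always for `t ≤ 0`; for `t > 0` when `k > 1`; in
  the exponential-tail case `k = 1` for `t` below the rate `s = α/θ`;
  never for `k < 1`. Out-of-domain requests raise `MgfDomainError`.
- **Order statistics** use the standard r-th order-statistic density
  `n!/((r−1)!(n−r)!) F^{r−1}(1−F)^{n−r} f` in log space (the textbook
  `B(r, n−r+1)` normalization — the only one that integrates to 1).
- **Quantile shape measures** default to the quantile-skewness and
  octile-kurtosis forms with denominator `x.75 − x.5`; a
  `standard=True` switch selects the conventional Galton and Moors
  coefficients (denominators `x.75 − x.25`), so figures are reproducible
  under either convention.

## Estimation

The analytic score is obtained by direct differentiation of the
log-likelihood

    ℓ = n log(αβc/θ) + (cβ−1) Σ log y_i − α Σ y_i^{cβ},  y_i=(x_i+λ)/θ,

and is verified against central finite differences in the tests (some
published per-parameter derivative listings for this model drop
per-observation factors; differentiation of ℓ itself is authoritative).

All five fits run in smooth transformed coordinates — logs of the
positive parameters and `λ = −min(x) + e^η` — so positivity and the
support constraint hold by construction and no penalty spikes are
needed. The data-driven starting point sets the support endpoint
0.1·IQR below the sample minimum, reads the shape `k₀` off a Weibull
probability-plot slope of `x + λ₀` (clipped to [0.2, 50]), splits it
arbitrarily as `c₀ = β₀ = √k₀`, and takes θ₀ from the plot intercept at
α₀ = 1; `n_starts − 1` seeded log-normal perturbations (sd 0.5) are
added. MLE minimizes with L-BFGS-B using the analytic gradient followed
by a Nelder–Mead polish; the minimum-distance criteria (percentile,
LSE, WLS with weights `(n+1)²(n+2)/(i(n−i+1))`, Cramér–von Mises) use
Nelder–Mead. The reported objective is always recomputed from the
returned parameters. Degenerate inputs (e.g. all observations equal)
yield a non-converged `FitResult`, never an exception. Ties are kept in
stable sorted order for plotting positions.

## Goodness of fit

Information criteria follow the small-sample conventions
`AIC = 2k − 2ℓ`, `BIC = k ln n − 2ℓ`, `CAIC = AIC + 2k(k+1)/(n−k−1)`
(corrected AIC; requires n > k+1) and `HQIC = 2k ln ln n − 2ℓ` — the
combination that makes the four packaged application tables internally
consistent. The K-S statistic is the two-sided one-sample
`D = max_i max(i/n − F(x_(i)), F(x_(i)) − (i−1)/n)` with the asymptotic
Kolmogorov p-value of `√n·D` and estimated parameters plugged in (no
Lilliefors correction); A-D is the plug-in
`A² = −n − (1/n)Σ(2i−1)[ln F(x_(i)) + ln(1 − F(x_(n+1−i)))]` without
small-sample modification, with degenerate F values clipped and logged.

Competitors are fitted by the same multistart MLE machinery in
log-parameter space: the two-parameter Lomax, and one documented parse
of each of the truncated-Weibull power Lomax (unit truncated-Weibull
generator over a power-Lomax baseline), the odd Lomax inverse Weibull
(odd-Lomax generator over an inverse-Weibull baseline) and the
exponentiated generalized modified Weibull
`F = (1 − e^{−α(θx + μx^λ)})^β` — the three published forms are typeset
with flattened exponents, so a grouping had to be chosen; their fitted
rows are a convenience, not a validated reproduction. Parameter counts:
Lomax 2, TWPL 4, OLIW 4, EGMW 5. The Lomax likelihood on the
failure-time data is nearly flat toward its exponential limit
(θ, λ → ∞ with θ/λ fixed); the multistart optimizer follows the ridge
and the reported optimum (≈162.877) is stable even though the raw
(θ̂, λ̂) are not.

## Monte Carlo harness

Each scenario draws `reps` inverse-transform samples per sample size
from a stated truth (four canonical truth vectors, Sets I–IV, ship with
the harness) and fits every requested method to the *same* replicate
data. Bias and MSE are averaged over Monte Carlo replicates (dividing
by the sample size instead would make the per-cell summaries
dimensionally incoherent); a median squared error per cell is also
reported since raw-parameter errors on the identifiability ridge are
heavy-tailed. Replicate fits use the same data-driven initialization as
ordinary fits — never the truth — so recovery is not trivialized.
Failed or non-finite fits are counted per cell and excluded from the
aggregates.

Problem sizes: the harness defaults to the canonical design
(n ∈ {20, 50, 100, 200, 300, 500}, 1000 repetitions), while the test
suite exercises a scaled-down design — 200 repetitions over
n ∈ {20, 100, 500} for Sets I–II, with all five methods compared at
n = 500 — which keeps a full run to a few minutes on one CPU while
preserving the qualitative conclusions (bias of the identifiable
functionals decays with n; MLE and WLS are the most accurate).

## What the synthetic data does and does not show

The generator produces exact i.i.d. NLW samples, so simulation results
validate the estimators *under the model*: correctness of the
objectives, consistency on the identifiable functionals, and the
relative accuracy ranking. They say nothing about robustness to
contamination, censoring, dependence or measurement rounding, none of
which the model addresses (censored likelihoods and Bayesian inference
are explicitly out of scope). Real-data conclusions rest on the
packaged datasets and the goodness-of-fit engine instead.

## Known limitations

- The moment/PWM series representations are validated only on their
  integer-shape (finite) cases; for non-integer k with small λ they can
  fail the Cauchy criterion and raise — quadrature is the supported path.
- Standard errors on the five raw parameters are ridge-inflated by
  construction; only the identifiable triple has a stable sampling
  distribution.
- K-S p-values ignore parameter estimation (no Lilliefors-type
  correction), matching common applied practice but overstating
  p-values slightly when parameters are fitted to the same data.
- The TWPL/OLIW/EGMW competitor cdfs implement one documented parse of
  ambiguously typeset formulas; treat their fitted rows as indicative.
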