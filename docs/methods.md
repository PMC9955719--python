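# Methods

This document records the statistical methods implemented in `entrosim`,
the default parameter choices and why they were made, and the limits of the
approach. Equation-level references are to standard results in the
long-range-dependence literature (Beran's *Statistics for Long-Memory
Processes*; Richman & Moorman's Sample Entropy).

## 1. Model: ARFIMA(0, d, 0) fractional noise

A single family covers every process the package simulates. Fractionally
integrated white noise with difference order *d* ∈ ]−0.5, 0.5[ is a
stationary Gaussian process with autocovariance

```
gamma(0) = Gamma(1 - 2d) / Gamma(1 - d)^2
gamma(k) = gamma(k - 1) * (k - 1 + d) / (k - d)
```

equivalent to fractional Gaussian noise (fGn) in its long-run scaling. Its
lag-1 autocorrelation is d / (1 − d). Cumulatively summing an fGn series
yields fractional Brownian motion (fBm), the nonstationary half of the
family. The scaling exponent α unifies both:

- stationary (fGn): α = (2d + 1) / 2 = d + 0.5 ∈ ]0, 1[
- nonstationary (fBm, simulated by integration): α = d + 1.5 ∈ ]1, 2[

α = 0.5 is uncorrelated noise, α > 0.5 persistent, α < 0.5 anti-persistent,
and α = 1 the 1/f boundary between the families. α = 1 itself is not
representable (it would require d = 0.5) and is approached from below via
α = 0.99.

### Exact simulation

Two exact Gaussian samplers share the closed-form autocovariance:

- **Durbin–Levinson** (default for N ≤ 2048): O(N²) recursive
  conditional sampling; compiled with numba.
- **Circulant embedding** (N > 2048): the autocovariance sequence is
  embedded in a circulant matrix whose eigenvalues come from one FFT;
  for this model the embedding is nonnegative definite, so the method is
  exact, at O(N log N).

Both are validated in the test suite by ensemble covariance checks at fixed
indices against the closed form. Simulated fGn is standardized (mean 0,
SD 1, population convention) after generation; fBm series are the cumulative
sum of the fGn, standardized afterwards. Standardization order matters for
entropy at extreme persistence (see §7).

Per-replicate seeds are derived with `numpy.random.SeedSequence`
(`child_seed(master, *key)`), masked to stay below 2³¹ so they remain valid
for every downstream RNG and file format.

## 2. Whittle estimation and stationarity classification

The difference order is estimated by minimizing the profile Whittle
objective over the periodogram ordinates λ_j = 2πj/N, j = 1 … ⌊(N−1)/2⌋:

```
Q(d) = log( mean_j I_j / g_j(d) ) + mean_j log g_j(d),
g_j(d) = |2 sin(lambda_j / 2)|^(-2d)
```

`fit_d` runs a 41-point grid presearch followed by bounded Brent refinement
on [−0.5 + ε, 0.5 − ε], making the minimizer effectively global; it is
scale- and location-invariant by construction.

**Classification.** Nonstationary series push the bounded estimate onto the
upper boundary. A fit is declared *nonconverged* when the estimate lands
within 0.01 of the boundary (d̂ ≥ 0.489). The difference-and-refit
procedure is then:

1. Fit *d* to the series as given. If converged → label **stationary**,
   α̂ = d̂ + 0.5.
2. Otherwise difference the series, refit, and label **nonstationary**,
   α̂ = d̂_diff + 1.5.

At N = 1000 this misclassifies ≤ 5% of series at α = 0.9 or 1.1 and splits
roughly 50/50 at α = 0.99, exactly the behavior expected from the
asymptotic SD of d̂, √(6 / (π² N)) ≈ 0.025 at N = 1000.

## 3. Detrended fluctuation analysis

`dfa_alpha` implements evenly spaced average DFA: integrate the
mean-centered series, split it into non-overlapping forward windows of size
n, linearly detrend each window, pool the residual RMS per n, average
log₁₀ F(n) within k evenly spaced bins of log₁₀ n, and regress the binned
means on log₁₀ n. Defaults: n from 10 to N/4; k = 26, 37, 47 at
N = 250, 500, 1000 (interpolated otherwise). DFA is retained as an
independent cross-check; it is unbiased but roughly twice as variable as
the Whittle estimate at these lengths.

## 4. Sample Entropy

SampEn(m, r, τ) = −ln(A/B), where B counts pairs of length-m templates
(delay τ, Chebyshev distance, no self-matches) within tolerance r·SD, and A
the pairs still matching at length m + 1. Both template lengths use the
same index range i = 1 … N − mτ so A ≤ B always. Defaults m = 1, r = 0.25,
τ = 1 — the working point at which the package's study results were
established. B = 0 returns NaN (undefined), never infinity.

The largest observable value for given (N, m, τ) is

```
max_sampen = ln(N - m*tau - 1) + ln(N - m*tau) - ln 2
```

(one A match against the maximal B count); 13.12 at N = 1000, m = τ = 1.
`normalize_sampen` divides by this bound, mapping SampEn to [0, 1] for
comparisons across record lengths — raw SampEn means are nearly constant in
N while the bound grows, so normalized entropy decreases with N by design.

For iid Gaussian input the m = 1 expectation has the closed form
−ln(2Φ(r/√2) − 1) ≈ 1.964 at r = 0.25, recovered by the generator +
estimator chain within Monte-Carlo error.

## 5. Contamination and remedies

**Injection.** `contaminate` perturbs k = ⌈0.01·N⌉ distinct uniformly chosen
samples (3, 5, 10 at N = 250, 500, 1000) by adding z · 3 · (max − min) with
z standard normal. This inflates the sample SD, hence the tolerance r·SD,
and typically biases SampEn downward by 25–40% on stationary series.

**Detection.** Scaled MAD = 1.4826 · median|x − median(x)|; samples beyond
5 scaled MADs are flagged — a deliberately conservative threshold with a
near-zero false-positive rate on clean Gaussian fGn. The report carries
`sd_ratio` = SD(unflagged)/SD(all).

**Remedies.**

- `adjust_r`: keep the data, use r·sd_ratio as tolerance. Residual mean
  bias ≤ ~5% for α < 1.5.
- `remove`: delete flagged samples. Residual mean bias ≤ ~1% for most
  α < 1.5 (see §7 for the α = 1.4 edge).
- `classify_remove`: classify the series first; if nonstationary, detect on
  the increments instead (a spike at position p produces two large
  consecutive increments; adjacent flags map back to the single position)
  and delete the mapped positions. This keeps removal effective across the
  whole α range, including strongly nonstationary series where raw-series
  MAD misses spikes riding on large excursions.

### Design note: classification input under contamination

`clean_with_classification` classifies a *spike-suppressed copy* of the
series (increment-based detection and removal) rather than the contaminated
series as given, then applies the chosen branch to the original data. The
reason is empirical and structural: 1% spikes at 3× peak-to-peak add a
white-noise floor to the spectrum that pulls the bounded exact-spectrum
Whittle estimate into the interior, so contaminated fBm would otherwise be
labeled stationary almost always and the classification-guided remedy would
silently degenerate to plain removal (with > 15% bias at α = 1.8).
Suppressing the spikes before classification restores essentially perfect
labels on contaminated data and keeps the remedy's residual bias ≤ ~1.2%
across the full α grid. The branch actions and outputs are unchanged.

## 6. Study harness

`StudyConfig` + `run_study` generate deterministic Monte-Carlo studies:

- **estimation**: Whittle-α and DFA-α recovery over the α × N grid.
- **classification** / **classification_fine**: proportion labeled
  nonstationary; the fine grid defaults to α = 0.71 … 1.29 (step 0.01,
  excluding 1.00).
- **outlier**: percent bias of SampEn vs the same realization's
  uncontaminated baseline, per remedy condition; undefined values are
  excluded from means and counted.
- **discrimination**: SampEn as a function of α (an inverted-U peaking at
  α = 0.5).
- **normalization**: raw vs bound-normalized SampEn across N.
- **sweep**: one-at-a-time sweeps of m, r, τ.

Default grids (α ∈ {0.1 … 0.9, 0.99, 1.1 … 1.9}, N ∈ {250, 500, 1000},
100 replicates; 500 on the fine grid) are package choices that set the
scale at which the shipped results were validated; all are overridable via
YAML or keyword arguments. Everything is single-CPU and seeds every
replicate from the master seed.

## 7. Limitations

- **Extreme persistence is generator-sensitive.** At α = 1.9, N = 1000 the
  mean SampEn is ~0.02 with our exact generator; published values from
  approximate (truncated-filter) ARFIMA generators can differ by factors
  approaching two in this corner, because the entropy there rests on a
  handful of template matches and is acutely sensitive to the simulated
  low-frequency tail and to the order of standardization (standardizing
  before vs after integration changes the value severalfold). Treat
  absolute SampEn values at α ≳ 1.8 as generator-specific.
- **Plain removal near the family boundary.** With detection on the raw
  series, the `remove` remedy retains a small systematic positive bias
  (~1.3% at α = 1.4, N = 1000) — the regime `classify_remove` exists for.
- **The Whittle fit assumes the ARFIMA(0, d, 0) spectrum.** Short-memory
  contamination (AR/MA structure) biases d̂; the estimator is quasi-MLE
  only under the fitted model.
- **α = 1 is unreachable** in the simulator (d = 0.5 is outside the
  stationary region); boundary behavior is studied via α = 0.99.
- **max_sampen bound at m·τ + 1 ≥ N** is undefined and raises; series must
  exceed (m + 1)·τ samples for SampEn at all.
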