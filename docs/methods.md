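# Methods

## The generator

Each simulated dataset is a two-group sample from a *p*-dimensional
multivariate normal. Baseline feature means μ₁…μ_p are drawn i.i.d. from
Gamma(κ = 50, θ = 1/50), giving intensities centred near 1 with SD ≈ 0.14
across features — a stand-in for the spread of baseline abundances in a
normalized omics table. The covariance is block diagonal: three
compound-symmetry blocks σ²[(1−ρ)I + ρJ] of `block_size` features each,
then `noise_count` independent features; σ² = 1 throughout, so the
planted shifts Δ are on Cohen's d scale. Twelve features are differential
(four per block, shifts 0.2 / 0.5 / 0.8 added to the group-2 mean). The
remaining block members are "correlated non-null": correlated with
differential features but with no shift of their own. Their selection
rate is tracked as its own metric family and never folded into Type I
error, which is defined exclusively on the independent noise features.

Sampling uses the one-factor representation of compound symmetry
(x = √ρ·z + √(1−ρ)·e with a shared z per sample and block), which is
exactly equivalent to a Cholesky draw of the block and avoids
materializing the p×p covariance at p = 2050.

Fixed conventions, immaterial by exchangeability but stated for
reproducibility: the differential features are the first four indices of
each block, and the shift is added to group 2. The generator does not
emulate non-normal noise, missing values, batch effects, heteroscedastic
features or more than two groups — passing tests say nothing about those
aspects of real data, only about the correlation/effect-size/sample-size
trade-offs the grid varies.

## The two selectors

**ANOVA screen.** Two-group one-way F-tests computed directly from sums
of squares (df 1, n−2), vectorized across features; p-values from the F
survival function. A feature with zero within-group variance gets F = ∞,
p = 0 if the group means differ, else F = 0, p = 1. BH adjustment is the
step-up procedure (sort, scale by m/i, cumulative minimum from the
largest rank, cap at 1); it is applied to one feature family per call, so
stratified adjustment (e.g. per ionization mode) is expressed by calling
it per stratum. Selection is strict inequality at the threshold. Note BH
is *not* idempotent — re-adjusting an adjusted vector rescales by m/i
again — so adjusted p-values must be computed from raw ones only.

**Elastic-net logistic regression.** The solver is written from scratch
(numba kernel): for each λ on a geometric path from
λ_max = max_i |(1/n)·x_iᵀ(y − ȳ)| / max(α, 0.001) down to
λ_max·`lambda_min_ratio` (0.01 when n < p, else 1e-4; 100 points), an
outer IRLS loop builds the weighted quadratic approximation
(w_j = p_j(1−p_j), probabilities clamped to [1e-5, 1−1e-5]) and an inner
cyclic coordinate descent solves it with soft-thresholding, denominator
v_i + λ(1−α), unpenalized intercept, warm starts, and an active-set
strategy (full sweep → iterate the non-zero set → confirming full
sweep). λ_max carries a 1e-9 relative nudge so floating-point rounding
cannot leak a 1-ulp non-zero coefficient at the top of the path.
Features are standardized to unit (population) variance before fitting
and coefficients returned on the original scale. Convergence is
max_i v_i·(Δβ_i)² < 1e-7; a per-λ cap of 10⁵ sweeps marks
non-convergence on the fit rather than raising.

Cross-validation: seeded unstratified shuffle into 10 folds (a shuffle
leaving a training split one-classed is redrawn, 10 attempts); held-out
binomial deviance on the common λ grid; λ chosen by the
one-standard-error rule by default ("min" available) — the one-SE choice
mirrors the coefficient-extraction default of the standard R
implementation, which the solver was checked against during development.
Selection is exact non-zero coefficients at the chosen λ; at α = 0
nothing is thresholded, so all p features are selected by construction.

The test suite verifies the solver against independent oracles: a FISTA
proximal-gradient minimizer of the identical objective (agreement 1e-4),
the unpenalized Newton–Raphson MLE at λ → 0 (1e-3), KKT
stationarity/subgradient conditions at every path point, and
monotonicity of the recorded penalized objective across solver cycles.

## Metrics and the harness

Per replicate, each method's boolean selection is cross-tabulated with
ground truth: power per Δ (mean over that block's four differential
features), Type I error (mean over noise features), and
correlated-non-null selection per block. Estimates average the
per-replicate proportions; the Monte-Carlo SE is the between-replicate
SD divided by √R — replicate-level aggregation, because features within
a replicate are correlated by design and pooled Bernoulli counts would
understate the error.

Seeds form a hierarchy base → scenario → replicate → CV folds via
`numpy.random.SeedSequence` with a CRC of the scenario id, so any single
replicate is re-runnable in isolation and results are independent of
execution order. A method failure on one replicate is logged with its
child seed and excluded from that method's aggregation only.

The standard grid is 20 scenarios (layouts (35, 100) and (350, 1000) ×
ρ ∈ {0.4, 0.8} × n ∈ {10, 20, 30, 50, 100}) with an optional extension
(n ∈ {200, 500, 1000} at the large layout, ρ = 0.4). The grid runner
writes per-scenario CSVs as they complete and can resume, plus a tidy
combined CSV and a manifest with the config hash and base seed.

## Problem sizes

The package's own reproduction runs (acceptance script and test suite)
use 100–200 replicates per scenario rather than 1000: every reported
quantity is a proportion, so 200 replicates put the Monte-Carlo SE at
binomial scale (≤ 0.5/√200 ≈ 0.035 for power; far smaller for
noise-feature rates, which also average over 100–1000 features), well
inside the margins the checks assert. The full 1000-replicate,
20-scenario, 11-α sweep is a configuration value
(`GridSpec(replicates=1000)`), not a different code path.

## Known limitations

* The real-data path consumes a generic wide table; instrument-level
  processing (peak picking, QC blank filtering, identification) is out
  of scope.
* CV folds are unstratified; at n = 10 a held-out fold can be
  one-classed (its deviance is still well defined), and the guard only
  enforces two-classed training splits.
* Exact per-feature reproduction of any particular published RNG stream
  is impossible; only distributional structure is reproduced, which is
  what the metrics depend on.
* The λ = 0 limit with n ≤ p is allowed but warned about: the
  unpenalized MLE need not exist under separation.
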