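# Methods

This note records the statistical models implemented in `altrec`, the
numerical choices behind the solvers, what the simulator does and does not
emulate, and the known limitations. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Data model

Observed data per subject: episodes `(X_ij, Y_ij, Δ^X_ij, Δ^Y_ij)`,
`j = 1..m_i`, where episodes before the last are fully observed
(`Δ^X = Δ^Y = 1`), the last Type II gap is always censored (`Δ^Y = 0`), and
the last Type I gap is censored when follow-up ends during it. Follow-up
`C_i` is reconstructed exactly as the subject's total observed time
`Σ_j (X_ij + Y_ij)` — exact because the final Type II gap is censored at the
end of follow-up. The *effective episode count* `m*_i = m_i − 1` for
`m_i ≥ 2` (else 1) restricts all estimating sums to fully observed episodes
while weighting subjects by `1/m*_i`, which corrects the informative number
of episodes (frail subjects with short gaps contribute more episodes).

Validation enforces the structural rules (nonnegative gaps, consecutive
integer episode numbers, indicator patterns, at least one uncensored
episode) and additionally rejects a zero gap with an uncensored indicator,
because the regression model works on log gaps. Subjects with missing values
are dropped whole, with a logged count. Three error messages are contractual
strings relied on by the CLI: `Error: Data not cleaned`,
`Error: Time-varying covariates not allowed`, and
`Error: Max Iterations reached. Did not converge.`

## Nonparametric estimators

The joint CDF estimator integrates the weighted jump process of total gaps
against the product-limit survival of the total gap evaluated at the left
limit (realized exactly as the `Π_{l<k}` prefactor over strictly earlier
jump times); ties among jump times are aggregated into a single jump mass.
Estimates are flagged missing — never extrapolated — beyond the censoring
support, estimated as `τ̂_c = max_i C_i`. (The largest subject follow-up is
the natural estimate of `sup{t : G(t) > 0}`; using the largest total gap
instead would wrongly exclude points that are estimable, e.g. the upper
corner of the toy fixture.)

The weight `a_i` is 1 (default) or `C_i`; the two choices estimate the same
population CDF with different efficiency, which the tests check by agreement
on large simulated samples.

The conditional CDF uses the difference form
`[F̂(v2, y) − F̂(v1, y)] / [Ŝ_X(v1) − Ŝ_X(v2)]`, which targets
`Pr(Y ≤ y, v1 < X ≤ v2) / Pr(v1 < X ≤ v2)` at population level; the
single-bound conditional is the special case `v1 = 0`. Because numerator and
denominator are estimated separately the raw ratio can leave `[0, 1]` in
finite samples; the returned CDF is clipped and the raw value kept in a
diagnostic field.

Standard errors are a subject-level bootstrap (default 200 replicates,
seeded): whole trajectories are resampled with replacement, duplicates
becoming distinct subjects; intervals are normal-quantile on the probability
scale, clipped to `[0, 1]`. Closed-form influence-function variances are not
implemented (their components are defined only in external work); the
bootstrap is the package's variance route, with the default grid for the
joint CDF being deciles of the observed uncensored gaps.

## AFT regression

### Smooth U-statistic method (`lee`, default)

Estimating equations sum over ordered subject pairs the covariate difference
`A_i' − A_i` times episode-averaged kernel comparisons
`Δ · O_L(observed, pairwise-transformed) / Ĝ(observed ∧ L)`, with
`O_L(s,t) = log(min(max(t,s), L)) − log L` and `Ĝ₁`, `Ĝ₂` Kaplan–Meier
estimates of the censoring survival built from first-episode data with
censoring treated as the event (via lifelines). The Type I equation depends
on `β₁` alone and is solved first; the Type II equation is then solved with
`β₁` plugged in. The equations are monotone (each term has the form
`A g(A'b)` with `g` non-decreasing), so a damped Newton iteration with
central-difference Jacobian (`h = 1e-5 · max(1, |b_k|)`), backtracking line
search, and a hybrid-Powell fallback reliably reaches residuals below the
default tolerance `1e-8`.

Trimming bound: `L` defaults to the largest *uncensored* first-episode total
gap and is automatically reduced to stay strictly below the first time
either censoring KM reaches zero, keeping every inverse weight finite. Both
`L` and the KM inputs are overridable.

Variance: sandwich `Σ̂⁻¹ Ω̂ Σ̂⁻ᵀ`. The bread `Σ̂` is the numerical Jacobian
of the stacked equations at the fit (block lower-triangular: the Type I
block does not depend on `β₂`). The middle `Ω̂` is a subject-level bootstrap
(default 200 replicates) of the estimating functions at the fitted
coefficients; the pairwise kernels are precomputed once, so a bootstrap
replicate is a cheap index-gather, with the censoring weights held fixed. A
`full_bootstrap=True` option refits the whole estimator per resample
instead. On simulated data the two routes give standard errors within a few
percent of each other, so the fast sandwich is the default.

Finite-sample calibration: at the designed study size (n = 150) Wald
z-statistics for the Type II coefficients are mildly over-dispersed
(standard deviation ≈ 1.1–1.2), giving measured 95% CI coverage of roughly
90–94% per coefficient; at n = 400 the statistics are indistinguishable from
standard normal and coverage is nominal. This is a finite-sample property of
the inverse-censoring-weighted U-statistic pipeline, not a variance-estimator
defect: the sandwich SEs were verified against full refit-bootstrap SEs, and
recomputing the censoring KM inside the bootstrap or enlarging the Jacobian
step changes nothing. Users needing exact small-sample calibration should
increase n or bootstrap the full fit.

### Rank-based method (`chang`)

Gap times are transformed to the baseline covariate level,
`X̃⁰ = X e^{−A'b₁}`, `Z̃⁰ = X e^{−A'b₁} + Y e^{−A'b₂}`, and truncated at the
transformed residual follow-up `C e^{−A'b₁} − Σ_{l<j} Z̃_il`; the truncated
running sum telescopes to `min(cumsum Z̃⁰, C e^{−A'b₁})`, which is how it is
computed. When `b₁ ≠ b₂` this cap can cut an episode that was fully
observed on the original scale; such episodes are *artificially censored*:
their transformed event indicator is switched off while they remain in the
risk sets. Without this, the Type II estimating function is not centered at
the truth (its outer terms would count censored comparisons as events),
which simulation at n = 600 makes obvious.

The estimating functions center each subject's covariate against the
at-risk weighted mean (`S₁/S₀`) over transformed times, scaled `n^{−1/2}`.
They are step functions: the smallest achievable residual is the jump
resolution, of order `n^{−1/2}`, so the convergence tolerance defaults to
`4/√n` on the sup norm — a fixed tiny tolerance would declare every fit
failed. Solving minimizes `‖U‖²` by Nelder–Mead from five starts (origin,
`±0.5`, two seeded uniform draws) inside a box `|b_k| ≤ 3` (log gap-time
ratios beyond `e³ ≈ 20` are outside any plausible application, and the
statistic degenerates there), and candidate roots must retain at least half
the original events under artificial censoring — at extreme parameters the
truncation censors every comparison and the statistic vanishes identically,
creating spurious roots. Among admissible candidates the smallest residual
wins. A constant covariate makes the equations vanish for every `b`; this is
reported as nonconvergence (no informative root exists).

Variance: perturbed-estimating-equation resampling. Replicate `r` solves
`U(b) = u*_r` with `u*_r = n^{−1/2} Σ_i G_i φ_i(β̂)`, where `G_i` are i.i.d.
standard normal subject multipliers and `φ_i` the per-subject summands of
`U` at the fit — this puts the perturbation on the scale of the statistic's
own sampling noise (an identity-covariance perturbation would routinely be
unreachable by the step function). Replicates warm-start at the fit; more
than 20% nonconvergent replicates aborts with advice to use the smooth
method. The empirical covariance of replicate solutions is the variance
estimate.

### Equivariance

Both methods depend on covariates only through differences or risk-set
centering. For the smooth method, location shifts leave all coefficients
unchanged and rescaling a covariate by `k` divides its coefficients by `k`,
exactly (to solver precision, `1e-6`). For the rank-based method these
identities are exact at the level of the estimating *function* (the Type I
statistic under a common transformation scale; tested to `1e-12`), but the
solver returns any point of the nonsmooth near-root region, so solver-level
agreement holds at the root-region resolution rather than machine precision;
the Type II statistic mixes the two transformation scales and its shift
invariance is only approximate.

## Simulator

The generator draws, per subject and in a documented order from one seeded
generator: `a1 ~ Bernoulli(0.5)`, `a2 ~ Uniform(0, 1)`, a bivariate normal
frailty pair, `C ~ Uniform(0, τ_c)`, then error pairs in blocks of eight
until the cumulative latent total exceeds `C` (one extra pair is retained
for oracle tests). Censoring truncation follows the observed-data
construction exactly, including the degenerate `(0, 0, 0, 0)` last row when
follow-up ends exactly at an episode boundary.

Scenario `"1.1"` defaults: frailty mean 1.1, variance 0.25, correlation 0.5;
error SD 0.5; `n = 150`, `β₁ = (0.5, 0.5)`, `β₂ = (0, −0.5)`, `τ_c = 63`.
The frailty/error values are the package's calibration choice: they put the
average first-pair censoring rate at `τ_c = 63` at ≈ 15%, the design figure
for this scenario, and give lognormal-shaped gaps with within-subject
correlation — a realistic shape for care/break durations. All fields are
overridable.

What the simulator does *not* emulate: discrete (day-resolution) times and
the resulting ties (real registries need the small-quantity jitter the
validator suggests), covariate-dependent censoring, time-varying covariates,
non-uniform censoring laws, and heavy-tailed or skewed frailty laws. Passing
tests therefore certify the estimators under a correctly specified
continuous AFT model with independent uniform censoring — not robustness to
those violations.

## Numerical conventions

- Ties in transformed times and risk sets use exact float comparisons with
  `≥`; input jitter for same-day events is the user's responsibility.
- Episode ordering is taken from sorted `(id, episode)`, never input order.
- Zero gaps are admitted only with a zero indicator (fully truncated rows).
- All resampling (bootstrap, Parzen-type, simulator) is driven by
  `numpy.random.default_rng` with caller-supplied seeds; identical seeds
  give bit-identical results.
- Problem sizes in the test suite (e.g., 100 simulation replicates at
  n = 150 for recovery and coverage, 500 datasets for the censoring-rate
  calibration, brute-force oracles at n ≤ 6) are the package's chosen
  balance between Monte-Carlo resolution and a test suite that runs in a
  few minutes.

## Limitations

- The marginal distribution of Type II gaps is not identifiable (induced
  dependent censoring) and is deliberately not offered.
- Closed-form asymptotic variances for the nonparametric estimators and for
  the smooth-method sandwich components are not implemented; resampling
  stands in for them throughout.
- The rank-based method inherits the usual pathologies of nonsmooth
  estimating functions (non-unique near-roots, resampling cost, possible
  nonconvergence); the smooth method is the recommended default.
- Wald coverage at n ≈ 150 runs a few points below nominal for Type II
  coefficients (see above); intervals are asymptotically exact.
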