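# Methods

## Model

Each ROI is represented by two observed variables: the series `A` and a
lag-1 copy `A_lag` (each time point advanced by one). A directed edge
A → B expands to three free paths — `A → B`, `A_lag → B_lag`, and
`A → B_lag` — and every node has an autoregressive path `A → A_lag`.
The `A_lag → B_lag` coefficient is the connectivity-strength measure:
it captures the influence of A on B after delayed effects and
autocorrelation have been accounted for.

The path system is parameterized as a RAM: an asymmetric coefficient
matrix `A` over the `p = 2n` variables and a diagonal residual matrix
`S`, with implied covariance `Σ(θ) = (I−A)⁻¹ S (I−A)⁻ᵀ`. Residual
covariances among the unlagged (exogenous-block) variables are fixed at
zero, not free; this is what makes the free-parameter count per cohort
`3·E + n + 2n` (three paths per edge, `n` autoregressive paths, `2n`
residual variances) and reproduces the reference degrees of freedom
(9 nodes, 6 cohorts: null model df 864; 13-edge model df 630 from
6·171 moments − 396 parameters).

Cohorts are fitted as a multigroup model. By default all parameters are
free per cohort (the mode used for cohort-trend analysis; the pooled
multigroup χ² is the sum of per-cohort contributions, each scaled by
`N⁽ᵍ⁾−1`). An equality-constrained mode (all parameters shared across
cohorts) is available for single-model summaries.

## Estimation

The discrepancy per cohort is the Wishart ML form
`F = ln|Σ(θ)| − ln|S| + tr(S Σ(θ)⁻¹) − p`, with `χ² = Σg (N⁽ᵍ⁾−1) F̂g`.

Two routes:

- **Recursive models, free grouping** (the common case, including every
  model the specification search visits): the Gaussian likelihood of an
  acyclic path system with uncorrelated residuals factorizes into one
  conditional regression per endogenous variable, so the exact ML
  solution is computed equation-by-equation from the sample covariance
  (no iteration; observed gradient max-norms ~1e−14).
- **Non-recursive variants and equality constraints**: L-BFGS-B with
  the analytic RAM gradient (`∂F/∂A = 2(I−A)⁻ᵀ W Σ` restricted to free
  cells, `W = Σ⁻¹ − Σ⁻¹S Σ⁻¹`), start values of 0.1 for paths and the
  sample variances for residuals, residuals bounded below at 1e−8,
  ftol 1e−14 / gtol 1e−8, up to 500 iterations and 5 seeded restarts.

Standard errors come from the inverse expected information,
`acov(θ̂) = 2 H⁻¹/(N−1)` with `H_ij = tr(Σ⁻¹ Σ_i Σ⁻¹ Σ_j)` (block per
cohort in free mode, summed across cohorts under equality constraints).
A simulation test confirms the reported SEs match the sampling spread
of the estimator within ~30%.

Bidirectional candidate edges are resolved empirically: the
non-recursive variant (both direction triples present, a feedback loop)
and every unidirectional orientation are fitted and ranked by RMSEA,
then CFI — mirroring how ambiguous meta-analytic edges are adjudicated
in practice.

## Fit indices

- `RMSEA = sqrt(max(χ²−df, 0)/(n·df))` with `n` the total sample size
  across cohorts. The 90% CI solves `Φ(χ² | δ, df) = 0.05` (upper) and
  `= 0.95` (lower) for the noncentrality δ of the noncentral χ²
  distribution (Brent root-finding, tolerance 1e−10 relative; δ clamped
  at 0 when the equation has no root), bounds `sqrt(δ/(n·df))`.
  Per-cohort RMSEAs treat each cohort as fit alone (`n = N⁽ᵍ⁾`,
  per-cohort df). Saturated models (df ≤ 0) report RMSEA 0.
- `BCC = χ² + 2q·[Σg b⁽ᵍ⁾p(p+3)/(N⁽ᵍ⁾−p−2)]/[Σg p(p+3)]` with
  `b⁽ᵍ⁾ = N⁽ᵍ⁾`. The denominator as printed in the reference
  (`Σ b⁽ᵍ⁾(p+3)`) would make the penalty vanish at large N and cannot
  reproduce the reference BCC−χ² gaps of ≈2q; the corrected form
  reproduces them to <0.1% and the printed form is available behind
  `printed_denominator=True`.
- `CFI = 1 − max(χ²−df,0)/max(χ²null−dfnull, χ²−df, 0)`, with the
  independence model (all 2n variables uncorrelated, variances free) as
  the baseline; its χ² has the closed form `Σg (N⁽ᵍ⁾−1)(Σi ln Sii − ln|S|)`.
- AIC and BIC are included for reporting.

## Specification search

The search starts from the null model (auto paths only). Per iteration:

1. **Modification indices.** For every absent directed edge, the three
   candidate paths are scored at the restricted optimum by the
   univariate score test `MI = (N−1) g² / (2·h)`, where `g` is the
   discrepancy gradient for the fixed parameter and `h` its effective
   information after partialling out all free parameters
   (`h = H_cc − H_cf H_ff⁻¹ H_fc`). Cohort contributions add; the
   edge-level MI aggregates its three paths by sum (a `max` option
   exists). The MI is a quadratic lower-bound estimate of the refit χ²
   improvement; the suite checks it against brute-force refits at the
   score-test's 25% tolerance.
2. **Candidates.** The top five unordered region pairs by MI are each
   fitted as full three-path additions in both orientations (up to 10
   fits).
3. **Acceptance.** The single best addition by BCC is accepted if it
   improves the current BCC (ties broken by lower RMSEA, then
   lexicographic edge label).
4. **Stopping.** The search ends when the per-cohort RMSEA 90% upper
   bound is ≤ 0.08 for at least ⌈G/2⌉ cohorts, when no candidate
   improves the BCC, or at a 25-edge cap (an overfitting guard).

The search is deterministic given the covariances and settings.

## Synthetic data generator

Panels are generated from the structural VAR

```
y_t = C y_t + (L + diag(a)) y_{t−1} + ε_t ,   ε_t ~ N(0, diag(σ²))
```

solved per time step through the reduced form
`y_t = (I−C)⁻¹(L+diag(a)) y_{t−1} + (I−C)⁻¹ ε_t` — contemporaneous
effects are resolved exactly by matrix inversion, matching the
simultaneous-equation semantics of the SEM. Stationarity (spectral
radius of the reduced-form transition < 1) is checked for every
cohort's coefficient set and violations fail loudly, naming the cohort.
The stationary covariance solves the discrete Lyapunov equation
`Σ = MΣMᵀ + Q`, which doubles as the independent oracle for sample
moments, implied covariances and fitted parameters in the test suite.
Defaults: 200 burn-in steps (discards initial-condition transients so
the stationary oracles apply), independent unit-variance Gaussian
innovations (what ML covariance fitting assumes of standardized data),
an even male/female split per cohort, and optional multi-ROI spike
artifacts injected after generation in units of the clean series SD.

The packaged DMN scenario uses the published 13-edge topology with the
decade-k coefficient of each edge as the cohort-k contemporaneous
(`A_lag → B_lag`-analog) coefficient, cross-lags zero, and a lag-1
autoregression of 0.6 for every node — chosen because lag-1
autocorrelation explaining ≈36% of variance (a² = 0.36) is the reported
magnitude for resting-state BOLD. Scenario sizes default to 6 cohorts ×
20 subjects × 600 time points: the cohort structure and subject count
follow the reference design, while the series length is set so that
parameter-recovery experiments have per-coefficient standard errors
near 0.01 and finish in seconds on one CPU.

Two deliberate properties of this scenario matter for interpretation:

- **Standardized-scale ground truth.** The published coefficients are
  standardized estimates of an imperfectly fitting model; no process
  can have exactly those structural coefficients *and* unit stationary
  variances (the innovation-variance calibration system has negative
  solutions — `calibrate_unit_variance` checks and refuses). Since the
  pipeline standardizes every series before fitting, the recoverable
  ground truth for a path A → B is `C[B,A]·sd(A)/sd(B)` under the
  stationary law, provided by `standardized_coefficients`. Parameter
  recovery is asserted against these values (78/78 edge×cohort cells
  within 3 SE at the default scenario size).
- **An exogenous-block misfit floor.** The unified SEM models the
  unlagged block as a DAG with independent residuals, but the true
  stationary marginal of a VAR has richer structure, so even the
  generating 13-edge model retains a population discrepancy
  (per-cohort RMSEA ≈ 0.075 here). Consequently the 0.08 stopping rule
  ends the specification search at 11–12 accepted edges — one to two
  generating edges short, with exactly one substitute edge absorbing
  shared variance — and this endpoint is reproduced with exact
  population covariances, i.e. it is a property of the study
  conditions, not of sampling noise. With the RMSEA stop disabled the
  search recovers all 13 generating edges before the BCC stalls.

What passing tests on this generator do *not* show about real data: no
hemodynamic blurring or scanner noise model, Gaussian innovations by
construction, linear-in-cohort drift only, and spike artifacts as
idealized additive impulses.

## Preparation stages

- **Spike censoring.** A time point is artifactual when its
  point-to-point change exceeds the threshold ladder 7 SD in ≥2 ROIs,
  6 in ≥3, 5 in ≥4, 4 in ≥5, or 3 in ≥6 ROIs, in units of the
  subject's full-series per-ROI SD (single pass, so the mask depends
  only on the input). Of the two endpoints of a qualifying jump, the
  one farther from the series mean (averaged over offending ROIs) is
  censored, so an impulse artifact is censored exactly once; a `level`
  mode applies the ladder to deviation-from-mean directly.
- **Standardization** to mean 0, variance 1 per subject × ROI over
  uncensored points, population (divisor-n) convention; the choice of
  divisor is a pure rescaling and immaterial downstream.
- **Lagged pairs** are formed within subjects only and never span a
  censored point; cohort sample sizes `N⁽ᵍ⁾` count pairs. Cohort
  covariances use divisor `N⁽ᵍ⁾−1`, matching the `(N⁽ᵍ⁾−1)` χ² scaling.
- **AR-order assessment** fits successively higher-order AR models per
  ROI (least squares on within-subject lagged rows pooled over
  subjects) and reports incremental variance explained, to justify the
  lag-1 truncation.

## Trend analysis

Per-cohort `A_lag → B_lag` coefficients are correlated with the cohort
axis (default index 1..G; Pearson r is affine-invariant, so index and
mean-age axes agree). Significance is the two-sided t test with G−2 df
at α = 0.05 (for G = 6, |r| ≥ 0.811); significant edges are classed
rising/falling and grouped by receiving node to expose paired
rising+falling inputs. Sex-split trends refit per cohort × sex and flag
edges significant in exactly one sex. Per-subject coefficients are
available but secondary — single-subject standard errors are an order
of magnitude larger than cohort-level ones. The chance level of
agreement between two edge sets over the same nodes is the exact
hypergeometric tail over the `C(n,2)` undirected pairs, evaluated in
rational arithmetic.

## Numerical notes and limitations

- Sample covariances must be positive definite; non-PD input raises.
  A singular `(I−A)` during fitting raises an error naming the
  feedback loop with unit gain.
- The χ² statistic treats the N lagged pairs as independent
  observations although consecutive pairs share a time point; at short
  series lengths (T ≈ 150) this inflates the mean null χ²/df by
  ~10–15%, decaying to 1 as T grows (measured: 1.10 at T=151, 1.02 at
  T=501, 0.99 at T=2001). The reference analyses inherit the same
  approximation.
- Modification indices are quadratic approximations; they can
  marginally exceed the refit improvement for far-from-null parameters
  (observed ratios 0.77–1.13).
- RMSEA CI inversion residuals are < 1e−6 in the defining CDF
  equations.
- No latent variables, mean structures, Bayesian or spectral
  estimation, Granger causality, backward pruning, or neuroimaging
  (NIfTI) ingestion: inputs are delimited-text ROI panels.
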