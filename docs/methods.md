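# Methods

## The model and the problem

Retention in gradient reversed-phase HPLC is modelled as a linear QSRR,
`t_R = α₀ + Σ_k α_k x_k + ε`, over K named molecular descriptors. Ordinary
least squares (the *control* model) minimizes the unweighted squared
retention error; it is agnostic to whether close peaks come out in the
right order. The package's core re-optimizes the full coefficient vector
(intercept included) against the pair of relative errors

- `f₁ = %RMSE(t_R) = 100·√(mean(((t̂−t)/t)²))` over the training analytes,
- `f₂ = %RMSE(order)`, the same functional applied to 1-based elution
  ranks, computed within the evaluated subset only.

Because both metrics divide by the observed value, early-eluting analytes
dominate: a swap between ranks 1 and 2 costs ~79%, the same swap between
ranks 97 and 98 costs ~1%. That emphasis is deliberate — early parts of a
gradient are the most crowded — and it also means `f₂` can exceed 100% for
badly scrambled orders.

Some published statements of this metric omit the square and the root;
interpreted literally that is a *signed relative mean*, which can be
negative and cannot reproduce the error magnitudes reported for the case
studies. The default therefore implements the standard relative RMSE; the
signed-mean form is retained as `rmse_variant="signed_mean"` purely for
auditing, and `validate_config` warns when it is active.

## Train/test splitting

`kennard_stone_split` implements the classical max–min algorithm in
autoscaled (zero-mean, unit-variance) descriptor space: the two mutually
farthest points seed the training set, then each added point maximizes its
minimum distance to the selected set. Ties break toward the lowest row
index, making the split a pure function of the table. The training size is
`round(ratio·n)` with half-up rounding; the default ratio is 0.70. MLR is
fit on *raw* descriptors so the coefficients remain comparable to published
descriptor models; only the selection geometry is autoscaled.

## The multi-objective stage

No multi-objective optimizer library is assumed; the GA is implemented in
`eluorder.moo`:

- **Ranking**: fast non-dominated sorting plus crowding distance
  (NSGA-II-style), binary tournament selection, (μ+λ) elitist truncation.
- **Variation**: simulated binary crossover (η=15, pair probability 0.9,
  per-gene exchange 0.5) and polynomial mutation (η=20, per-gene
  probability 0.2). The coefficient space is unbounded, so mutation steps
  are scaled per gene by `init_spread · max(|α_k^MLR|, 10⁻³)` instead of by
  box bounds.
- **Seeding**: the initial population is the MLR vector plus
  `population_size − 1` Gaussian perturbations at the same per-gene scale
  (`init_spread` default 0.1). Seeding the control into an elitist
  population guarantees the final front contains a point that weakly
  dominates the control — the improvement direction reported for the
  published case studies holds here *by construction*, at any generation
  count.
- **Defaults**: population 100, generations 200. On a 70-analyte training
  set a full run takes well under a second; tests use smaller budgets.
- Individuals with non-finite objectives are assigned infinite objectives
  (worst rank) and the run continues; an all-non-finite population raises.

Objectives are always evaluated on the training set; test-set metrics are
reported afterwards and never optimized, to avoid selection leakage.

**Knee point**: objectives are min-max normalized over the front to [0,1]
and the knee is the point closest (Euclidean) to the ideal corner (0,0),
ties toward lower f₁. **Selection**: among front points whose relative f₁
increase over the control is at most `max_tr_loss_percent` (default 10%,
the published working bound), the one with minimal f₂ is selected (ties
toward lower f₁); if none is feasible the minimal-f₁ point is returned.
Since the control is always weakly dominated, the feasible set is never
empty for a non-negative bound, and the selected solution never has a worse
order error than the control. Front solutions are numbered by ascending f₁.

## Applicability domain

The Williams plot pairs each analyte's leverage
`h = x'(X'ₜᵣX ₜᵣ)⁻¹x` (training design with intercept) with its
standardized residual (residual divided by the *training* residual sample
SD — the simplest reading of "standardized"; no leave-one-out
studentization). Warning limits are the critical leverage and ±3 SD. The
default critical leverage is `h* = 3(K−1)/N` with K counting the model
variables *including* the intercept (K=4 for three descriptors), matching
the case-study convention; `leverage_formula="k_plus_1"` switches to the
common `3(K+1)/N` with K = number of descriptors. For K=1 the default
formula degenerates to 0 and a warning is emitted. When a fit is exact to
rounding noise (residual magnitudes below 10⁻⁹ of the retention scale) the
residuals are treated as zero rather than standardized by a machine-epsilon
SD, which would manufacture spurious outliers.

## SRD and the CRNN null

`srd_value` defaults to the sum of absolute rank differences (Spearman
footrule), normalized by its permutation maximum (`n²/2` even n,
`(n²−1)/2` odd n) to SRD% in [0,100]. SRD is often described with squared
differences, but the published case-study null statistics this package is
validated against (XX1 59.0, median 66.1, XX9 73.2 at n=98) match the
footrule null — whose mean is `(n²−1)/3` raw, i.e. ≈66.7% of the maximum —
and are incompatible with the squared variant (null median 50%). Squared
mode (maximum `n(n²−1)/3`) is available via `srd_mode="squared"`.

The CRNN validation draws uniformly random permutations (ranking i.i.d.
random numbers yields exactly this) and reports the 5th/50th/95th
percentiles of their SRD%; 100 000 draws put the Monte-Carlo quantile
noise near 0.05 points. A model ranking below XX1 is flagged significantly
better than random. For n ≤ 8 an exhaustive enumeration over all n!
permutations serves as the exact oracle.

## Synthetic data

`generate_linear_dataset` draws descriptors from an equicorrelated
multivariate normal (default pairwise correlation 0.3–0.4) and adds
Gaussian noise to the exact linear response. The heteroscedastic option
scales each row's noise SD by `t_true/mean(t_true)`, emulating the larger
deviations seen at the retention extremes while keeping the average noise
at `noise_sd`. Rows with non-positive retention are redrawn (up to 1000
batches) rather than truncated, preserving the linear-Gaussian structure;
an infeasible scale raises.

Preset shapes: 62 analytes (organics-like; retention ≈15±3.5 min, noise
1.3 min homoscedastic) and 98 analytes (peptides-like; retention ≈30±12
min, noise 3.5 min heteroscedastic). Both put the control model's
%RMSE(t_R) inside the 8–25% band reported for the real case studies
(measured 8–16% across seeds). What the generator does *not* emulate —
skewed and structurally collinear real descriptor distributions,
nonlinearity of retention at low t, column physics — bounds what a green
test establishes: correctness of the algorithms and metrics under the
model's own assumptions, not chromatographic realism. Notably, on
heteroscedastic synthetic data the re-optimized model can beat the control
in *both* objectives (MLR minimizes absolute, not relative, error); on the
real case-study tables the published trade-off is a modest retention-error
increase bought for a large order-error decrease.

## Numerical conventions

- Elution ranks are 1-based; ties in retention break by original row order
  (stable sort), so ranks are always a permutation and runs are
  deterministic.
- Kennard–Stone, GA and CRNN are pure functions of their seeds; the CLI
  threads one root `--seed` through all stages and records it in the run
  summary.
- Pareto fronts deduplicate exact objective-space duplicates (first
  occurrence kept); along the stored front f₁ strictly increases and f₂
  strictly decreases.
- CSV I/O preserves row order and round-trips floats exactly
  (`float_precision="round_trip"` on read).

## Known limitations

- Only linear QSRR; no regularization or nonlinear learners.
- Two objectives exactly; the knee rule (min distance to normalized ideal)
  is fixed, not configurable.
- The applicability domain offers only the Williams plot (no distance-to-
  model or kNN domains).
- Reproduction of the published per-column error tables requires the
  original case-study descriptor/retention data, which are not
  redistributed here; the pipeline accepts them as plain CSV when
  available.
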