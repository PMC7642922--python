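# Methods

## Models

### Penalized Poisson regression (`countgs.glm`)

One count trait at a time is modelled as `y.i ~ Poisson(mu.i)` with
`log mu.i = eta + x.i'beta`, where the predictor vector concatenates
one-hot environment dummies, the line's 0/1 marker genotypes and,
optionally, every environment×marker product column. The fitted objective
is the Poisson negative log-likelihood with the constant `log y!` dropped,

    L(eta, beta) = sum_i [mu.i − y.i log mu.i]
                   + n·λ [ (1−α)·½‖beta‖₂² + α‖beta‖₁ ],

with the intercept unpenalized. Scaling the penalty by `n` makes a λ value
mean the same thing across sample sizes (the per-observation convention of
the common lasso-path solvers). The printed form of this penalty in some
reports nests the brackets differently; we use the standard elastic-net
form because only it yields ridge at α = 0 and lasso at α = 1.

**Optimization.** Iteratively reweighted least squares: at the current
linear predictor `z`, weights `w = mu` and working response
`u = z + (y − mu)/mu` define a penalized weighted least-squares problem,
solved by cyclic coordinate descent with soft-thresholding (a numba-jitted
kernel; the linear predictor is clamped to ±30 before exponentiation).
For α = 0 the inner problem has no L1 part and is solved directly as a
ridge-augmented normal system. A step-halving line search between the old
and proposed iterates keeps the penalized objective monotone
non-increasing; convergence is declared when the objective change falls
below `tol·(|L|+1)` (default `tol = 1e-7`) or parameters move < 1e-8.

**λ path and selection.** The automatic grid is 100 log-spaced values from
λ_max (the smallest λ that zeroes every coefficient; for α = 0 the
α = 0.001 value is used) down to 10⁻³·λ_max, fitted with warm starts. The
path stops early once a fit explains > 99.9 % of the null deviance or an
extra step improves the deviance ratio by < 10⁻⁴ — saturated p > n fits at
tiny λ are expensive and never win the cross-validation. λ is chosen by
K-fold CV (default 10) on the mean held-out Poisson deviance, at the
minimum with ties going to the larger λ (no 1-SE rule). The final model is
refitted on all data at the selected λ.

**Degenerate input.** An all-zero response has no finite MLE on the log
scale; the fit returns `eta = log(0.5/n)`, `beta = 0`, flagged on the
result.

### Poisson deep network (`countgs.nnet`)

A fully connected feedforward network with 1–4 ReLU hidden layers and an
exponential output activation per trait, so predictions are strictly
positive rates. The loss is the mean over observations of the per-trait
Poisson NLL summed over traits (traits equally weighted), plus an L1
penalty on all weight matrices (biases excluded). With one output the
multivariate computation *is* the univariate model — the univariate front
end is a thin wrapper over the same code path, so the reduction is exact
by construction and verified bit-for-bit in tests.

Everything is plain numpy: manual backpropagation (ReLU subgradient 0 at
exactly 0; L1 subgradient 0 at 0), Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-7),
inverted dropout on hidden activations during training only, mini-batches
reshuffled per epoch, and early stopping on a seeded 20 % validation split
with best-epoch weight restoration (default patience 50). During training
the output layer's net input is clipped at 30 (with a warning) to prevent
overflow; inference is unclipped. All randomness flows from one seed, so
training is bit-reproducible.

## Evaluation protocol (`countgs.evaluation`)

Fivefold cross-validation over line×environment cells: each fold holds out
20 % of cells for testing; a seeded 20 % of the remaining cells is the
tuning set, giving 64/16/20 TRN/TUN/TST. Because cells (not lines) are
partitioned, a line can be trained in some environments and predicted in
others — the sparse-trial scenario the protocol mimics.

Networks are tuned per depth by grid search (candidate units × L1 × dropout;
fixed batch size, learning rate, epoch budget), trained on TRN with early
stopping, scored by tuning-set MSE (averaged over traits for the
multivariate family; ties keep the earliest grid entry), and the winner is
refitted on TRN∪TUN. The two reference grids are 5 unit counts × 2 L1
values (batch 273) and 4 × 2 × 2 with dropout (batch 500). Penalized
regressions are fitted per trait on TRN∪TUN with inner 10-fold CV for λ.

Metrics on each fold's test set, per trait: MSE; MAAPE = mean
arctan|(y−ŷ)/y| with the conventions 0 when y = ŷ = 0 and π/2 when y = 0,
ŷ ≠ 0 (the bounded limit of the arctangent); APC = Pearson correlation
within each environment, averaged unweighted over environments, skipping
slices with < 2 points or zero variance (NaN if all are degenerate).
Bootstrap SEs resample (y, ŷ) pairs 500 times (stratified within
environments for APC). Metrics are computed per fold and averaged over
folds; SEs are the mean over folds of per-fold bootstrap SEs; environments
are averaged within fold before folds are averaged. Report tables carry
one row per (model, trait) plus an across-trait "Average" row (exact mean
pre-rounding; files are written at 3 decimals). Every run records, per
(model, fold), exactly which rows were fitted on and which were predicted;
`MetricReport.check_no_leakage()` audits that no model ever saw its own
test rows.

Percent superiority of the best (smaller-is-better) value over the worst is
`(worst − best)·100/best`. The reference benchmark tables in
`countgs.benchmarks` store only per-trait rows; averages and superiority
figures are recomputed, using decimal half-up rounding (the convention of
printed tables — banker's rounding would turn 50.5555 into 50.555) and,
for the MSE ratio, the best value additionally rounded to 1 decimal as in
the reported arithmetic.

## Synthetic data (`countgs.simulate`)

For trait t, line i (marker vector x.i), environment e:

    log mu.iet = eta.t + x.i'beta.t + gamma.et + delta.iet
                 [+ c·( (x.i'beta.t)² − mean over lines ) if nonlinear]

with markers Bernoulli(f.j), f.j ~ U(maf_range); `n_causal` shared causal
positions whose effect vectors across traits are correlated via a Gaussian
copula (correlation acts on the genetic signal, not the Poisson noise, so
counts stay conditionally independent Poisson); environment effects and
line×environment deviations Gaussian; `y ~ Poisson(mu)`. A configuration
whose maximum log-rate exceeds 20 is rejected as mis-specified. One root
seed spawns independent child streams for markers, effects and noise, so
changing one component leaves the others bit-identical. The quadratic term
is the simplest mechanism a deep network can exploit and a log-linear GLM
cannot.

The two benchmark presets reproduce the shapes of the wheat disease-count
data sets (182×1635×3×2 and 438×11617×6×3 = 2628 observations) with
intercepts and effect scales chosen so counts are right-skewed with mode
near zero and maxima below ~70 (data set 1) or concentrated in 0–5 with
maxima below ~20 (data set 2). The generator does not model linkage
disequilibrium, pedigree structure or overdispersion; passing tests
therefore speak to the estimators under ideal Poisson sampling with
independent markers, not to every property of field data.

## Reduced-scale claim checks (`countgs.experiments`)

Two qualitative comparisons are run at desk scale (sizes chosen for a
single CPU; all seeds derived from one root):

* **Multivariate vs univariate networks** — 300 lines × 500 markers × 3
  environments × 2 traits, trait correlation 0.6, quadratic coefficient
  0.5, intercept log 3, genetic-score sd 0.3 (counts mean ≈ 4, max ≈ 20).
  Both families use 2 hidden layers × 64 units, L1 10⁻³, Adam up to 600
  epochs with patience 60; APC is averaged over three seeded 80/20 splits
  per seed (the split-averaged form in which fold-averaged results are
  reported). In our runs the multivariate network wins only about half the
  seeds: with equal capacity and symmetric training, joint fitting of two
  0.6-correlated traits confers no reliable APC advantage at this scale.
  The corresponding acceptance check is therefore expected to fail, and we
  report the measured win count rather than force it.
* **Regression vs network on linear data** — 200 lines × 200 markers × 3
  environments × 2 traits, no quadratic term; CV-lasso per trait against
  the same multivariate network. The regression wins essentially always
  (10/10 seeds in our runs), as expected when the GLM is correctly
  specified.

Supporting numerical checks: a central-finite-difference audit of
backpropagation over 100 random topologies (depths 1–4, T ∈ {1, 3}),
redrawing networks whose pre-activations sit within 10⁻³ of a ReLU kink;
and CV-lasso recovery of 5 ±0.3 effects among 20 standard-normal
predictors at n = 1000 (mean corr(β̂, β) ≳ 0.99).

## Numerical conventions and limitations

* Linear predictors are clamped to ±30 before exponentiation in the GLM,
  and network output net inputs to ≤ 30 during training only.
* Marker QC: markers with minor-allele frequency < 0.05 (on observed
  calls) or missingness above threshold are dropped; remaining missing
  calls are imputed by the observed allele frequency thresholded at 0.5,
  keeping the matrix binary and deterministic.
* Markers enter models as raw 0/1 columns (no relationship-matrix
  eigendecomposition); optional centering/scaling is deliberately left out
  of the default path since the inputs are already bounded.
* Grid-search ties keep the first grid entry; CV-λ ties keep the largest λ.
* The package fits networks on CPU in numpy; it is meant for data of the
  benchmark scale (10²–10⁴ observations), not for image-style inputs or
  very large cohorts.
* GPR is univariate by design (one fit per trait); no multi-response
  covariance is estimated — the multivariate network shares hidden layers
  but likewise estimates no trait covariance matrix.
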