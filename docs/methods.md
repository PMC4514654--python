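# Methods

## Linearized steady-state model

Gene dynamics are modelled as dx_i/dt = f_i(x_1, …, x_n; θ_i) with θ_i a
kinetic parameter reachable by external perturbation.  At a stable
equilibrium, the direct effect of gene j on gene i is the log-to-log
derivative u_ij = ∂ln x_i / ∂ln x_j; a first-order expansion of the
equilibrium condition links the relative steady-state changes
φ_j = Δx_j/x_j across an experiment through Σ_{j≠i} u_ij φ_j ≈ φ_i.
Stacking m experiments yields the per-gene regression Φ α_i = b with Φ
the m×(n−1) matrix of relative changes of the other genes and b the
target gene's column.  The model assumes (i) perturbations small enough
for the linearization to hold, (ii) the system re-equilibrates before
measurement, and (iii) perturbations used for gene i do not act through
f_i itself.  For knockout designs the package therefore excludes, by
default, the row in which the target gene itself was deleted from that
gene's regression (its φ_i = −1 is an intervention, not a response); the
flag `exclude_target_knockout` switches this off.

Because regulatory in-degree distributions are heavy-tailed, α_i is
treated as sparse and estimated by stagewise sparse recovery rather than
dense regression.

## Degree prior

In-degrees follow a truncated power law on {1, …, n}: mass ∝ k_min^−γ
for k ≤ k_min and ∝ k^−γ above, normalized over the support.  Note the
flat head: with k_min = n the law degenerates to the uniform over
{1..n}, not to a point mass.  Defaults k_min = 1, γ = 2.5 give a mean
in-degree ≈ 1.9 at n = 100, i.e. ≈ 1.9 % of off-diagonal cells are true
edges — the class imbalance that motivates precision-recall scoring.

## The synthetic benchmark

The generator emulates a linear network A₀X₀ = B₀: A₀ is m×n with
entries uniform on [1, 10] (optionally on [−10, −1] ∪ [1, 10]); each
column i of X₀ draws a degree k from the prior, places k nonzeros at
uniformly random non-self rows, and draws signed magnitudes uniform on
[−2, −ρ_a] ∪ [ρ_a, 2] with ρ_a = 10⁻⁵; the observed A and B add i.i.d.
N(0, σ²) noise to A₀ and A₀X₀ respectively.  The self entry is always
zero, matching the regression's exclusion of the target column.  A
single seed drives four ordered sub-streams (degrees, locations,
magnitudes, noise), so identical seeds give bit-identical instances.

What the generator does **not** emulate: nonlinear saturation,
non-Gaussian or correlated measurement error, feedback-induced
correlations between Φ and the noise, and hidden confounders.  Passing
benchmarks here therefore demonstrates correctness of the estimation
machinery under the stated linear-Gaussian conditions, not performance
on real expression compendia.

## SmOMP

Each stage s of SmOMP, starting from x₀ = 0, r₀ = y on a column-normalized
Φ:

1. Matched filter c = Φᵀr.  Coordinates already selected are excluded
   (their correlations are zero by residual orthogonality).
2. Null-scale estimate σ₁ by outlier deletion: iterate the zero-mean ML
   standard deviation of the retained coefficients, deleting |c| > t·σ,
   until the relative change falls below ε (default 10⁻³) or nothing is
   deleted.  **Deliberate bias:** the solver uses the raw truncated-ML
   value.  Its downward bias (factor √g(t), g(t) = 1 − 2tφ(t)/(2Φ(t)−1))
   keeps the stage threshold tracking the shrinking residual, which is
   what sustains candidate flow in later stages; with a
   truncation-corrected (consistent) estimate the solver stalls on empty
   candidate sets in oversampled regimes and loses its advantage over
   plain StOMP at high δ.  The standalone estimator
   `estimate_null_sigma` defaults to the corrected, consistent variant
   for use as a measurement tool.
3. Hard threshold: candidates are the free coordinates with
   |c| > t·σ₁.  The multiplier t comes from false-alarm control,
   t = z_{1−α₀/2} with α₀ = (m−k)/(S(n−k)) (k unknown: k_hint, default
   0) or a user-supplied α₀, clamped into [2, 3] *after* the quantile.
   For overdetermined systems the formula leaves (0, 1); the solver then
   falls back to the clamp floor, which is where the raw quantile would
   be clamped anyway.
4. Nonnull fit and TPR: Gaussian ML (mean, ML sd) on the **absolute**
   values of the candidate correlations — the single-mean nonnull model
   cannot represent signed effects, and the TPR integral is stated on the
   folded variable — then β = Q((tσ₁−μ)/σ₂) + Q((tσ₁+μ)/σ₂), clipped
   into (0, 1].  σ₂ is floored at 10⁻¹² so β stays defined for
   single-candidate stages.
5. Projection and refinement: least squares on the enlarged support
   (previous support ∪ candidates), then keep the ⌊k_s·β⌋ candidates of
   largest projected amplitude (never fewer than `min_keep` = 1, so a
   stage with candidates cannot stall; ties break to the lower index),
   update the support, re-solve least squares on it, refresh the
   residual.

Stopping: stage cap S (default 10), relative residual below 10⁻⁶·‖y‖, or
an empty candidate set.  The support is additionally capped at m
coordinates (keeping the largest correlations) so least-squares
sub-problems stay determined; sub-solves use a dense SVD-backed `lstsq`
(problem sizes ≤ ~10³), with rank deficiency handled by the
pseudo-inverse.  If σ₁ collapses to zero (noise-free stages where the
residual is orthogonal to every free column), the threshold falls back
to a machine-epsilon scale so remaining true coordinates are still
selected.  Coefficients are reported on the caller's original column
scaling.

**StOMP** differs in exactly two ways: the null scale is the single-pass
zero-mean ML sd of all free coefficients (the ‖r‖/√m convention was
evaluated and is noted as an alternative; the ML variant reproduces the
expected solver ordering), and every thresholded candidate joins the
support.

**TLS** is the classical estimate from the right singular vector of
[Φ b] at the smallest singular value, rescaled so the b-component is −1;
a vanishing b-component raises a non-generic-problem error.  It is dense
— no sparsification — and serves as the baseline.

## Preprocessing: normalization and common-mode removal

Φ columns are divided by their ℓ₂ norms (scales recorded; coefficients
and ranking scores are mapped back to the original scale, so response
variance is not conflated with effect size).  With measurement entries
uniform on [1, 10] every column shares a large mean direction (pairwise
column correlation ≈ 0.8 after normalization), which violates the
zero-mean null premise of the mixture model — the matched-filter
coefficients all concentrate around a large common value and no
coordinate crosses the threshold.  The inference drivers therefore
row-center Φ and b by default before solving.  Centering is an exact
operation on the model (projecting both sides of Φα = b onto the
complement of the all-ones direction preserves the equation) and is a
no-op for designs that are already zero-mean.  It is exposed as
`center=` on `infer_network` / `solve_linear_model` and off by default
in the lower-level `build_gene_problem`, whose contract is
normalization only.

## Evaluation protocol

- Confusion counts run over off-diagonal cells with |value| > `zero_tol`
  (default 10⁻⁸) treated as edges; the false-sign count FS is reported
  but plays no role in presence-only rates.
- ROC/PR curves scan all distinct score thresholds with tied scores
  grouped.  AUROC is the trapezoid over (FPR, TPR) — identical to the
  tie-corrected Mann–Whitney statistic; AUPR uses step-wise achievable
  precision (no linear interpolation), the appropriate choice under the
  ~2 % edge prevalence of these networks.  Averaged curves across trials
  use vertical averaging on a 201-point uniform grid.
- Permutation p-values: the upper-tail frequency of the metric under
  uniformly random orderings of the potential links against the same
  gold standard, with add-one smoothing so p > 0 and the combined score
  −½ log₁₀[(∏p_AUROC)^⅕ (∏p_AUPR)^⅕] stays finite.
- Error/bias convergence: per data length, mean squared error
  (1/M)Σ‖x̂⁽ʰ⁾−x‖² and squared bias ‖(1/M)Σx̂⁽ʰ⁾−x‖² over M replicates.
- Phase experiment: for each (δ, ρ) cell, m = round(δn),
  k = round(ρm), Gaussian Φ with unit columns, k-sparse x with signed
  magnitudes uniform on [1, 2]; success is relative ℓ₂ error below 10⁻³
  (recovery at these sizes is either essentially exact or grossly wrong,
  so the exact cutoff is uncritical).  Cells with k < 1 or k ≥ m after
  rounding are flagged NaN.  Each cell draws from its own seeded
  sub-stream, so results are independent of grid layout.

## Problem sizes and defaults

The shipped benchmark experiment uses n = 100 genes, m = 1000
experiments, noise sd 2.0, α₀ = 0.3 and 50 trials (≈ one minute on one
CPU); the small-sample configuration uses m = 80 with sd 0.3 (a second
stated value, 0.1, is equally exposed — the source material reports both
for the same experiment, so neither is hard-coded).  The phase grid runs
at n = 200 with 50 trials per cell over δ ∈ {0.25, 0.5, 0.75, 1} and
ρ ∈ {0.1, …, 0.6}.  These sizes were chosen so the entire study runs on
a laptop while keeping binomial/trial standard errors small relative to
the effects of interest.

## Known limitations

- The two-component Gaussian mixture is only an approximation for
  coherent designs; the common-mode removal above is required for
  heavily positively-correlated measurement matrices.
- Edge direction between two genes whose responses are exactly
  proportional is not identifiable from steady-state data alone;
  knockout designs resolve this through the target-knockout exclusion.
- TLS assumes i.i.d. errors in all columns; column normalization of a
  noisy matrix distorts that structure, which is partly why the dense
  baseline trails the sparse solvers on the benchmark's precision-recall
  axis.
- No time-series inference, no nonlinear ODE simulation, and no
  asymptotic phase-boundary calculation — the phase diagram here is
  strictly empirical.
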