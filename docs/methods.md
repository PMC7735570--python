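# Methods

## The problem

Two feature matrices are measured on the same n samples: an *output* set
X (n × p) and an *input* set W (n × q). Both may be high-dimensional
(p, q ≫ n): SNP panels at two densities, expression vs. methylation, and
so on. The quantity of interest is the proportion of variance of vectors
in the linear span of X, L_X = {Xα}, that can be explained by linear
regression on W — an R² that is deliberately *not* symmetric in X and W
(if X's columns are a subset of W's, W explains all of X but X explains
only part of W).

Least-squares multivariate ANOVA is unusable when q > n, and
regularized methods (PLS, sparse CCA) answer a prediction question, not a
variance-decomposition question. The approach here instead treats each
probe vector z ∈ L_X as the response of a Gaussian random-effects model:

    z = 1μ + Wβ + ε,   β ~ iid N(0, σβ²),   ε ~ iid N(0, σε²),

equivalently z = 1μ + u + ε with u ~ N(0, K σβ²), K = WW′. With the
columns of W centered and scaled so that mean(diag K) = 1 (see *Scaling*),
R² = σβ²/(σβ² + σε²) is the proportion of the variance of z captured by
regression on W. Variance components are estimated by restricted maximum
likelihood (REML).

Two estimators aggregate over L_X:

* **MC-ANOVA** — draw B random weight vectors α_s, form x_s = Xα_s, fit
  each, and summarize the sequence {R²_s} (mean, median, SD, quantiles).
  The default weight distribution is iid standard normal; a sparse variant
  (exactly k non-zero weights) mimics simple "traits" built from few
  features and widens the R² distribution without moving its center.
* **Eigen-ANOVA** — take the left-singular vectors u_i of the
  (standardized) X, fit each, and combine with eigenvalue weights:
  R² = Σ d_i² R²_{u_i} / Σ d_i². Vectors with small d_i often produce
  corner fits (R̂² = 0), which is the known source of this estimator's
  downward bias when the true shared variance is high; corner fits are
  kept in the weighted sum because dropping them would change the
  estimator.

A cross-validated PLS baseline (`pls_r2`) is included for comparison: X on
W with 1..100 components, 10-fold CV on pooled held-out squared error,
refit at the CV-argmin count, training R² reported. It is a baseline, not
a recommendation — component selection by prediction accuracy biases it
low at low shared variance and (on spectrally concentrated panels) high at
high shared variance.

## The REML engine

The intercept is absorbed by restricting to the orthogonal complement of
the ones vector. We build an explicit orthonormal basis C of that
complement (a Householder reflector), eigendecompose C′KC = V diag(ξ) V′,
and map back U = CV: m = n − 1 eigenpairs, each exactly orthogonal to 1,
robust to rank-deficient kernels. For a response z, the rotated vector
η = U′(z − z̄) makes the restricted log-likelihood a one-dimensional
function of the variance ratio δ = σε²/σβ²:

    RL(δ) = ½[ m log(m/2π) − m − m log Σ_s η_s²/(ξ_s + δ) − Σ_s log(ξ_s + δ) ],

with σ̂β² = m⁻¹ Σ η²/(ξ + δ̂) and R² = 1/(1 + δ̂). The eigendecomposition
is computed once per input layer and reused across every response (random
vectors, singular vectors, user traits) — the O(n³) step is paid once, and
each additional response costs O(n²) for the rotation plus an O(m · G)
scan.

Maximization over δ: a shared log-spaced grid (log₁₀ δ ∈ [−8, 8], step
0.02) evaluated for all responses of a batch as one matrix product, then
bisection on the score (dRL/dδ) inside the bracketing grid cells down to
~1e-14 in log₁₀ δ. Unit tests and the acceptance suite verify the result
against an exhaustive grid at step 0.001 (within 1e-6 in RL) and against a
canonical dense 2-parameter REML optimizer (this was done during
development on rank-deficient and full-rank kernels; the shipped oracle is
the dense grid). Because the bracket collapses far below reporting
precision, R̂² is invariant to rescaling or shifting the response to well
under 1e-8.

Boundary handling: δ pinned at 1e-8 is reported with `boundary="at_one"`
(R² ≈ 1), at 1e8 with `"at_zero"` (R² ≈ 0). Corner solutions are data,
not errors — they are counted and surfaced in every result object.
Eigenvalues below 1e-12·ξ₁ are clipped to zero; a raw eigenvalue below
−1e-8·ξ₁ is a hard error (the kernel is not PSD).

## Scaling conventions

* `unit_variance`: column mean 0, sample SD 1 (denominator n − 1). Used
  for output sets before forming span vectors, so no single high-variance
  feature dominates every random trait.
* `span_scaled`: column mean 0, then divide by the population SD
  (denominator n) and by √q. This makes the per-column sum of squares
  exactly n/q and mean(diag WW′) exactly 1 — the normalization under
  which σβ² reads as "variance of z captured by W". The two denominators
  differ deliberately: the kernel-diagonal identity is exact only with the
  population SD, and it, not the per-column SD convention, carries the R²
  interpretation.

Responses are centered but never variance-scaled (R² is scale-invariant;
rescaling would be an undocumented transformation).

## Synthetic marker panels

`synth_markers` generates the stand-in for a real genotype panel. Per
haplotype, a latent AR(1) Gaussian chain with parameter `ld_rho` runs
along the markers; marker j carries the minor allele where the latent
value is below the quantile of its target MAF, drawn uniform in
`maf_range`. Dosage is the sum over `ploidy` haplotypes. Defaults: n =
599, p = 1,279, ploidy 1 (inbred 0/1 codes), maf_range (0.05, 0.5),
ld_rho 0.5 — the shape of a classic wheat inbred-line panel, with
moderate adjacent-marker LD.

What the generator reproduces: discreteness of genotype codes, a MAF
spectrum, monotone-decaying adjacent-marker correlation. What it does
not: long-range LD, family/population structure, and in particular the
*spectral concentration* of real breeding panels, whose kernels
concentrate much of their variance in the top few dozen eigenvalues and
may be effectively rank-deficient. Three consequences, all verified
numerically and worth stating plainly because they bound what passing
tests show about real data:

1. With a full-rank synthetic kernel, an exact-span response (X = W)
   yields R̂² ≈ 0.99 rather than exactly 1: the restricted likelihood
   only diverges at the zero-noise corner when the kernel has (near-)zero
   eigenvalues, and otherwise δ̂ retains ordinary sampling noise.
2. Eigen-ANOVA's small bias at moderate truth depends on the spectrum:
   at true share 0.3 it averages ≈ 0.34 on the default panel and
   decreases toward ≈ 0.29 as ld_rho → 0.95.
3. The PLS baseline's training R² at high truth is far below its value on
   a concentrated panel, because 100 components of a flat 598-dimensional
   spectrum absorb only a fraction of the variance.

MC-ANOVA's unbiasedness, and the asymmetric variance decomposition of the
nested design, are insensitive to all of this — which is precisely the
argument for preferring MC-ANOVA.

## Simulation designs

* **Noisy copy**: X = W + δ with δ iid N(0, σδ²) on standardized columns
  and σδ² = (1 − r²)/r², so the true shared variance is exactly r²
  (r² = 0: X pure noise; r² = 1: X = W). The panel is fixed across
  replicates; only the noise is redrawn.
* **Nested**: X is a seeded uniform subset of p = round(f·q) marker
  columns; W = [X, Z] with q − p iid Gaussian filler columns, everything
  standardized. True share of W explained by X is p/q; of X explained by
  W is 1. The marker subset is fixed per scenario; Z is redrawn per
  replicate.

`run_study` runs scenario × replicate × method × direction, caches the
kernel eigendecomposition whenever the explanatory layer is constant
across replicates, and tabulates replicate means and SDs. Defaults: B =
300 random vectors per MC-ANOVA run (a few hundred suffice to pin down
mean, median and SD of the R² distribution) and 200 replicates per
scenario, which resolves replicate means to ~0.001 while keeping a full
study in minutes on one core. The test suite uses the same designs at
20–30 replicates (Monte Carlo SE ≈ 0.002, an order of magnitude below the
0.02 comparison bands) and exercises the PLS bias checks on a 200 × 400
panel because a single CV'd PLS fit at full scale costs minutes.

## Numerical and design choices

* Seeding: every stochastic component takes an integer seed; child seeds
  derive via `numpy.random.SeedSequence`, and each MC weight draw uses its
  own (seed, draw-index) substream, so draws are independent of execution
  order and any run is bit-reproducible.
* Sample alignment between layers is by identifier, order taken from X;
  unequal sample sets are an error unless explicitly allowed — silent row
  misalignment is the deadliest failure mode of two-matrix methods.
* Missing values are rejected with coordinates, never imputed.
* LD pruning is a greedy left-to-right pass against the most recently
  retained column; MAF filtering composes before pruning (a constant
  column has no correlation).
* Evenly spaced subsetting keeps 1-based indices
  round(1 + (j−1)(p−1)/(k−1)), j = 1..k, round-half-up: deterministic and
  endpoint-inclusive.
* A degenerate (constant) random span vector is resampled once and then
  raises — silent resampling loops would hide pathological inputs.
* Nested-design rounding is half-away-from-zero; the subset is uniform
  at random because no marker ordering should be privileged.

## Known limitations

* Single-kernel models only: no two simultaneous explanatory sets, no
  non-linear (RKHS) embeddings.
* REML only; no Bayesian posterior over variance components.
* Exact dense eigendecomposition/SVD: intended for n up to a few
  thousand samples.
* The synthetic panel generator does not emulate population structure or
  long-range LD; conclusions about estimator bias on strongly structured
  real panels should be drawn from the trends documented above, not from
  the defaults alone.
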