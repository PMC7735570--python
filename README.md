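# anovahd

**How much of one high-dimensional data layer lives in the linear span of
another?**

Modern genomic studies routinely hold several data layers for the same
samples — whole-genome SNPs and a low-density array, gene expression and
methylation, genotypes and image-derived phenotypes. A recurring question
is a variance-decomposition one: *what proportion of the variance of an
output layer X can be explained by regression on an input layer W* when
both layers have far more features than samples? Classical answers fail
here: MANOVA needs least squares (impossible for q > n), canonical
correlation is symmetric by construction (but the real relationship often
is not), and penalized regressions answer a prediction question whose
tuning biases variance estimates.

`anovahd` is for quantitative geneticists and multi-omics analysts who
need that number. It estimates, for vectors z in the span of X, the
random-effects model

    z = 1μ + Wβ + ε,   β ~ iid N(0, σβ²),   ε ~ iid N(0, σε²)

by single-kernel REML (K = WW′, scaled so mean diag K = 1), and reads off
R² = σβ²/(σβ² + σε²). Two estimators aggregate over the span:

* **MC-ANOVA** — B random span vectors x_s = Xα_s; reports the mean,
  median, SD and quantiles of {R²_s}. Nearly unbiased across the board;
  the recommended estimator. Sparse weight vectors (k non-zero entries)
  probe "simple-trait" architectures.
* **Eigen-ANOVA** — per-left-singular-vector R² of X combined with
  eigenvalue weights Σ d_i²R²_i / Σ d_i². Also yields the per-eigenvector
  R² profile (which directions of X are shared); biased downward when the
  true shared variance is high, because small-eigenvalue vectors hit
  R̂² = 0 corners.

A cross-validated PLS baseline, genotype QC (MAF filter, adjacent-LD
pruning, evenly spaced SNP subsetting), a synthetic marker-panel
generator, and a replicated simulation harness with known ground truth
are included. One kernel eigendecomposition is reused across all
responses, so thousands of REML fits cost seconds.

## Worked example

```python
from anovahd import (MarkerPanelSpec, synth_markers, center_scale_columns,
                     mc_anova, eigen_anova, sim_noisy_copy)
from anovahd.mc_anova import WeightSpec

panel = synth_markers(MarkerPanelSpec(n=300, p=600, seed=7))
W = center_scale_columns(panel, "unit_variance")
X = sim_noisy_copy(W, 0.5, seed=1)          # true shared variance: 0.5

mc = mc_anova(X, W, B=300, spec=WeightSpec(seed=2))
print(f"MC-ANOVA   mean R2 = {mc.mean:.3f}  (SD {mc.sd:.3f}, "
      f"95% band [{mc.q025:.3f}, {mc.q975:.3f}], corners {mc.boundary_count})")

ev = eigen_anova(X, W)
print(f"Eigen-ANOVA global R2 = {ev.global_r2:.3f}  "
      f"({ev.rank_retained} singular vectors, corners {ev.boundary_count})")
```

prints

```
MC-ANOVA   mean R2 = 0.492  (SD 0.115, 95% band [0.269, 0.691], corners 0)
Eigen-ANOVA global R2 = 0.525  (299 singular vectors, corners 181)
```

X was built as W plus entry-wise noise calibrated so each column shares
exactly half its variance with W. MC-ANOVA's mean over 300 random span
vectors recovers that truth (0.492); the spread of the 300 per-vector
estimates (SD 0.115) is the genuine vector-to-vector variation across the
span, not uncertainty in the mean. Eigen-ANOVA lands nearby (0.525) and
additionally reports that 181 of the 299 singular vectors — the
small-eigenvalue tail — were corner fits with R̂² = 0.

The same estimators run from the shell on delimited matrices or PLINK
`.raw` exports:

```
anovahd estimate --x expression.tsv --w methylation.tsv --method mc \
        --b 300 --seed 1 --out results/
anovahd qc --geno chip.raw --min-maf 0.005 --ld-prune 0.99 --out clean.tsv
anovahd subset --geno clean.tsv --format tsv --k 500 --out sparse.tsv
anovahd simulate --config study.yaml --out study/
```

Every run writes its resolved configuration next to its results, so any
output directory is reproducible from its own contents.

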