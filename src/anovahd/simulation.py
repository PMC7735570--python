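"""Synthetic marker panels and the two shared-variance simulation designs.

No external data is required: :func:`synth_markers` generates a marker
panel with the features that matter for the estimators — strictly discrete
dosage codes, a tunable minor-allele-frequency spectrum, and adjacent-marker
linkage disequilibrium (an AR(1) latent Gaussian per haplotype, thresholded
at each marker's MAF quantile). The default panel shape, 599 lines x 1,279
binary markers, mirrors a classic wheat inbred-line genotype panel.

Two designs with known truth sit on top of it:

* ``noisy_copy`` — X = W + iid Gaussian noise on standardized columns, with
  noise variance (1 - r2)/r2 so the true proportion of variance of X
  explained by W is exactly r2 (r2 = 0 makes X pure noise; r2 = 1 makes
  X = W).
* ``nested`` — X is a column subset of the panel and W = [X, Z] with Z iid
  Gaussian columns; after standardization the true share of W explained by
  X is p/q_total while the share of X explained by W is 1, a deliberately
  asymmetric decomposition.

:func:`run_study` runs any set of scenarios for any subset of the three
estimators and tabulates replicate means and SDs, caching the one kernel
eigendecomposition whenever the explanatory layer does not change across
replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data_model import (
    FeatureMatrix,
    GenotypeMatrix,
    center_scale_columns,
)
from .eigen_anova import eigen_anova
from .exceptions import InvalidFraction, InvalidSpec, ScalingRequired
from .mc_anova import DEFAULT_B, WeightSpec, mc_anova
from .pls_baseline import pls_r2
from .reml_core import build_kernel


def _child_seed(*parts) -> int:
    """Deterministic 31-bit child seed from integer parts."""
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] & 0x7FFFFFFF)


@dataclass(frozen=True)
class MarkerPanelSpec:
    """Shape and population-genetic knobs of a synthetic marker panel."""

    n: int = 599
    p: int = 1279
    maf_range: tuple = (0.05, 0.5)
    ld_rho: float = 0.5
    ploidy: int = 1  # 1 -> inbred 0/1 codes, 2 -> dosages 0/1/2
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise InvalidSpec("maf_range must satisfy 0 < low <= high <= 0.5")
        if not 0.0 <= self.ld_rho < 1.0:
            raise InvalidSpec("ld_rho must be in [0, 1)")
        if self.ploidy not in (1, 2):
            raise InvalidSpec("ploidy must be 1 or 2")
        if self.n < 3 or self.p < 1:
            raise InvalidSpec("need n >= 3 and p >= 1")


def synth_markers(spec: MarkerPanelSpec) -> GenotypeMatrix:
    """Generate a discrete marker panel with adjacent-marker LD.

    Per haplotype, a latent AR(1) Gaussian chain with parameter ``ld_rho``
    runs along the markers; marker j carries the minor allele where the
    latent value falls below the quantile of its target MAF (drawn uniform
    in ``maf_range``). Dosage is the sum over ``ploidy`` haplotypes.
    Monomorphic columns (possible at small n and low MAF) are re-thresholded
    by flipping the single most extreme latent value so every column is
    polymorphic. Deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    n, p, rho = spec.n, spec.p, spec.ld_rho
    mafs = rng.uniform(spec.maf_range[0], spec.maf_range[1], size=p)
    thresholds = norm.ppf(mafs)
    dosage = np.zeros((n, p), dtype=float)
    innov = np.sqrt(1.0 - rho * rho)
    for _ in range(spec.ploidy):
        latent = np.empty((n, p))
        latent[:, 0] = rng.standard_normal(n)
        eps = rng.standard_normal((n, p - 1)) if p > 1 else None
        for j in range(1, p):
            latent[:, j] = rho * latent[:, j - 1] + innov * eps[:, j - 1]
        dosage += (latent < thresholds[None, :]).astype(float)
    # guarantee polymorphism: flip the most borderline sample at any
    # monomorphic marker (deterministic, vanishingly rare at default sizes)
    col_mean = dosage.mean(axis=0)
    for j in np.flatnonzero((col_mean == 0.0) | (col_mean == spec.ploidy)):
        i = rng.integers(n)
        dosage[i, j] = spec.ploidy - dosage[i, j]
    ids = [f"m{j}" for j in range(p)]
    samples = [f"line{i}" for i in range(n)]
    return GenotypeMatrix(dosage, samples, ids, scaling_state="raw", ploidy=spec.ploidy)


def sim_noisy_copy(W: FeatureMatrix, true_r2: float, seed: int = 0) -> FeatureMatrix:
    """Noisy copy of a standardized layer with known shared variance.

    X = W + delta, delta iid N(0, (1 - r2)/r2) per entry, so the per-column
    R^2 of x on w is exactly ``true_r2``. ``true_r2=1`` returns W itself;
    ``true_r2=0`` returns pure unit-variance noise.
    """
    if W.scaling_state not in ("unit_variance",):
        raise ScalingRequired("sim_noisy_copy requires a unit_variance input layer")
    if not 0.0 <= true_r2 <= 1.0:
        raise InvalidSpec("true_r2 must be in [0, 1]")
    rng = np.random.default_rng(seed)
    shape = W.values.shape
    if true_r2 == 1.0:
        vals = W.values.copy()
    elif true_r2 == 0.0:
        vals = rng.standard_normal(shape)
    else:
        sigma_delta = np.sqrt((1.0 - true_r2) / true_r2)
        vals = W.values + sigma_delta * rng.standard_normal(shape)
    return FeatureMatrix(vals, W.sample_ids, W.feature_ids, scaling_state="raw")


def noise_variance(true_r2: float) -> float:
    """sigma_delta^2 such that 1 / (1 + sigma_delta^2) = true_r2."""
    if not 0.0 < true_r2 <= 1.0:
        raise InvalidSpec("true_r2 must be in (0, 1]")
    return (1.0 - true_r2) / true_r2


def nested_subset_indices(q_total: int, fraction: float, seed: int = 0) -> np.ndarray:
    """Seeded uniform column subset of size round-half-away(fraction * q)."""
    p = int(np.floor(fraction * q_total + 0.5))
    if p <= 0 or p >= q_total:
        raise InvalidFraction(
            f"fraction {fraction} yields p={p} of q_total={q_total}"
        )
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(q_total, size=p, replace=False))


def sim_nested(
    G: GenotypeMatrix,
    fraction: float,
    seed: int = 0,
    subset_seed: int | None = None,
):
    """Nested design: X a marker subset, W = [X, Z] with Gaussian filler.

    Both outputs are centered and unit-variance scaled, so the true share
    of the variance of W explained by X is p/q_total and the share of X
    explained by W is 1 (X is contained in W). ``subset_seed`` lets a study
    fix the marker subset across replicates while regenerating Z.
    """
    q_total = G.n_features
    idx = nested_subset_indices(q_total, fraction, seed if subset_seed is None else subset_seed)
    p = idx.size
    rng = np.random.default_rng(_child_seed(seed, 1))
    raw_x = G.values[:, idx]
    x_ids = [G.feature_ids[i] for i in idx]
    X = center_scale_columns(
        FeatureMatrix(raw_x, G.sample_ids, x_ids), "unit_variance"
    )
    Z = rng.standard_normal((G.n_samples, q_total - p))
    w_vals = np.concatenate([raw_x, Z], axis=1)
    w_ids = x_ids + [f"z{j}" for j in range(q_total - p)]
    W = center_scale_columns(
        FeatureMatrix(w_vals, G.sample_ids, w_ids), "unit_variance"
    )
    return X, W


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulation scenario: a design, its truth, and what to run."""

    design: str  # noisy_copy | nested
    true_r2: float | None = None  # noisy_copy truth
    fraction: float | None = None  # nested column fraction
    n_replicates: int = 200
    methods: tuple = ("mc",)
    directions: tuple | None = None  # default: design-appropriate
    B: int = DEFAULT_B
    weight_spec: str = "gaussian"
    n_nonzero: int | None = None
    max_components: int = 100
    folds: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.design not in ("noisy_copy", "nested"):
            raise InvalidSpec(f"unknown design {self.design!r}")
        if self.design == "noisy_copy":
            if self.true_r2 is None or not 0.0 <= self.true_r2 <= 1.0:
                raise InvalidSpec("noisy_copy requires true_r2 in [0, 1]")
        else:
            if self.fraction is None or not 0.0 < self.fraction < 1.0:
                raise InvalidSpec("nested requires fraction in (0, 1)")
        bad = set(self.methods) - {"mc", "eigen", "pls"}
        if bad:
            raise InvalidSpec(f"unknown methods {sorted(bad)}")

    @property
    def sigma_delta_sq(self) -> float | None:
        if self.design != "noisy_copy" or self.true_r2 in (None, 0.0):
            return None
        return noise_variance(self.true_r2)

    @property
    def label(self) -> str:
        if self.design == "noisy_copy":
            return f"noisy_copy:r2={self.true_r2:g}"
        return f"nested:frac={self.fraction:g}"


@dataclass(frozen=True)
class StudyTable:
    """Per-replicate estimates plus the mean (SD) summary table."""

    replicates: pd.DataFrame  # scenario, method, direction, replicate, estimate
    summary: pd.DataFrame = field(default=None)

    @staticmethod
    def from_replicates(rep_df: pd.DataFrame) -> "StudyTable":
        g = rep_df.groupby(["scenario", "method", "direction"], sort=False)["estimate"]
        summary = g.agg(
            mean_estimate="mean", sd_estimate="std", n_replicates="size"
        ).reset_index()
        return StudyTable(replicates=rep_df, summary=summary)


def _one_estimate(method, X, W, ke, scenario, rep_seed):
    if method == "mc":
        spec = WeightSpec(
            distribution=scenario.weight_spec,
            n_nonzero=scenario.n_nonzero,
            seed=rep_seed,
        )
        return mc_anova(X, W, B=scenario.B, spec=spec, ke=ke).mean
    if method == "eigen":
        return eigen_anova(X, W, ke=ke).global_r2
    return pls_r2(
        X,
        W,
        max_components=scenario.max_components,
        folds=scenario.folds,
        fold_seed=rep_seed,
    ).training_r2


def run_study(panel: MarkerPanelSpec, scenarios) -> StudyTable:
    """Run every scenario x replicate x method x direction; tabulate.

    The marker panel (the input layer of the noisy-copy design) is fixed
    across replicates; only noise and filler columns are redrawn. Kernel
    eigendecompositions are cached whenever the explanatory matrix is
    unchanged across replicates (the panel in the noisy-copy design, the
    marker subset in the reverse nested direction).
    """
    G = synth_markers(panel)
    W_unit = center_scale_columns(G, "unit_variance")
    ke_panel = None
    rows = []
    for sc_idx, sc in enumerate(scenarios):
        if sc.design == "noisy_copy":
            if ke_panel is None:
                ke_panel = build_kernel(center_scale_columns(G, "span_scaled"))
            for rep in range(sc.n_replicates):
                rs = _child_seed(sc.seed, sc_idx, rep)
                X = sim_noisy_copy(W_unit, sc.true_r2, seed=rs)
                for method in sc.methods:
                    est = _one_estimate(method, X, W_unit, ke_panel, sc, rs)
                    rows.append((sc.label, method, "X~W", rep, est))
        else:
            subset_seed = _child_seed(sc.seed, sc_idx, 90001)
            directions = sc.directions or ("X~W", "W~X")
            ke_x = None
            for rep in range(sc.n_replicates):
                rs = _child_seed(sc.seed, sc_idx, rep)
                X, W = sim_nested(G, sc.fraction, seed=rs, subset_seed=subset_seed)
                if ke_x is None and "W~X" in directions:
                    ke_x = build_kernel(center_scale_columns(X, "span_scaled"))
                ke_w = (
                    build_kernel(center_scale_columns(W, "span_scaled"))
                    if "X~W" in directions
                    else None
                )
                for method in sc.methods:
                    for direction in directions:
                        if direction == "X~W":
                            est = _one_estimate(method, X, W, ke_w, sc, rs)
                        else:
                            est = _one_estimate(method, W, X, ke_x, sc, rs)
                        rows.append((sc.label, method, direction, rep, est))
    rep_df = pd.DataFrame(
        rows, columns=["scenario", "method", "direction", "replicate", "estimate"]
    )
    return StudyTable.from_replicates(rep_df)
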