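"""Monte Carlo ANOVA: shared variance via random vectors in a linear span.

The linear span of an output layer X contains every "trait" x = X a that can
be formed from its features. MC-ANOVA samples B random weight vectors a_s,
forms x_s = X a_s, estimates the proportion of variance of each x_s
explained by regression on the input layer W with the single-kernel REML
engine, and summarizes the resulting sequence {R^2_s}. Its mean (or median)
estimates the overall proportion of variance of the span of X explained by
W; the spread is informative in its own right — sparse weight vectors mimic
simple traits and widen the distribution without moving its center.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import FeatureMatrix, center_scale_columns, check_aligned
from .exceptions import DegenerateSpan, InvalidSpec
from .reml_core import KernelEigen, build_kernel, reml_fit_many

#: default number of random span vectors; a few hundred are enough to pin
#: down the mean, median and SD of the R^2 distribution.
DEFAULT_B = 300


@dataclass(frozen=True)
class WeightSpec:
    """How to draw the random weights a_s.

    distribution
        ``gaussian`` — all p weights iid N(0,1); ``sparse_gaussian`` —
        exactly ``n_nonzero`` uniformly chosen positions carry iid N(0,1)
        weights, the rest are exactly zero (the "trait architecture" knob).
    """

    distribution: str = "gaussian"
    n_nonzero: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.distribution not in ("gaussian", "sparse_gaussian"):
            raise InvalidSpec(f"unknown weight distribution {self.distribution!r}")
        if self.distribution == "sparse_gaussian":
            if self.n_nonzero is None or self.n_nonzero <= 0:
                raise InvalidSpec("sparse_gaussian requires n_nonzero >= 1")


@dataclass(frozen=True)
class MCResult:
    """The sequence {R^2_s} over B random span vectors plus summaries."""

    r2_samples: np.ndarray
    B: int
    mean: float
    median: float
    sd: float
    q025: float
    q975: float
    boundary_count: int
    weight_spec: WeightSpec

    @classmethod
    def from_samples(cls, r2, boundary_count, spec):
        r2 = np.asarray(r2, dtype=float)
        return cls(
            r2_samples=r2,
            B=r2.size,
            mean=float(r2.mean()),
            median=float(np.median(r2)),
            sd=float(r2.std(ddof=1)) if r2.size > 1 else 0.0,
            q025=float(np.quantile(r2, 0.025)),
            q975=float(np.quantile(r2, 0.975)),
            boundary_count=int(boundary_count),
            weight_spec=spec,
        )


def sample_weights(p: int, spec: WeightSpec, rng=None, draw: int = 0) -> np.ndarray:
    """Draw one weight vector of length p.

    Each draw consumes its own seeded substream (seed, draw index), so the
    full sequence is reproducible and individual draws are independent of
    the order in which they are taken.
    """
    if p < 1:
        raise InvalidSpec("p must be >= 1")
    if rng is None:
        rng = np.random.default_rng([int(spec.seed), int(draw)])
    if spec.distribution == "gaussian":
        return rng.standard_normal(p)
    if spec.n_nonzero > p:
        raise InvalidSpec(f"n_nonzero={spec.n_nonzero} exceeds p={p}")
    a = np.zeros(p)
    idx = rng.choice(p, size=spec.n_nonzero, replace=False)
    a[idx] = rng.standard_normal(spec.n_nonzero)
    return a


def sample_weight_matrix(p: int, B: int, spec: WeightSpec) -> np.ndarray:
    """B independent weight vectors as a (p, B) matrix (per-draw substreams)."""
    A = np.empty((p, B))
    for s in range(B):
        A[:, s] = sample_weights(p, spec, draw=s)
    return A


def mc_anova(
    X: FeatureMatrix,
    W: FeatureMatrix,
    B: int = DEFAULT_B,
    spec: WeightSpec | None = None,
    ke: KernelEigen | None = None,
) -> MCResult:
    """Estimate the distribution of span-of-X variance explained by W.

    Columns of X are standardized to unit variance before forming spans
    (unless X already is), so no single high-variance feature dominates
    every random vector. The kernel eigendecomposition of W is computed at
    most once; pass ``ke`` to reuse one across calls.
    """
    check_aligned(X, W)
    spec = spec or WeightSpec()
    if ke is None:
        Wsc = W if W.scaling_state == "span_scaled" else center_scale_columns(W, "span_scaled")
        ke = build_kernel(Wsc)
    Xv = (
        X.values
        if X.scaling_state in ("unit_variance", "span_scaled")
        else center_scale_columns(X, "unit_variance").values
    )
    p = Xv.shape[1]
    A = sample_weight_matrix(p, B, spec)
    Z = Xv @ A
    # a numerically constant span vector can only come from pathological
    # inputs; resample it once, then fail loudly
    sd = Z.std(axis=0)
    dead = np.flatnonzero(sd <= 1e-300)
    if dead.size:
        for s in dead:
            A[:, s] = sample_weights(p, spec, draw=B + int(s))
        Z[:, dead] = Xv @ A[:, dead]
        if np.any(Z[:, dead].std(axis=0) <= 1e-300):
            raise DegenerateSpan("random span vector constant after resampling")
    fit = reml_fit_many(Z, ke)
    return MCResult.from_samples(
        fit["r2"], boundary_count=int(np.sum(fit["boundary"] != 0)), spec=spec
    )
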