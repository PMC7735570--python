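"""Feature-matrix containers, column scaling conventions, and genotype QC.

Two data layers enter every analysis: an output set ``X`` (n samples x p
features) and an input set ``W`` (n x q). Both are held as
:class:`FeatureMatrix` objects that track their scaling state, because the
variance-component interpretation of R^2 depends on how the input columns
were scaled:

* ``unit_variance`` — each column centered and divided by its sample SD;
  the convention for output sets before forming span vectors.
* ``span_scaled`` — additionally divided by sqrt(p), so the implied sample
  kernel K = V V' has mean diagonal 1 and the signal variance component can
  be read as variance of the response captured by the input layer.

Genotype layers (dosage codes 0/1 or 0/1/2) get a :class:`GenotypeMatrix`
subtype plus the two QC filters used on real marker panels: a minor-allele-
frequency floor and greedy adjacent-marker LD pruning.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import (
    DuplicateIds,
    MissingValues,
    ZeroVarianceColumn,
)

SCALING_STATES = ("raw", "centered", "unit_variance", "span_scaled")


def _as_labels(ids, n, prefix) -> list:
    if ids is None:
        return [f"{prefix}{i}" for i in range(n)]
    ids = [str(i) for i in ids]
    if len(ids) != n:
        raise ValueError(f"expected {n} {prefix} labels, got {len(ids)}")
    if len(set(ids)) != n:
        raise DuplicateIds(f"duplicate {prefix} identifiers")
    return ids


@dataclass(frozen=True)
class FeatureMatrix:
    """An n x p numeric data layer with row/column identifiers.

    Parameters
    ----------
    values
        Real matrix, n samples by p features. Copied and validated:
        missing values raise :class:`~anovahd.exceptions.MissingValues`.
    sample_ids, feature_ids
        Optional labels; generated as ``s0..`` / ``f0..`` when omitted.
    scaling_state
        One of ``raw``, ``centered``, ``unit_variance``, ``span_scaled``.
    """

    values: np.ndarray
    sample_ids: list = None
    feature_ids: list = None
    scaling_state: str = "raw"

    def __post_init__(self):
        v = np.array(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, p = v.shape
        if n < 3 or p < 1:
            raise ValueError(f"need n >= 3 samples and p >= 1 features, got {n}x{p}")
        if self.scaling_state not in SCALING_STATES:
            raise ValueError(f"unknown scaling_state {self.scaling_state!r}")
        bad = np.argwhere(~np.isfinite(v))
        sids = _as_labels(self.sample_ids, n, "s")
        fids = _as_labels(self.feature_ids, p, "f")
        if bad.size:
            raise MissingValues([(sids[i], fids[j]) for i, j in bad])
        v.setflags(write=False)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "sample_ids", sids)
        object.__setattr__(self, "feature_ids", fids)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def __repr__(self):  # pragma: no cover - cosmetic
        return (
            f"{type(self).__name__}({self.n_samples}x{self.n_features}, "
            f"scaling={self.scaling_state})"
        )


@dataclass(frozen=True)
class GenotypeMatrix(FeatureMatrix):
    """A FeatureMatrix of integer dosage codes with per-column MAF.

    ``ploidy`` is 1 for inbred/haploid codes {0,1} and 2 for diploid
    dosages {0,1,2}. The minor-allele frequency of column j is
    min(f_j, 1 - f_j) with f_j = mean dosage / ploidy.
    """

    ploidy: int = 2
    maf: np.ndarray = field(default=None)

    def __post_init__(self):
        super().__post_init__()
        if self.ploidy not in (1, 2):
            raise ValueError("ploidy must be 1 or 2")
        if self.scaling_state == "raw":
            codes = set(range(self.ploidy + 1))
            vals = self.values
            if not np.isin(vals, sorted(codes)).all():
                raise ValueError(f"genotype entries must be in {sorted(codes)}")
        freq = self.values.mean(axis=0) / self.ploidy
        maf = np.minimum(freq, 1.0 - freq)
        maf.setflags(write=False)
        object.__setattr__(self, "maf", maf)


def center_scale_columns(M: FeatureMatrix, mode: str) -> FeatureMatrix:
    """Return a copy of ``M`` with columns centered and scaled.

    ``unit_variance`` gives every column mean 0 and sample SD 1
    (denominator n-1). ``span_scaled`` divides each centered column by its
    population SD (denominator n) and by sqrt(p), so that the sum of squares
    per column is exactly n/p and the mean diagonal of the implied kernel
    V V' equals 1 — the normalization that lets the signal variance
    component be read as variance of the response captured by the layer.
    Constant columns raise :class:`~anovahd.exceptions.ZeroVarianceColumn`.
    """
    if mode not in ("unit_variance", "span_scaled"):
        raise ValueError(f"mode must be unit_variance or span_scaled, got {mode!r}")
    v = M.values - M.values.mean(axis=0)
    ddof = 1 if mode == "unit_variance" else 0
    sd = v.std(axis=0, ddof=ddof)
    dead = np.flatnonzero(sd == 0.0)
    if dead.size:
        raise ZeroVarianceColumn(M.feature_ids[dead[0]])
    v = v / sd
    if mode == "span_scaled":
        v = v / np.sqrt(M.n_features)
    return FeatureMatrix(v, M.sample_ids, M.feature_ids, scaling_state=mode)


def maf_filter(G: GenotypeMatrix, min_maf: float):
    """Drop columns with minor-allele frequency below ``min_maf``.

    Returns ``(filtered, n_removed)``; column order is preserved and an
    empty result is allowed (flagged by ``n_removed == p``).
    """
    if not 0.0 <= min_maf <= 0.5:
        raise ValueError("min_maf must be in [0, 0.5]")
    keep = np.flatnonzero(G.maf >= min_maf)
    n_removed = G.n_features - keep.size
    filtered = subset_columns(G, keep)
    return filtered, n_removed


def ld_prune_adjacent(G: GenotypeMatrix, r2_max: float) -> GenotypeMatrix:
    """Greedy left-to-right pruning of adjacent markers in near-perfect LD.

    Walk the columns in the given (genomic) order; drop a candidate column
    whenever its squared Pearson correlation with the most recently
    *retained* column is >= ``r2_max``. Deterministic; constant columns are
    an error (apply :func:`maf_filter` first).
    """
    if not 0.0 < r2_max <= 1.0:
        raise ValueError("r2_max must be in (0, 1]")
    v = G.values
    sd = v.std(axis=0, ddof=1)
    dead = np.flatnonzero(sd == 0.0)
    if dead.size:
        raise ZeroVarianceColumn(G.feature_ids[dead[0]])
    centered = (v - v.mean(axis=0)) / sd
    m = G.n_samples - 1
    keep = [0]
    for j in range(1, G.n_features):
        r = centered[:, keep[-1]] @ centered[:, j] / m
        if r * r < r2_max:
            keep.append(j)
    return subset_columns(G, np.asarray(keep))


def subset_columns(G: FeatureMatrix, idx: np.ndarray):
    """Column subset preserving the container type and identifiers."""
    vals = G.values[:, idx]
    fids = [G.feature_ids[i] for i in np.atleast_1d(idx)]
    if isinstance(G, GenotypeMatrix):
        return GenotypeMatrix(
            vals, G.sample_ids, fids, scaling_state=G.scaling_state, ploidy=G.ploidy
        )
    return replace(G, values=vals, feature_ids=fids)


def check_aligned(X: FeatureMatrix, W: FeatureMatrix) -> None:
    """Require identical, identically ordered sample identifiers."""
    from .exceptions import SampleMismatch

    if X.sample_ids != W.sample_ids:
        raise SampleMismatch(
            "X and W must share sample_ids in identical order; "
            "use align_samples() to intersect and reorder"
        )


def align_samples(X: FeatureMatrix, W: FeatureMatrix, allow_subset: bool = False):
    """Align two layers on sample_id, order taken from ``X``.

    With ``allow_subset=False`` (default) the sample sets must be equal —
    silent row misalignment is the deadliest failure mode of two-matrix
    methods, so mismatched sets are an error unless explicitly allowed.
    """
    from .exceptions import SampleMismatch

    if X.sample_ids == W.sample_ids:
        return X, W
    common = [s for s in X.sample_ids if s in set(W.sample_ids)]
    if not allow_subset and (
        len(common) != len(X.sample_ids) or len(common) != len(W.sample_ids)
    ):
        raise SampleMismatch(
            f"sample sets differ ({len(common)} shared of "
            f"{len(X.sample_ids)}/{len(W.sample_ids)}); pass allow_subset=True "
            "to intersect"
        )
    xi = [X.sample_ids.index(s) for s in common]
    wi = [W.sample_ids.index(s) for s in common]
    Xs = FeatureMatrix(X.values[xi], common, X.feature_ids, X.scaling_state)
    Ws = FeatureMatrix(W.values[wi], common, W.feature_ids, W.scaling_state)
    return Xs, Ws
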