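"""Partial least squares baseline: CV component selection + training R^2.

The comparison method: regress the whole output layer X on the input layer
W with multivariate PLS, choose the number of components by 10-fold
cross-validated prediction MSE (pooled over all held-out entries), refit at
the chosen count on all data, and report the training R^2
(1 - SSE/SST over all entries of the standardized X). This estimator is a
baseline, not a recommendation: component selection by prediction accuracy
makes it biased low when the shared variance is low and biased high when it
is high.

scikit-learn's PLSRegression (NIPALS) does the fitting; predictions at a
truncated component count k reuse one full-rank fit via the standard
identity  Y_hat_k = (X - x_mean) @ x_rotations[:, :k] @ y_loadings[:, :k]'.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cross_decomposition import PLSRegression

from .data_model import FeatureMatrix, center_scale_columns, check_aligned
from .exceptions import TooFewSamples


@dataclass(frozen=True)
class PLSResult:
    components_tried: list
    cv_mse: np.ndarray
    chosen_components: int
    training_r2: float
    fold_seed: int


def _standardized(M: FeatureMatrix) -> np.ndarray:
    if M.scaling_state in ("unit_variance", "span_scaled"):
        return M.values
    return center_scale_columns(M, "unit_variance").values


def _fit(W, X, n_components):
    """Fit PLS on explicitly train-centered data; returns (model, means)."""
    w_mean = W.mean(axis=0)
    x_mean = X.mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = PLSRegression(n_components=n_components, scale=False)
        model.fit(W - w_mean, X - x_mean)
    return model, w_mean, x_mean


def _predict_truncated(model, w_mean, x_mean, W_new, k):
    """Prediction using only the first k components of a fitted model."""
    coef_k = model.x_rotations_[:, :k] @ model.y_loadings_[:, :k].T
    return (W_new - w_mean) @ coef_k + x_mean


def pls_r2(
    X: FeatureMatrix,
    W: FeatureMatrix,
    max_components: int = 100,
    folds: int = 10,
    fold_seed: int = 0,
) -> PLSResult:
    """CV-selected PLS of X on W; returns the training-data R^2.

    Folds are a seeded uniform partition of the rows. The per-count CV MSE
    pools squared errors over every held-out entry of X; ties in the argmin
    go to the smallest count.
    """
    check_aligned(X, W)
    n = X.n_samples
    if n < folds:
        raise TooFewSamples(f"n={n} < folds={folds}")
    Xs = _standardized(X)
    Ws = _standardized(W)
    min_train = n - (n // folds + (1 if n % folds else 0))
    K = int(min(max_components, min_train - 1, W.n_features, 100))
    if K < 1:
        raise TooFewSamples("not enough samples for a single PLS component")

    rng = np.random.default_rng(fold_seed)
    order = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    fold_of[order] = np.arange(n) % folds

    sse = np.zeros(K)
    for f in range(folds):
        test = fold_of == f
        model, w_mean, x_mean = _fit(Ws[~test], Xs[~test], K)
        for k in range(1, K + 1):
            resid = Xs[test] - _predict_truncated(model, w_mean, x_mean, Ws[test], k)
            sse[k - 1] += float(np.sum(resid * resid))
    cv_mse = sse / Xs.size
    chosen = int(np.argmin(cv_mse)) + 1

    full, w_mean, x_mean = _fit(Ws, Xs, chosen)
    resid = Xs - _predict_truncated(full, w_mean, x_mean, Ws, chosen)
    sst = float(np.sum((Xs - Xs.mean(axis=0)) ** 2))
    training_r2 = 1.0 - float(np.sum(resid * resid)) / sst
    return PLSResult(
        components_tried=list(range(1, K + 1)),
        cv_mse=cv_mse,
        chosen_components=chosen,
        training_r2=float(training_r2),
        fold_seed=fold_seed,
    )
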