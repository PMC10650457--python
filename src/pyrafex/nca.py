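"""Neighborhood component analysis (NCA) feature weighting and selection.

This is the feature-selection form of NCA: each feature column l carries a
weight w_l, pairwise sample distances are the weighted l1 distances

    D_w(i, j) = sum_l w_l^2 |x_il - x_jl|,

and sample i softly picks each other sample j as its nearest neighbor with
probability

    p_ij = exp(-D_w(i,j) / sigma) / sum_{k != i} exp(-D_w(i,k) / sigma),

with p_ii = 0.  The regularized leave-one-out objective

    xi(w) = (1/N) sum_i sum_{j != i} y_ij p_ij  -  lambda sum_l w_l^2,

where y_ij = 1 iff labels match, rewards weights under which same-class
samples are soft nearest neighbors.  It is maximized by full-batch gradient
ascent with the analytic gradient

    d xi / d w_l = (2 w_l / sigma) (1/N) sum_i [ p_i sum_j p_ij |x_il - x_jl|
                   - sum_j y_ij p_ij |x_il - x_jl| ] - 2 lambda w_l,

with p_i = sum_j y_ij p_ij.  Features are then ranked by w_l^2 and the
top k kept.  Columns are z-scored first so the l1 distances are scale-free.

The computation is blocked over feature columns so tables as wide as the
85,000-column pyramid vectors fit in memory; blocking is purely a memory
layout and gives results identical to the naive formula.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .features import FeatureTable

__all__ = [
    "NcaConfig",
    "NcaWeights",
    "SelectedFeatures",
    "standardize",
    "nca_objective",
    "nca_gradient",
    "nca_fit",
    "select_top_k",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class NcaConfig:
    """Hyperparameters of the NCA feature-selection fit.

    sigma
        Kernel width of the soft-neighbor exponential, applied after
        z-scoring; 1.0 is a neutral scale-free default.
    lam
        l2 regularization weight on w; ``None`` means 1/N, chosen at fit
        time, which shrinks uninformative weights without overpowering the
        data term.
    learning_rate
        Initial gradient-ascent step; halved whenever a step would decrease
        the objective, grown 5% after each accepted step.
    max_iter, tol
        Stop after ``max_iter`` accepted/rejected iterations or when the
        relative objective improvement falls below ``tol``.
    standardize
        z-score columns before fitting (population sd); zero-variance
        columns become all-zero and are reported.
    """

    sigma: float = 1.0
    lam: float | None = None
    learning_rate: float = 0.01
    max_iter: int = 100
    tol: float = 1e-6
    seed: int = 0
    standardize: bool = True
    block_size: int = 4096

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.lam is not None and self.lam < 0:
            raise ValueError("lambda must be non-negative")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class NcaWeights:
    """Fitted per-column weights (effective weight is w**2) and the trace."""

    w: np.ndarray
    objective_trace: list[float]
    zero_variance_columns: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.intp)
    )


@dataclass(frozen=True)
class SelectedFeatures:
    """Top-k column indices, ordered by descending w**2 (ties: ascending index)."""

    indices: np.ndarray
    weights_at_selection: np.ndarray


def standardize(table: FeatureTable) -> tuple[FeatureTable, np.ndarray, np.ndarray]:
    """z-score every column (population sd); returns (table, means, sds).

    Zero-variance columns are mapped to all-zeros (their sd is reported as
    0) and logged; restandardizing a standardized table is a no-op.
    """
    if table.n_samples < 2:
        raise ValueError("standardization needs at least 2 samples")
    means = table.matrix.mean(axis=0)
    sds = table.matrix.std(axis=0)  # ddof=0: population convention
    zero_var = sds == 0.0
    safe = np.where(zero_var, 1.0, sds)
    mat = (table.matrix - means) / safe
    mat[:, zero_var] = 0.0
    if zero_var.any():
        log.warning("%d zero-variance columns set to 0", int(zero_var.sum()))
    out = FeatureTable(mat, table.labels.copy(), list(table.sample_ids),
                       list(table.column_names))
    return out, means, sds


# Unique-pair |x_i - x_j| cache: distances and gradients then reduce to two
# matrix-vector products per iteration instead of re-materializing the full
# N x N x D difference tensor.  Capped so an 85,000-column table with a few
# dozen rows fits comfortably in memory; above the cap the blocked
# recomputation path is used with identical results.
_PAIR_CACHE_MAX_ELEMS = 1 << 26


class _PairCache:
    """Absolute differences for all unordered sample pairs of a fixed X."""

    def __init__(self, X: np.ndarray):
        n = X.shape[0]
        iu, ju = np.triu_indices(n, k=1)
        self.n = n
        self.iu, self.ju = iu, ju
        self.A = np.abs(X[iu] - X[ju])  # P x D

    def distances(self, w2: np.ndarray) -> np.ndarray:
        d = self.A @ w2
        dist = np.zeros((self.n, self.n))
        dist[self.iu, self.ju] = d
        dist[self.ju, self.iu] = d
        return dist

    def weighted_sum(self, M: np.ndarray) -> np.ndarray:
        """sum_ij M_ij |x_il - x_jl| per column l, for any square M."""
        coeff = M[self.iu, self.ju] + M[self.ju, self.iu]
        return coeff @ self.A


def _pairwise_distances(
    X: np.ndarray, w2: np.ndarray, block_size: int
) -> np.ndarray:
    n = X.shape[0]
    dist = np.zeros((n, n))
    for lo in range(0, X.shape[1], block_size):
        blk = X[:, lo : lo + block_size]
        absdiff = np.abs(blk[:, None, :] - blk[None, :, :])
        dist += absdiff @ w2[lo : lo + block_size]
    return dist


def _soft_neighbor_probs(
    X: np.ndarray,
    w: np.ndarray,
    sigma: float,
    block_size: int,
    cache: "_PairCache | None" = None,
) -> np.ndarray:
    """Row-stochastic soft-neighbor matrix P (p_ii = 0) under weights w."""
    w2 = w * w
    dist = (
        cache.distances(w2)
        if cache is not None
        else _pairwise_distances(X, w2, block_size)
    )
    z = -dist / sigma
    np.fill_diagonal(z, -np.inf)
    z -= z.max(axis=1, keepdims=True)  # per-row shift; cancels in the ratio
    expz = np.exp(z)
    denom = expz.sum(axis=1, keepdims=True)
    # a sample with no neighbors cannot occur for N >= 2 (max shift gives 1)
    return expz / denom


def _prep(table: FeatureTable, w: np.ndarray | None, config: NcaConfig):
    X = table.matrix
    if config.standardize:
        X = standardize(table)[0].matrix
    labels = np.asarray(table.labels)
    if w is None:
        w = np.ones(X.shape[1])
    w = np.asarray(w, dtype=np.float64)
    if w.shape != (X.shape[1],):
        raise ValueError(
            f"weight length {w.shape} does not match {X.shape[1]} columns"
        )
    lam = (1.0 / X.shape[0]) if config.lam is None else config.lam
    return X, labels, w, lam


def nca_objective(
    table: FeatureTable,
    w: np.ndarray,
    config: NcaConfig | None = None,
    _cache: _PairCache | None = None,
) -> float:
    """Evaluate the regularized leave-one-out objective xi(w)."""
    config = config or NcaConfig()
    X, labels, w, lam = _prep(table, w, config)
    P = _soft_neighbor_probs(X, w, config.sigma, config.block_size, _cache)
    Y = labels[:, None] == labels[None, :]
    n = X.shape[0]
    return float((P * Y).sum() / n - lam * float(w @ w))


def nca_gradient(
    table: FeatureTable,
    w: np.ndarray,
    config: NcaConfig | None = None,
    _cache: _PairCache | None = None,
) -> np.ndarray:
    """Analytic gradient of xi with respect to w (same blocking as the objective)."""
    config = config or NcaConfig()
    X, labels, w, lam = _prep(table, w, config)
    n, d = X.shape
    P = _soft_neighbor_probs(X, w, config.sigma, config.block_size, _cache)
    Y = (labels[:, None] == labels[None, :]).astype(np.float64)
    p_i = (P * Y).sum(axis=1)
    # M_ij = p_i p_ij - y_ij p_ij ; grad_l = (2 w_l / sigma n) sum_ij M_ij |dx_ijl|
    M = p_i[:, None] * P - Y * P
    if _cache is not None:
        grad = _cache.weighted_sum(M)
    else:
        grad = np.empty(d)
        for lo in range(0, d, config.block_size):
            blk = X[:, lo : lo + config.block_size]
            absdiff = np.abs(blk[:, None, :] - blk[None, :, :])
            grad[lo : lo + config.block_size] = np.einsum("ij,ijb->b", M, absdiff)
    return (2.0 * w / config.sigma) * grad / n - 2.0 * lam * w


def nca_fit(table: FeatureTable, config: NcaConfig | None = None) -> NcaWeights:
    """Gradient ascent on xi from w = 1, returning the best-objective iterate.

    The step size halves whenever a proposed step would decrease the
    objective (the proposal is rejected) and grows gently after accepted
    steps; iteration stops on ``tol`` relative improvement or ``max_iter``.
    """
    config = config or NcaConfig()
    labels = np.asarray(table.labels)
    if table.n_samples < 2:
        raise ValueError("NCA needs at least 2 samples")
    if len(np.unique(labels)) < 2:
        raise ValueError("NCA needs at least 2 classes")

    if config.standardize:
        std_table, _, sds = standardize(table)
        zero_var = np.flatnonzero(sds == 0.0)
    else:
        std_table, zero_var = table, np.empty(0, dtype=np.intp)
    inner = NcaConfig(
        sigma=config.sigma, lam=config.lam, learning_rate=config.learning_rate,
        max_iter=config.max_iter, tol=config.tol, seed=config.seed,
        standardize=False, block_size=config.block_size,
    )

    n_pairs = std_table.n_samples * (std_table.n_samples - 1) // 2
    cache = (
        _PairCache(std_table.matrix)
        if n_pairs * std_table.n_features <= _PAIR_CACHE_MAX_ELEMS
        else None
    )

    w = np.ones(std_table.n_features)
    obj = nca_objective(std_table, w, inner, cache)
    if not np.isfinite(obj):
        raise FloatingPointError(f"non-finite initial objective {obj}")
    best_w, best_obj = w.copy(), obj
    trace = [obj]
    lr = config.learning_rate
    for _ in range(config.max_iter - 1):
        grad = nca_gradient(std_table, w, inner, cache)
        cand = w + lr * grad
        cand_obj = nca_objective(std_table, cand, inner, cache)
        if not np.isfinite(cand_obj):
            raise FloatingPointError(
                f"non-finite objective at lr={lr:g}; |grad|max="
                f"{np.abs(grad).max():g}"
            )
        if cand_obj > obj:
            improved = cand_obj - obj
            w, obj = cand, cand_obj
            lr *= 1.05
            if obj > best_obj:
                best_w, best_obj = w.copy(), obj
            trace.append(obj)
            if improved <= config.tol * max(abs(obj), 1.0):
                break
        else:
            lr *= 0.5
            trace.append(obj)
            if lr < 1e-12:
                break
    return NcaWeights(best_w, trace, zero_var)


def select_top_k(weights: NcaWeights, k: int) -> SelectedFeatures:
    """Indices of the k largest squared weights, ties broken by ascending index."""
    w = np.asarray(weights.w, dtype=np.float64)
    if not (1 <= k <= w.size):
        raise ValueError(f"k={k} must be in [1, {w.size}]")
    w2 = w * w
    order = np.lexsort((np.arange(w.size), -w2))
    idx = order[:k]
    return SelectedFeatures(idx, w[idx])
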