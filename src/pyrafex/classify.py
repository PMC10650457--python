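"""Quadratic-kernel SVM training and stratified k-fold cross-validation.

The classifier preset mirrors the common toolbox "quadratic SVM": a
degree-2 polynomial kernel K(x, x') = (x.x' / s^2 + 1)^2 with kernel scale
s = sqrt(D) over D selected features, box constraint C = 1, one-vs-one
multiclass coding, and within-fold standardization.  Cross-validation can
fit standardization + NCA selection per training fold (leakage-free
default) or once globally on all data before splitting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from sklearn.svm import SVC

from .features import FeatureTable
from .nca import NcaConfig, nca_fit, select_top_k, standardize

__all__ = ["SvmConfig", "CvPlan", "CvResult", "make_folds", "train_svm",
           "cross_validate"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SvmConfig:
    """Quadratic-SVM preset; every toolbox-default value is overridable."""

    degree: int = 2
    C: float = 1.0
    coef0: float = 1.0  # kernel offset
    kernel_scale: float | None = None  # None -> sqrt(D) at fit time
    standardize_within_fold: bool = True

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")


@dataclass(frozen=True)
class CvPlan:
    """Stratified k-fold plan; ``selection_mode`` picks where NCA is fitted."""

    n_folds: int = 10
    seed: int = 0
    selection_mode: str = "per_fold"  # or "global"

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.selection_mode not in ("per_fold", "global"):
            raise ValueError(f"unknown selection_mode {self.selection_mode!r}")


@dataclass
class CvResult:
    """Out-of-fold predictions aggregated over all folds."""

    predictions: np.ndarray  # per-sample out-of-fold predicted labels
    fold_of_sample: np.ndarray
    per_fold_accuracy: list[float]
    selected_indices: list[np.ndarray]  # one entry per fold (or one, global)

    def overall_accuracy(self, true_labels: np.ndarray) -> float:
        return float(np.mean(self.predictions == np.asarray(true_labels)))


def make_folds(labels: np.ndarray, plan: CvPlan) -> np.ndarray:
    """Seeded stratified fold assignment; per-class fold sizes differ by <= 1.

    Each class's samples are shuffled and dealt round-robin to folds, with
    the starting fold rotating per class so small classes do not all land
    in fold 0.  A class with fewer samples than folds triggers a warning
    (some folds then lack that class) but assignment still proceeds.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n < plan.n_folds:
        raise ValueError(f"need at least {plan.n_folds} samples, got {n}")
    rng = np.random.default_rng(plan.seed)
    assignment = np.empty(n, dtype=np.intp)
    start = 0
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < plan.n_folds:
            warnings.warn(
                f"class {cls!r} has {len(idx)} samples for {plan.n_folds} "
                "folds; some folds will lack it"
            )
        rng.shuffle(idx)
        assignment[idx] = (start + np.arange(len(idx))) % plan.n_folds
        start += len(idx)
    return assignment


def train_svm(
    matrix: np.ndarray, labels: np.ndarray, config: SvmConfig | None = None
) -> SVC:
    """Fit the quadratic SVM; deterministic for fixed inputs and config."""
    config = config or SvmConfig()
    matrix = np.asarray(matrix, dtype=np.float64)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training split has fewer than 2 classes")
    d = matrix.shape[1]
    scale = np.sqrt(d) if config.kernel_scale is None else config.kernel_scale
    model = SVC(
        kernel="poly",
        degree=config.degree,
        C=config.C,
        coef0=config.coef0,
        gamma=1.0 / (scale * scale),
        decision_function_shape="ovo",
    )
    model.fit(matrix, labels)
    return model


def _fit_fold_model(
    train_mat: np.ndarray,
    train_labels: np.ndarray,
    svm: SvmConfig,
) -> tuple[SVC, np.ndarray, np.ndarray]:
    """Train an SVM with fold-local standardization; returns (model, mean, sd)."""
    if svm.standardize_within_fold:
        mean = train_mat.mean(axis=0)
        sd = train_mat.std(axis=0)
        sd = np.where(sd == 0.0, 1.0, sd)
    else:
        mean = np.zeros(train_mat.shape[1])
        sd = np.ones(train_mat.shape[1])
    model = train_svm((train_mat - mean) / sd, train_labels, svm)
    return model, mean, sd


def cross_validate(
    table: FeatureTable,
    plan: CvPlan | None = None,
    svm: SvmConfig | None = None,
    nca: NcaConfig | None = None,
    k_select: int | None = None,
) -> CvResult:
    """Stratified k-fold CV of NCA selection + quadratic SVM.

    With ``selection_mode="per_fold"`` (default) standardization, the NCA
    fit and the top-k cut are computed on each training split only and
    applied unchanged to the held-out fold, so no information from a test
    fold ever reaches the selector.  With ``"global"`` the selection is
    computed once on all rows first — the protocol to use when reproducing
    a selection-before-CV workflow — and only the SVM is refit per fold.
    Every sample is predicted exactly once; (seed, config) fully determine
    the result.
    """
    plan = plan or CvPlan()
    svm = svm or SvmConfig()
    nca = nca or NcaConfig()
    k = table.n_features if k_select is None else k_select
    if not (1 <= k <= table.n_features):
        raise ValueError(f"k_select={k} out of range for {table.n_features} columns")

    labels = np.asarray(table.labels)
    folds = make_folds(labels, plan)
    preds = np.empty(table.n_samples, dtype=labels.dtype)
    per_fold_acc: list[float] = []
    selections: list[np.ndarray] = []

    if plan.selection_mode == "global":
        if k < table.n_features:
            weights = nca_fit(table, nca)
            global_idx = select_top_k(weights, k).indices
        else:
            global_idx = np.arange(table.n_features)
        selections.append(global_idx)

    for f in range(plan.n_folds):
        test = folds == f
        train = ~test
        if not test.any():
            continue
        train_labels = labels[train]

        if plan.selection_mode == "per_fold":
            sub = FeatureTable(
                table.matrix[train], train_labels,
                [table.sample_ids[i] for i in np.flatnonzero(train)],
                list(table.column_names),
            )
            if k < table.n_features:
                weights = nca_fit(sub, nca)
                idx = select_top_k(weights, k).indices
            else:
                idx = np.arange(table.n_features)
            selections.append(idx)
        else:
            idx = selections[0]

        model, mean, sd = _fit_fold_model(
            table.matrix[np.ix_(train, idx)], train_labels, svm
        )
        test_mat = (table.matrix[np.ix_(test, idx)] - mean) / sd
        fold_pred = model.predict(test_mat)
        preds[test] = fold_pred
        per_fold_acc.append(float(np.mean(fold_pred == labels[test])))
        log.info("fold %d: accuracy %.3f (%d test samples)", f,
                 per_fold_acc[-1], int(test.sum()))

    return CvResult(preds, folds, per_fold_acc, selections)
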