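"""Cross-validated evaluation, classification metrics, and saliency ranking.

Metrics are computed on the *concatenation* of the k held-out test folds (not
averaged per fold): each subject is tested exactly once, and accuracy,
sensitivity, specificity and AUC are read off the pooled predictions.

Saliency ranking scores every connectivity feature by the chained product of
the encoder weight matrices, W(1) x W(2) x ... x W(L), which approximates the
partial derivative of the network output with respect to each input feature
(activation derivatives and the head coefficients are ignored by default; an
``include_head`` variant multiplies the head coefficients in for sensitivity
analyses).  Per-fold scores are accumulated by summation across the CV folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .classify import DTLNNModel, predict
from .connectome import ConnectomeDataset, edge_index_pairs
from .errors import InvalidInputError, ShapeError

__all__ = [
    "CVResult",
    "SaliencyRanking",
    "stratified_kfold",
    "classification_metrics",
    "cross_validate",
    "paired_t_test",
    "saliency_scores",
    "accumulate_rankings",
    "svm_trainer",
]


def svm_trainer(kernel: str = "linear", C: float = 1.0):
    """External comparator: an SVM behind the ``cross_validate`` interface.

    Training is delegated to scikit-learn; decision-function values serve as
    ranking scores.  The comparator shares the CV machinery but none of the
    network code paths.
    """
    from sklearn.svm import SVC

    class _FittedSVM:
        def __init__(self, clf):
            self._clf = clf

        def predict(self, X):
            return self._clf.predict(X).astype(int), self._clf.decision_function(X)

    def trainer(X, y, fold_seed):
        clf = SVC(kernel=kernel, C=C, random_state=fold_seed)
        clf.fit(X, y)
        return _FittedSVM(clf)

    return trainer


@dataclass
class CVResult:
    """Pooled predictions and metrics of one stratified k-fold run."""

    fold_assignments: np.ndarray
    truth: np.ndarray
    pred: np.ndarray
    scores: np.ndarray
    metrics: dict
    per_fold_models: list = field(default_factory=list, repr=False)


@dataclass
class SaliencyRanking:
    """Accumulated per-edge saliency with descending ranks (1 = most salient)."""

    edge_scores: np.ndarray
    ranks: np.ndarray
    top: pd.DataFrame  # columns: rank, edge, roi_a, roi_b, score


def stratified_kfold(labels: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Per-subject fold indices; per-class fold counts differ by at most 1."""
    labels = np.asarray(labels)
    if k < 2:
        raise InvalidInputError("k must be >= 2")
    classes, counts = np.unique(labels, return_counts=True)
    small = counts < k
    if np.any(small):
        raise InvalidInputError(
            f"class {classes[small][0]!r} has {counts[small][0]} members, fewer than k={k}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(labels.shape[0], dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros_like(labels), labels)):
        assignment[test_idx] = fold
    return assignment


def classification_metrics(truth: np.ndarray, pred: np.ndarray,
                           scores: np.ndarray) -> dict:
    """Accuracy, sensitivity, specificity (percent) and AUC.

    Positive class is label 1.  AUC is the probability that a random
    positive's score exceeds a random negative's, with ties counted 1/2.
    With a one-class truth vector the undefined rates are NaN with a warning.
    """
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    scores = np.asarray(scores, dtype=float)
    if not (truth.shape == pred.shape == scores.shape):
        raise ShapeError("truth, pred and scores must have equal length")
    pos = truth == 1
    neg = ~pos
    acc = 100.0 * float(np.mean(pred == truth))
    if pos.sum() == 0 or neg.sum() == 0:
        import warnings

        warnings.warn("one-class truth: sensitivity/specificity/AUC undefined", RuntimeWarning)
        sens = 100.0 * float(np.mean(pred[pos] == 1)) if pos.sum() else float("nan")
        spec = 100.0 * float(np.mean(pred[neg] == 0)) if neg.sum() else float("nan")
        auc = float("nan")
    else:
        sens = 100.0 * float(np.mean(pred[pos] == 1))
        spec = 100.0 * float(np.mean(pred[neg] == 0))
        auc = float(roc_auc_score(truth, scores))
    return {"accuracy": acc, "sensitivity": sens, "specificity": spec, "auc": auc}


def cross_validate(
    trainer: Callable[[np.ndarray, np.ndarray, int], object],
    ds: ConnectomeDataset,
    k: int = 5,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold CV of a training procedure on a labeled dataset.

    ``trainer(X_train, y_train, fold_seed)`` must return a fitted model that
    either is a :class:`DTLNNModel` or exposes ``predict(X) -> (labels,
    scores)``.  Per-fold models are retained for saliency accumulation.
    """
    if ds.labels is None:
        raise InvalidInputError("cross_validate requires labels")
    y = np.asarray(ds.labels).astype(int)
    folds = stratified_kfold(y, k, seed)
    truth = np.empty(0, dtype=int)
    pred = np.empty(0, dtype=int)
    scores = np.empty(0, dtype=float)
    models = []
    for fold in range(k):
        test = folds == fold
        train = ~test
        fold_seed = int(np.random.SeedSequence([seed, fold]).generate_state(1)[0] % (2**31))
        try:
            model = trainer(ds.features[train], y[train], fold_seed)
        except Exception as exc:  # annotate with the fold, preserve the cause
            raise type(exc)(f"fold {fold}: {exc}") from exc
        if isinstance(model, DTLNNModel):
            labels_f, scores_f = predict(model, ds.features[test])
        else:
            labels_f, scores_f = model.predict(ds.features[test])
        truth = np.concatenate([truth, y[test]])
        pred = np.concatenate([pred, np.asarray(labels_f, dtype=int)])
        scores = np.concatenate([scores, np.asarray(scores_f, dtype=float)])
        models.append(model)
    metrics = classification_metrics(truth, pred, scores)
    return CVResult(folds, truth, pred, scores, metrics, models)


def paired_t_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Classical paired t on the differences a-b; two-sided p with df = n-1."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise InvalidInputError("paired_t_test needs two equal-length vectors, n >= 2")
    d = a - b
    if np.all(d == 0.0):
        return 0.0, 1.0  # identical pairings: no effect, maximal p
    if np.all(d == d[0]):
        raise InvalidInputError("differences have zero variance (degenerate input)")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def saliency_scores(model: DTLNNModel, include_head: bool = False) -> np.ndarray:
    """Weight-product saliency, one non-negative score per input feature.

    Forms P = W(L) x ... x W(1) (the linear chain mapping input to top layer)
    and scores feature j by the sum of |P[:, j]| over the top-layer units.
    With ``include_head=True`` the head coefficient matrix is multiplied in
    first.
    """
    P = None
    for W, _ in model.ssae.encoders:
        P = W if P is None else W @ P
    if include_head:
        P = model.head.theta @ P
    if P.shape[1] != model.ssae.n_in:
        raise ShapeError("layer widths are inconsistent with the input width")
    return np.sum(np.abs(P), axis=0)


def accumulate_rankings(
    per_fold_scores: Sequence[np.ndarray],
    roi_names: Sequence[str],
    top_k: int = 10,
) -> SaliencyRanking:
    """Sum per-fold saliency scores and rank edges (descending, stable ties).

    ROI indices in the report are 1-based pairs in upper-triangle order; ties
    are broken by ascending edge index.
    """
    mats = [np.asarray(s, dtype=float) for s in per_fold_scores]
    if len({m.shape for m in mats}) != 1:
        raise ShapeError("per-fold score vectors have mismatched lengths")
    total = np.sum(mats, axis=0)
    n = len(roi_names)
    if total.shape[0] != n * (n - 1) // 2:
        raise ShapeError("score length does not match n(n-1)/2 for the ROI list")
    order = np.argsort(-total, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(1, total.shape[0] + 1)
    iu, ju = edge_index_pairs(n)
    rows = []
    for r, e in enumerate(order[:top_k], start=1):
        rows.append(
            {
                "rank": r,
                "edge": int(e),
                "roi_a": roi_names[iu[e]],
                "roi_b": roi_names[ju[e]],
                "roi_a_index": int(iu[e]) + 1,
                "roi_b_index": int(ju[e]) + 1,
                "score": float(total[e]),
            }
        )
    return SaliencyRanking(total, ranks, pd.DataFrame(rows))
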