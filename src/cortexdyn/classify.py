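"""Group classification from multiparameter maps.

Balanced subsampling of the larger group, PCA to 95% explained variance,
an RBF-kernel SVM with leave-one-out cross-validation, repeated over
random subsamples, with label-permutation significance and percentile
confidence intervals on ROC-AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray
from sklearn.decomposition import PCA
from sklearn.svm import SVC

__all__ = [
    "ClassifierConfig",
    "ConfusionMatrix",
    "ClassificationReport",
    "balance_subsample",
    "reduce_dimensionality",
    "train_eval_loocv",
    "f1_from_confusion",
    "permutation_pvalue",
]


@dataclass
class ClassifierConfig:
    c_grid: tuple = (0.1, 1.0, 10.0)  # regularization strengths
    gamma_grid: tuple = ("scale", 0.01, 0.1)  # kernel scales
    variance_threshold: float = 0.95
    n_subsamples: int = 200
    n_label_perms: int = 500
    seed: int = 0
    pca_scope: str = "per_fold"  # or "whole_subsample"
    auc_ci_percentiles: tuple = (17.0, 83.0)

    def __post_init__(self) -> None:
        if not 0 < self.variance_threshold <= 1:
            raise ValueError("variance_threshold must lie in (0, 1]")
        if self.n_subsamples < 1 or self.n_label_perms < 1:
            raise ValueError("counts must be >= 1")
        if self.pca_scope not in ("per_fold", "whole_subsample"):
            raise ValueError("pca_scope must be 'per_fold' or 'whole_subsample'")
        if not self.c_grid or not self.gamma_grid:
            raise ValueError("hyperparameter grid must be non-empty")


@dataclass
class ConfusionMatrix:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class ClassificationReport:
    mean_accuracy: float
    p_value: float
    confusion: ConfusionMatrix
    f1: float
    roc_auc: float
    roc_auc_ci: tuple[float, float]
    per_subsample: list = field(default_factory=list, repr=False)


def balance_subsample(features, labels, seed: int = 0):
    """Subsample the larger class (without replacement) to the smaller
    class size. Returns (features, labels, kept_indices)."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    rng = np.random.default_rng(seed)
    n_keep = counts.min()
    keep = []
    for c in classes:
        idx = np.flatnonzero(y == c)
        if len(idx) > n_keep:
            idx = rng.choice(idx, n_keep, replace=False)
        keep.append(idx)
    keep = np.sort(np.concatenate(keep))
    return X[keep], y[keep], keep


def reduce_dimensionality(features, variance_threshold: float = 0.95):
    """PCA keeping the smallest leading set of components whose cumulative
    explained variance reaches the threshold. Zero-variance features are
    dropped with a warning. Returns (reduced, transform_fn)."""
    X = np.asarray(features, dtype=float)
    keep = X.std(axis=0) > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance feature(s)",
                      stacklevel=2)
    Xk = X[:, keep]
    pca = PCA()
    pca.fit(Xk)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_comp = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    n_comp = min(n_comp, Xk.shape[1], len(Xk))

    def transform(data):
        d = np.asarray(data, dtype=float)[:, keep]
        return pca.transform(d)[:, :n_comp]

    return transform(X), transform


def _loo_folds(X, pca_scope, variance_threshold):
    """Per-fold (train, test) feature blocks, PCA-reduced.

    The reduction is label-independent, so it is computed once per
    subsample and shared across the hyperparameter grid.
    """
    n = len(X)
    folds = []
    if pca_scope == "whole_subsample":
        Xr, _ = reduce_dimensionality(X, variance_threshold)
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            folds.append((Xr[mask], Xr[[i]], mask))
    else:
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            _, tf = reduce_dimensionality(X[mask], variance_threshold)
            folds.append((tf(X[mask]), tf(X[[i]]), mask))
    return folds


def _loo_scores(folds, y_bin, c, gamma):
    """LOO decision scores and predictions for one hyperparameter pair."""
    n = len(y_bin)
    scores = np.empty(n)
    preds = np.empty(n, dtype=int)
    for i, (xtr, xte, mask) in enumerate(folds):
        clf = SVC(kernel="rbf", C=c, gamma=gamma)
        clf.fit(xtr, y_bin[mask])
        scores[i] = clf.decision_function(xte)[0]
        preds[i] = int(scores[i] > 0)
    return scores, preds


def roc_auc_pair_counting(scores, labels) -> float:
    """ROC-AUC as the fraction of correctly ordered positive/negative score
    pairs, ties counted one half."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    pos = s[y == 1]
    neg = s[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need both classes to compute ROC-AUC")
    diff = pos[:, None] - neg[None, :]
    return float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / diff.size)


def f1_from_confusion(confusion: ConfusionMatrix) -> float:
    """F1 = 2 TP / (2 TP + FP + FN); NaN (with a warning) when undefined."""
    denom = 2 * confusion.tp + confusion.fp + confusion.fn
    if denom == 0:
        warnings.warn("F1 undefined: 2TP + FP + FN == 0", stacklevel=2)
        return float("nan")
    return 2.0 * confusion.tp / denom


def _encode(labels):
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    # the lexically larger label is the positive class
    return (y == classes[1]).astype(int), classes


def _eval_subsample(X, y_bin, config: ClassifierConfig, folds=None):
    """Grid-select hyperparameters by LOO accuracy, return best fold stats."""
    if folds is None:
        folds = _loo_folds(X, config.pca_scope, config.variance_threshold)
    best = None
    for c in config.c_grid:
        for g in config.gamma_grid:
            scores, preds = _loo_scores(folds, y_bin, c, g)
            acc = float(np.mean(preds == y_bin))
            if best is None or acc > best[0]:
                best = (acc, scores, preds, (c, g))
    return best


def train_eval_loocv(features, labels, config: ClassifierConfig) -> ClassificationReport:
    """Full classification pipeline over repeated balanced subsamples.

    Per subsample: balance classes, pick (C, gamma) by LOO accuracy over
    the grid, keep the winning fold-wise decision scores; across
    subsamples: mean accuracy, summed confusion counts, F1, mean ROC-AUC
    with a percentile CI (defaults to the 17th-83rd band).
    """
    X = np.asarray(features, dtype=float)
    y_bin, classes = _encode(labels)
    rng = np.random.default_rng(config.seed)
    per = []
    confusion = ConfusionMatrix()
    for rep in range(config.n_subsamples):
        Xb, yb, _ = balance_subsample(X, y_bin, seed=int(rng.integers(2**31)))
        acc, scores, preds, hyper = _eval_subsample(Xb, yb, config)
        auc = roc_auc_pair_counting(scores, yb)
        confusion = ConfusionMatrix(
            tp=confusion.tp + int(np.sum((preds == 1) & (yb == 1))),
            fp=confusion.fp + int(np.sum((preds == 1) & (yb == 0))),
            fn=confusion.fn + int(np.sum((preds == 0) & (yb == 1))),
            tn=confusion.tn + int(np.sum((preds == 0) & (yb == 0))),
        )
        per.append({"accuracy": acc, "roc_auc": auc, "hyperparameters": hyper,
                    "scores": scores, "labels": yb})
    accs = np.array([r["accuracy"] for r in per])
    aucs = np.array([r["roc_auc"] for r in per])
    lo, hi = np.percentile(aucs, config.auc_ci_percentiles)
    return ClassificationReport(
        mean_accuracy=float(accs.mean()),
        p_value=float("nan"),
        confusion=confusion,
        f1=f1_from_confusion(confusion),
        roc_auc=float(aucs.mean()),
        roc_auc_ci=(float(lo), float(hi)),
        per_subsample=per,
    )


def permutation_pvalue(
    features, labels, config: ClassifierConfig,
    observed_accuracy: float | None = None,
    return_null: bool = False,
):
    """Label-permutation p-value for the classification accuracy.

    Null accuracies come from refitting (with the true-data procedure's
    hyperparameter selection) on label shuffles of balanced subsamples,
    pooled across ``n_label_perms`` draws; add-one corrected.
    """
    X = np.asarray(features, dtype=float)
    y_bin, _ = _encode(labels)
    if observed_accuracy is None:
        observed_accuracy = train_eval_loocv(X, y_bin, config).mean_accuracy
    rng = np.random.default_rng(config.seed + 7919)
    # the PCA folds are label-independent: build a pool of balanced
    # subsamples once and share their fold caches across label shuffles
    n_caches = min(config.n_subsamples, config.n_label_perms)
    caches = []
    for _ in range(n_caches):
        Xb, yb, _ = balance_subsample(X, y_bin, seed=int(rng.integers(2**31)))
        folds = _loo_folds(Xb, config.pca_scope, config.variance_threshold)
        caches.append((Xb, yb, folds))
    null = np.empty(config.n_label_perms)
    for t in range(config.n_label_perms):
        Xb, yb, folds = caches[t % n_caches]
        y_perm = rng.permutation(yb)
        acc, *_ = _eval_subsample(Xb, y_perm, config, folds=folds)
        null[t] = acc
    p = (1.0 + np.sum(null >= observed_accuracy)) / (1.0 + config.n_label_perms)
    if return_null:
        return float(p), null
    return float(p)
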