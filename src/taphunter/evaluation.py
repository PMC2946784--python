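"""Classifier evaluation: confusion metrics, ROC/AROC, stratified CV,
and bootstrap comparison of two predictors' AROC.

AROC here is always the Mann-Whitney statistic — the probability that a
randomly chosen binder outscores a randomly chosen non-binder, with ties
counted one half — which equals the trapezoidal area under the empirical ROC
curve. The bootstrap comparator resamples the test set with replacement
(stratified, so both classes survive every replicate) and reports percentile
confidence intervals plus a sign-based two-sided p-value for the AROC
difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .encoding import EncodingConfig, encode_set
from .errors import ValidationError
from .seqio import LabeledPeptideSet
from .svm_model import KernelSpec, TapBinderClassifier


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "TN", "FN"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def confusion_metrics(counts: ConfusionCounts) -> tuple[float, float, float]:
    """Return (SE, SP, ACC); an undefined ratio is returned as NaN.

    SE = TP/(TP+FN), SP = TN/(TN+FP), ACC = (TP+TN)/total. A zero
    denominator yields NaN (an explicit undefined flag), never a silent 0.
    """
    if counts.total == 0:
        raise ValidationError("no evaluated instances")
    se = counts.TP / (counts.TP + counts.FN) if counts.TP + counts.FN else math.nan
    sp = counts.TN / (counts.TN + counts.FP) if counts.TN + counts.FP else math.nan
    acc = (counts.TP + counts.TN) / counts.total
    return se, sp, acc


def counts_from_predictions(
    y_true: Sequence[int], y_pred: Sequence[int]
) -> ConfusionCounts:
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    if yt.shape != yp.shape:
        raise ValidationError("y_true / y_pred length mismatch")
    return ConfusionCounts(
        TP=int(np.sum((yt == 1) & (yp == 1))),
        FP=int(np.sum((yt == -1) & (yp == 1))),
        TN=int(np.sum((yt == -1) & (yp == -1))),
        FN=int(np.sum((yt == 1) & (yp == -1))),
    )


@dataclass
class ROCResult:
    """ROC curve points (FPR, TPR) and the Mann-Whitney AUC."""

    points: list[tuple[float, float]]
    auc: float
    n_pos: int
    n_neg: int


def _mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via midranks: (#(pos>neg) + 0.5 #(pos=neg)) / (n_pos * n_neg)."""
    ranks = rankdata(scores)  # average ranks handle ties exactly
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> ROCResult:
    """Threshold-sweep ROC with trapezoidal AUC equal to the tie-aware
    Mann-Whitney statistic."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise ValidationError("scores / labels length mismatch")
    if not np.all(np.isfinite(s)):
        raise ValidationError("non-finite scores")
    classes = set(np.unique(y).tolist())
    if classes != {-1, 1}:
        raise ValidationError(
            f"labels must contain both +1 and -1, got {sorted(classes)}"
        )
    fpr, tpr, _ = roc_curve(y, s, pos_label=1, drop_intermediate=False)
    auc = _mann_whitney_auc(s, y)
    return ROCResult(
        points=list(zip(fpr.tolist(), tpr.tolist())),
        auc=auc,
        n_pos=int(np.sum(y == 1)),
        n_neg=int(np.sum(y == -1)),
    )


def kfold_split(
    pset: LabeledPeptideSet, k: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic stratified k-fold partition of a labeled set.

    Each fold's class ratio is within one instance of the global ratio;
    folds are disjoint and cover every index.
    """
    if k < 2:
        raise ValidationError(f"k must be >= 2, got {k}")
    y = np.asarray(pset.labels)
    for cls in (1, -1):
        n_cls = int(np.sum(y == cls))
        if n_cls < k:
            raise ValidationError(
                f"class {cls:+d} has only {n_cls} members; needs >= k={k}"
            )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(y)), y)]


@dataclass
class CVResult:
    """Per-fold and aggregate cross-validation metrics.

    ``acc`` defaults to the pooled-prediction accuracy (all held-out
    predictions counted once); the per-fold mean is also reported.
    """

    fold_acc: list[float]
    fold_auc: list[float]
    mean_acc: float
    mean_auc: float
    pooled_acc: float
    pooled_auc: float
    k: int
    seed: int

    @property
    def acc(self) -> float:
        return self.pooled_acc

    @property
    def auc(self) -> float:
        return self.mean_auc


def cross_validate(
    pset: LabeledPeptideSet,
    config: EncodingConfig,
    kernel: KernelSpec | None = None,
    C: float = 1.0,
    k: int = 5,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold CV of the encode-train-score pipeline.

    Per fold: fit on k-1 folds, score the held-out fold; ACC uses the SVM's
    natural threshold 0, AROC is threshold-independent.
    """
    kernel = kernel or KernelSpec()
    pset.require_both_classes()
    X, y = encode_set(pset, config)
    folds = kfold_split(pset, k, seed)
    fold_acc: list[float] = []
    fold_auc: list[float] = []
    pooled_scores = np.empty(len(y))
    for tr, te in folds:
        clf = TapBinderClassifier(
            kernel=kernel.kind, C=C, gamma=kernel.gamma,
            degree=kernel.degree, coef0=kernel.coef0,
        ).fit(X[tr], y[tr])
        scores = clf.decision_function(X[te])
        pooled_scores[te] = scores
        pred = np.where(scores > 0, 1, -1)
        fold_acc.append(float(np.mean(pred == y[te])))
        fold_auc.append(roc_auc(scores, y[te]).auc)
    pooled_pred = np.where(pooled_scores > 0, 1, -1)
    return CVResult(
        fold_acc=fold_acc,
        fold_auc=fold_auc,
        mean_acc=float(np.mean(fold_acc)),
        mean_auc=float(np.mean(fold_auc)),
        pooled_acc=float(np.mean(pooled_pred == y)),
        pooled_auc=roc_auc(pooled_scores, y).auc,
        k=k,
        seed=seed,
    )


@dataclass
class BootstrapComparison:
    mean_auc_a: float
    mean_auc_b: float
    ci95_a: tuple[float, float]
    ci95_b: tuple[float, float]
    mean_delta: float
    ci95_delta: tuple[float, float]
    delta_distribution: list[float] = field(repr=False)
    p_value: float = 1.0
    B: int = 1000
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "mean_auc_a": self.mean_auc_a,
            "mean_auc_b": self.mean_auc_b,
            "ci95_a": list(self.ci95_a),
            "ci95_b": list(self.ci95_b),
            "mean_delta": self.mean_delta,
            "ci95_delta": list(self.ci95_delta),
            "p_value": self.p_value,
            "B": self.B,
            "seed": self.seed,
            "delta_distribution": self.delta_distribution,
        }


def bootstrap_compare(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[int],
    B: int = 1000,
    seed: int = 0,
    subsample_fraction: float = 1.0,
) -> BootstrapComparison:
    """Bootstrap AROC comparison of two predictors scored on the same set.

    Each replicate resamples positives and negatives separately with
    replacement (so both classes always survive), at ``subsample_fraction``
    of the original class sizes. The two-sided p-value for a non-zero AROC
    difference is sign-based: twice the fraction of replicates whose
    difference falls on the opposite side of zero from the mean difference,
    floored at 1/B and capped at 1. A mean difference of exactly zero yields
    p = 1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels, dtype=int)
    if not (a.shape == b.shape == y.shape):
        raise ValidationError(
            f"misaligned inputs: |a|={a.shape}, |b|={b.shape}, |labels|={y.shape}"
        )
    if not (0 < subsample_fraction <= 1):
        raise ValidationError("subsample_fraction must be in (0, 1]")
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == -1)
    if len(pos_idx) == 0 or len(neg_idx) == 0:
        raise ValidationError("both classes required for bootstrap comparison")
    n_pos = max(1, round(subsample_fraction * len(pos_idx)))
    n_neg = max(1, round(subsample_fraction * len(neg_idx)))
    rng = np.random.default_rng(seed)
    auc_a = np.empty(B)
    auc_b = np.empty(B)
    for r in range(B):
        idx = np.concatenate(
            [rng.choice(pos_idx, n_pos), rng.choice(neg_idx, n_neg)]
        )
        auc_a[r] = _mann_whitney_auc(a[idx], y[idx])
        auc_b[r] = _mann_whitney_auc(b[idx], y[idx])
    delta = auc_a - auc_b
    mean_delta = float(delta.mean())
    if mean_delta == 0.0:
        p = 1.0
    else:
        opposite = np.sum(delta * np.sign(mean_delta) <= 0)
        p = min(1.0, max(2.0 * opposite / B, 1.0 / B))
    ci = lambda v: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
    return BootstrapComparison(
        mean_auc_a=float(auc_a.mean()),
        mean_auc_b=float(auc_b.mean()),
        ci95_a=ci(auc_a),
        ci95_b=ci(auc_b),
        mean_delta=mean_delta,
        ci95_delta=ci(delta),
        delta_distribution=delta.tolist(),
        p_value=float(p),
        B=B,
        seed=seed,
    )
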