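"""Multiclass classification metrics: per-class precision/recall/F1, macro and
weighted F1, accuracy, and the multiclass Matthews correlation coefficient.

Conventions
-----------
* A 0/0 precision or recall (class never predicted, or absent from truth) is
  defined as 0, so every per-class F1 is well defined and weighted F1 stays a
  proper weighted mean.
* Class weights ``w_i`` are the proportions of each class among the *true*
  labels of the evaluated samples, so weighted F1 reflects the real class
  composition even when training folds were oversampled.
* The multiclass MCC is the Pearson correlation between the one-hot encoded
  truth and prediction matrices; when either matrix is constant the
  denominator vanishes and the coefficient is defined as 0.  For two classes
  it reduces to the classical binary Matthews coefficient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dataset import ValidationError

__all__ = [
    "ConfusionCounts",
    "ClassMetrics",
    "EvaluationSummary",
    "confusion",
    "summarize",
    "mcc_multiclass",
]


@dataclass
class ConfusionCounts:
    """An L x L confusion matrix with per-class derived counts.

    ``matrix[i, j]`` counts samples of true class ``class_order[i]`` predicted
    as ``class_order[j]``.
    """

    class_order: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int64)
        L = len(self.class_order)
        if self.matrix.shape != (L, L):
            raise ValidationError(
                f"confusion matrix shape {self.matrix.shape} != ({L}, {L})"
            )
        if np.any(self.matrix < 0):
            raise ValidationError("confusion counts must be nonnegative")

    @property
    def n(self) -> int:
        return int(self.matrix.sum())

    @property
    def tp(self) -> np.ndarray:
        return np.diag(self.matrix).copy()

    @property
    def fp(self) -> np.ndarray:
        return self.matrix.sum(axis=0) - np.diag(self.matrix)

    @property
    def fn(self) -> np.ndarray:
        return self.matrix.sum(axis=1) - np.diag(self.matrix)


@dataclass
class ClassMetrics:
    precision: float
    recall: float
    f1: float


@dataclass
class EvaluationSummary:
    """Aggregate metrics of one evaluation (typically pooled CV predictions)."""

    acc: float
    mcc: float
    macro_f1: float
    weighted_f1: float
    per_class: dict[str, ClassMetrics]
    class_weights: dict[str, float]
    per_fold_acc: list[float] = field(default_factory=list)


def _as_label_array(labels) -> np.ndarray:
    return np.asarray([str(l) for l in labels], dtype=object)


def confusion(true_labels, predicted_labels, class_order: list[str]) -> ConfusionCounts:
    """Count the L x L confusion matrix over ``class_order``."""
    t = _as_label_array(true_labels)
    p = _as_label_array(predicted_labels)
    if len(t) == 0:
        raise ValidationError("cannot build a confusion matrix from zero samples")
    if len(t) != len(p):
        raise ValidationError(
            f"length mismatch: {len(t)} true vs {len(p)} predicted labels"
        )
    lut = {c: i for i, c in enumerate(class_order)}
    mat = np.zeros((len(class_order), len(class_order)), dtype=np.int64)
    for ti, pi in zip(t, p):
        if ti not in lut:
            raise ValidationError(f"unknown true label: {ti!r}")
        if pi not in lut:
            raise ValidationError(f"unknown predicted label: {pi!r}")
        mat[lut[ti], lut[pi]] += 1
    return ConfusionCounts(list(class_order), mat)


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def _mcc_from_confusion(mat: np.ndarray) -> float:
    # Pearson correlation of one-hot truth/prediction matrices, written in
    # terms of confusion counts: cov(X,Y) = c*s - sum_k t_k p_k etc.
    mat = np.asarray(mat, dtype=np.float64)
    s = mat.sum()
    c = np.trace(mat)
    t = mat.sum(axis=1)  # true counts per class
    p = mat.sum(axis=0)  # predicted counts per class
    cov_xy = c * s - float(t @ p)
    cov_xx = s * s - float(t @ t)
    cov_yy = s * s - float(p @ p)
    den = math.sqrt(cov_xx) * math.sqrt(cov_yy)
    if den == 0.0:
        return 0.0
    return cov_xy / den


def summarize(conf: ConfusionCounts, per_fold_acc: list[float] | None = None) -> EvaluationSummary:
    """Per-class and aggregate metrics from a confusion matrix."""
    if conf.n < 1:
        raise ValidationError("confusion matrix is empty")
    tp, fp, fn = conf.tp, conf.fp, conf.fn
    per_class: dict[str, ClassMetrics] = {}
    f1s = np.zeros(len(conf.class_order))
    for i, cls in enumerate(conf.class_order):
        prec = _safe_div(tp[i], tp[i] + fp[i])
        rec = _safe_div(tp[i], tp[i] + fn[i])
        f1 = _safe_div(2.0 * prec * rec, prec + rec)
        per_class[cls] = ClassMetrics(prec, rec, f1)
        f1s[i] = f1
    true_counts = conf.matrix.sum(axis=1)
    weights = true_counts / conf.n
    return EvaluationSummary(
        acc=float(np.trace(conf.matrix)) / conf.n,
        mcc=_mcc_from_confusion(conf.matrix),
        macro_f1=float(f1s.mean()),
        weighted_f1=float(f1s @ weights),
        per_class=per_class,
        class_weights={c: float(w) for c, w in zip(conf.class_order, weights)},
        per_fold_acc=list(per_fold_acc) if per_fold_acc is not None else [],
    )


def mcc_multiclass(true_labels, predicted_labels, class_order: list[str]) -> float:
    """Multiclass Matthews correlation coefficient.

    Builds n x L one-hot indicator matrices X (truth) and Y (prediction) over
    ``class_order`` and returns the Pearson correlation between them,

        cov(X, Y) / sqrt(cov(X, X) * cov(Y, Y)),

    with cov(A, B) = sum_k sum_s (A_sk - mean_k(A)) (B_sk - mean_k(B)).
    Returns 0 when either matrix is constant (zero denominator).
    """
    t = _as_label_array(true_labels)
    p = _as_label_array(predicted_labels)
    if len(t) != len(p) or len(t) == 0:
        raise ValidationError("label vectors must be nonempty and equal-length")
    lut = {c: i for i, c in enumerate(class_order)}
    n, L = len(t), len(class_order)
    X = np.zeros((n, L))
    Y = np.zeros((n, L))
    for s in range(n):
        if t[s] not in lut:
            raise ValidationError(f"unknown true label: {t[s]!r}")
        if p[s] not in lut:
            raise ValidationError(f"unknown predicted label: {p[s]!r}")
        X[s, lut[t[s]]] = 1.0
        Y[s, lut[p[s]]] = 1.0
    Xc = X - X.mean(axis=0, keepdims=True)
    Yc = Y - Y.mean(axis=0, keepdims=True)
    cov_xy = float(np.sum(Xc * Yc))
    cov_xx = float(np.sum(Xc * Xc))
    cov_yy = float(np.sum(Yc * Yc))
    den = math.sqrt(cov_xx) * math.sqrt(cov_yy)
    if den == 0.0:
        return 0.0
    return cov_xy / den
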