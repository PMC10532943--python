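"""Incremental feature selection with cross-validated multiclass metrics.

Growing prefix subsets of a ranked gene list (sizes s, 2s, ... up to a cap)
are each evaluated by stratified k-fold cross-validation with a fixed
classifier; training folds are SMOTE-balanced in the active gene subspace,
evaluation folds are left untouched.  The subset size maximizing weighted F1
is the *optimal* size; the smallest size within ``feasible_delta`` of that
maximum is the *feasible* size, preferred when interpretability matters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from .balance import smote_matrix
from .dataset import LabeledDataset, ValidationError
from .evalmetrics import EvaluationSummary, confusion, summarize
from .ranking import FeatureList

logger = logging.getLogger(__name__)

__all__ = [
    "SmoteConfig",
    "IFSConfig",
    "IFSRecord",
    "IFSResult",
    "build_subsets",
    "stratified_folds",
    "evaluate_subset",
    "run_ifs",
    "make_classifier",
]


@dataclass
class SmoteConfig:
    """How class balancing is applied inside cross-validation.

    With ``before_cv=False`` (default) each fold's training part is balanced
    independently, in the gene subspace under evaluation, and test folds stay
    untouched.  ``before_cv=True`` reproduces the leaky variant that balances
    the whole dataset once before splitting; synthetic samples then leak into
    evaluation folds and metrics are optimistically biased.
    """

    enabled: bool = True
    k_neighbors: int = 5
    before_cv: bool = False


@dataclass
class IFSConfig:
    interval: int = 10
    cap: int = 2000
    cv_folds: int = 10
    classifier: str = "random_forest"
    classifier_params: dict = field(default_factory=dict)
    smote: SmoteConfig = field(default_factory=SmoteConfig)
    feasible_delta: float = 0.04
    seed: int = 0

    def validate(self) -> None:
        if self.interval < 1:
            raise ValidationError("interval must be >= 1")
        if self.cap < self.interval:
            raise ValidationError("cap must be >= interval")
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be >= 2")
        if self.classifier not in ("decision_tree", "random_forest"):
            raise ValidationError(f"unknown classifier: {self.classifier!r}")
        if self.feasible_delta < 0:
            raise ValidationError("feasible_delta must be >= 0")


@dataclass
class IFSRecord:
    k: int
    summary: EvaluationSummary


@dataclass
class IFSResult:
    method: str
    classifier: str
    records: list[IFSRecord]
    optimal_k: int
    feasible_k: int

    def record(self, k: int) -> IFSRecord:
        for r in self.records:
            if r.k == k:
                return r
        raise KeyError(k)

    @property
    def optimal(self) -> IFSRecord:
        return self.record(self.optimal_k)

    @property
    def feasible(self) -> IFSRecord:
        return self.record(self.feasible_k)


def build_subsets(feature_list: FeatureList, interval: int = 10, cap: int = 2000) -> list[list[str]]:
    """Prefix subsets of sizes interval, 2*interval, ..., up to min(len, cap).

    A final partial subset covers the remainder when the capped list length
    is not a multiple of ``interval``.
    """
    if interval < 1:
        raise ValidationError("interval must be >= 1")
    m = min(len(feature_list.genes), cap)
    if m == 0:
        raise ValidationError("feature list is empty")
    sizes = list(range(interval, m + 1, interval))
    if not sizes or sizes[-1] != m:
        sizes.append(m)
    return [feature_list.genes[:k] for k in sizes]


def stratified_folds(labels: np.ndarray, n_folds: int, seed: int) -> list[np.ndarray]:
    """Deterministic stratified fold assignment tolerant of tiny classes.

    Each class's shuffled members are dealt round-robin onto the folds, so a
    class smaller than ``n_folds`` simply contributes nothing to some folds
    (logged as a warning) instead of raising.
    """
    labels = np.asarray(labels, dtype=object)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xF01D]))
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    offset = 0
    for cls in sorted(set(labels), key=str):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < n_folds:
            logger.warning(
                "class %r has %d samples for %d folds; some folds will miss it",
                cls, len(idx), n_folds,
            )
        perm = rng.permutation(len(idx))
        for j, i in enumerate(idx[perm]):
            folds[(offset + j) % n_folds].append(int(i))
        offset += len(idx)
    return [np.asarray(sorted(f), dtype=np.intp) for f in folds]


def make_classifier(name: str, params: dict, seed: int):
    if name == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **params)
    if name == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    raise ValidationError(f"unknown classifier: {name!r}")


def evaluate_subset(
    dataset: LabeledDataset, genes: list[str], config: IFSConfig
) -> EvaluationSummary:
    """Cross-validated evaluation of one gene subset.

    Pools out-of-fold predictions over all cells and summarizes them; the
    per-fold accuracies are recorded on the returned summary.
    """
    config.validate()
    if len(genes) == 0:
        raise ValidationError("empty gene subset")
    X = dataset.submatrix(genes)
    labels = dataset.labels
    class_order = dataset.class_order

    if config.smote.enabled and config.smote.before_cv:
        Xs, ls, _ = smote_matrix(
            X, labels, config.smote.k_neighbors, seed=config.seed,
            on_singleton="duplicate",
        )
        if len(ls):
            X = np.vstack([X, Xs])
            labels = np.concatenate([labels, ls])

    folds = stratified_folds(labels, config.cv_folds, config.seed)
    n = len(labels)
    pred = np.empty(n, dtype=object)
    per_fold_acc: list[float] = []
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0xCF17]))
    for test_idx in folds:
        fold_seed = int(rng.integers(2**31))
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        Xtr, ytr = X[mask], labels[mask]
        if config.smote.enabled and not config.smote.before_cv:
            Xs, ls, _ = smote_matrix(
                Xtr, ytr, config.smote.k_neighbors, seed=fold_seed,
                on_singleton="duplicate",
            )
            if len(ls):
                Xtr = np.vstack([Xtr, Xs])
                ytr = np.concatenate([ytr, ls])
        clf = make_classifier(config.classifier, config.classifier_params, fold_seed)
        clf.fit(Xtr, ytr)
        if len(test_idx):
            yp = clf.predict(X[test_idx])
            pred[test_idx] = yp
            per_fold_acc.append(float(np.mean(yp == labels[test_idx])))
        else:
            per_fold_acc.append(float("nan"))
    conf = confusion(labels, pred, class_order)
    return summarize(conf, per_fold_acc=per_fold_acc)


def run_ifs(dataset: LabeledDataset, feature_list: FeatureList, config: IFSConfig) -> IFSResult:
    """Evaluate every prefix subset and select optimal and feasible sizes.

    Optimal: the subset size attaining the maximum weighted F1 (ties broken
    toward the smallest size).  Feasible: the smallest size whose weighted
    F1 is within ``feasible_delta`` of the maximum.
    """
    config.validate()
    subsets = build_subsets(feature_list, config.interval, config.cap)
    records: list[IFSRecord] = []
    for genes in subsets:
        summary = evaluate_subset(dataset, genes, config)
        records.append(IFSRecord(k=len(genes), summary=summary))
        logger.info(
            "IFS %s k=%d weighted_f1=%.4f acc=%.4f",
            feature_list.method, len(genes), summary.weighted_f1, summary.acc,
        )
    best = max(r.summary.weighted_f1 for r in records)
    optimal_k = next(r.k for r in records if r.summary.weighted_f1 == best)
    feasible_k = next(
        r.k for r in records if r.summary.weighted_f1 >= best - config.feasible_delta
    )
    return IFSResult(
        method=feature_list.method,
        classifier=config.classifier,
        records=records,
        optimal_k=optimal_k,
        feasible_k=feasible_k,
    )
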