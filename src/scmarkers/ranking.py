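"""Five feature-ranking schemes for labeled expression matrices.

Each ranker returns a :class:`FeatureList` covering the full gene set,
ordered by score descending with a deterministic tie-break (gene id
ascending).  The schemes:

``lasso``
    One-vs-rest L1-penalized logistic fits; a gene's score is the maximum
    absolute coefficient across classes.  The inverse penalty is scaled by
    1/n so the ranking is invariant to duplicating the dataset's rows, and
    classes are inverse-frequency weighted so minority-class markers are not
    penalized away.
``gbt``
    A gradient-boosted tree ensemble (LightGBM); a gene's score is the
    number of times it is used as a split across the ensemble.
``mcfs``
    Monte Carlo feature selection: many small decision trees, each trained
    on a random gene subset and a random train/test split of the cells.  A
    gene's relative importance aggregates, over every tree node that splits
    on it, the node's information gain weighted by the fraction of training
    samples reaching the node (exponent v) and by the tree's mean per-class
    held-out recall (exponent u).
``mrmr``
    Minimum-redundancy maximum-relevance: greedy selection on discretized
    expression maximizing mutual information with the class label minus the
    mean mutual information with already-selected genes.
``rf``
    Random-forest importance: mean impurity decrease by default, or
    permutation importance (held-out accuracy drop when one gene is
    shuffled) on request.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.tree import DecisionTreeClassifier

from .dataset import LabeledDataset, ValidationError

__all__ = [
    "FeatureList",
    "McfsParams",
    "MrmrParams",
    "rank_lasso",
    "rank_gbt",
    "rank_mcfs",
    "rank_mrmr",
    "rank_rf",
    "rank_features",
    "RANKERS",
]


@dataclass
class FeatureList:
    """One ranker's ordered genes with scores.

    For mRMR the order is the greedy selection order and scores are the
    selection-round criterion values; genes beyond the selected prefix carry
    NaN scores and are appended in tie-break order.
    """

    method: str
    genes: list[str]
    scores: list[float]

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.scores):
            raise ValidationError("genes and scores must have equal length")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("feature list contains duplicate genes")

    def top(self, k: int) -> list[str]:
        return self.genes[:k]


def _ordered(method: str, gene_ids: list[str], scores: np.ndarray) -> FeatureList:
    """Order by score descending, tie-break gene id ascending."""
    order = sorted(range(len(gene_ids)), key=lambda i: (-scores[i], gene_ids[i]))
    return FeatureList(
        method=method,
        genes=[gene_ids[i] for i in order],
        scores=[float(scores[i]) for i in order],
    )


# --------------------------------------------------------------------------
# LASSO-style sparse linear ranking


def rank_lasso(dataset: LabeledDataset, seed: int = 0, C0: float = 1000.0) -> FeatureList:
    """Rank genes by max |coefficient| over one-vs-rest L1 logistic fits.

    ``C0`` sets the inverse regularization strength as ``C0 / n_cells``;
    the 1/n scaling makes the fitted coefficients — hence the ranking —
    invariant to replicating the dataset's rows.
    """
    if len(dataset.class_order) < 2:
        raise ValidationError("ranking needs at least 2 classes")
    X = dataset.matrix
    n = dataset.n_cells
    scores = np.zeros(dataset.n_genes)
    if np.ptp(X, axis=0).max() == 0.0:
        return _ordered("lasso", dataset.gene_ids, scores)
    labels = dataset.labels
    for cls in dataset.class_order:
        y = (labels == cls).astype(int)
        model = LogisticRegression(
            l1_ratio=1.0,
            solver="liblinear",
            C=C0 / n,
            class_weight="balanced",
            random_state=seed,
            max_iter=1000,
        )
        model.fit(X, y)
        scores = np.maximum(scores, np.abs(model.coef_[0]))
    return _ordered("lasso", dataset.gene_ids, scores)


# --------------------------------------------------------------------------
# Gradient-boosted trees (LightGBM split counts)


def rank_gbt(dataset: LabeledDataset, seed: int = 0, **lgbm_kwargs) -> FeatureList:
    """Rank genes by their number of uses as a split in a boosted ensemble."""
    import lightgbm as lgb

    if len(dataset.class_order) < 2:
        raise ValidationError("ranking needs at least 2 classes")
    params = dict(
        random_state=seed,
        n_jobs=1,
        deterministic=True,
        force_row_wise=True,
        verbose=-1,
    )
    params.update(lgbm_kwargs)
    model = lgb.LGBMClassifier(**params)
    model.fit(dataset.matrix, dataset.label_codes())
    counts = model.booster_.feature_importance(importance_type="split")
    return _ordered("gbt", dataset.gene_ids, counts.astype(np.float64))


# --------------------------------------------------------------------------
# Monte Carlo feature selection


@dataclass
class McfsParams:
    """Monte Carlo feature selection parameters.

    ``n_subsets`` (s) gene subsets of size ``subset_size`` (m, default
    ceil(0.1 * n_genes)) are drawn; ``trees_per_subset`` (t) trees are
    trained per subset, each on a fresh random ``train_fraction`` split of
    the cells.  ``u`` and ``v`` weight the tree's held-out mean per-class
    recall and the node sample fraction in the importance aggregation.
    """

    n_subsets: int = 100
    trees_per_subset: int = 5
    subset_size: int | None = None
    u: float = 1.0
    v: float = 1.0
    train_fraction: float = 2.0 / 3.0
    seed: int = 0

    def validate(self, n_genes: int) -> int:
        if self.n_subsets * self.trees_per_subset < 1:
            raise ValidationError("n_subsets * trees_per_subset must be >= 1")
        m = self.subset_size or int(math.ceil(0.1 * n_genes))
        if m > n_genes:
            raise ValidationError(f"subset_size {m} > n_genes {n_genes}")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValidationError("train_fraction must lie in (0, 1)")
        if self.u < 0 or self.v < 0:
            raise ValidationError("u and v must be >= 0")
        return m


def _tree_gain_contributions(
    tree: DecisionTreeClassifier, n_train: int, v: float
) -> dict[int, float]:
    """Per-feature sum of IG(node) * (fraction of training samples at node)^v."""
    t = tree.tree_
    out: dict[int, float] = {}
    for node in range(t.node_count):
        left, right = t.children_left[node], t.children_right[node]
        if left == -1:  # leaf
            continue
        w = t.weighted_n_node_samples
        gain = t.impurity[node] - (
            w[left] / w[node] * t.impurity[left]
            + w[right] / w[node] * t.impurity[right]
        )
        frac = w[node] / n_train
        f = int(t.feature[node])
        out[f] = out.get(f, 0.0) + gain * frac**v
    return out


def _mean_class_recall(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean per-class recall over the classes present in ``y_true``."""
    recalls = []
    for cls in np.unique(y_true):
        mask = y_true == cls
        recalls.append(float(np.mean(y_pred[mask] == cls)))
    return float(np.mean(recalls))


def rank_mcfs(dataset: LabeledDataset, params: McfsParams | None = None) -> FeatureList:
    """Monte Carlo feature selection relative-importance ranking."""
    params = params or McfsParams()
    m = params.validate(dataset.n_genes)
    X = dataset.matrix
    y = dataset.label_codes()
    n = dataset.n_cells
    n_train = max(1, int(round(params.train_fraction * n)))
    if n_train >= n:
        n_train = n - 1
    rng = np.random.default_rng(np.random.SeedSequence([int(params.seed), 0x3C55]))
    ri = np.zeros(dataset.n_genes)
    for _ in range(params.n_subsets):
        cols = np.sort(rng.choice(dataset.n_genes, size=m, replace=False))
        Xs = X[:, cols]
        for _ in range(params.trees_per_subset):
            perm = rng.permutation(n)
            tr, te = perm[:n_train], perm[n_train:]
            tree = DecisionTreeClassifier(
                criterion="entropy",
                random_state=int(rng.integers(2**31)),
            )
            tree.fit(Xs[tr], y[tr])
            wacc = _mean_class_recall(y[te], tree.predict(Xs[te]))
            contrib = _tree_gain_contributions(tree, len(tr), params.v)
            if not contrib:
                continue
            w = wacc**params.u if params.u > 0 else 1.0
            for f, g in contrib.items():
                ri[cols[f]] += w * g
    return _ordered("mcfs", dataset.gene_ids, ri)


# --------------------------------------------------------------------------
# mRMR


@dataclass
class MrmrParams:
    """mRMR parameters.

    ``discretization`` is ``("mean_std", alpha)`` — 3 states split at
    mean ± alpha*std per gene — or ``("equal_frequency", bins)``.
    ``criterion`` is ``"difference"`` (relevance − mean redundancy, MID) or
    ``"quotient"`` (relevance / mean redundancy, MIQ).  ``n_select`` of None
    selects min(500, n_genes) genes; the remaining genes are appended in
    tie-break order with NaN scores.  For cost control, candidate genes are
    pre-filtered to the ``max_prefilter`` highest-relevance genes.
    """

    n_select: int | None = None
    discretization: tuple[str, float] = ("mean_std", 1.0)
    criterion: str = "difference"
    max_prefilter: int = 5000

    def validate(self, n_genes: int) -> int:
        n_select = self.n_select if self.n_select is not None else min(500, n_genes)
        if n_select > n_genes:
            raise ValidationError(f"n_select {n_select} > n_genes {n_genes}")
        if self.criterion not in ("difference", "quotient"):
            raise ValidationError(f"unknown mRMR criterion: {self.criterion!r}")
        if self.discretization[0] not in ("mean_std", "equal_frequency"):
            raise ValidationError(
                f"unknown discretization: {self.discretization[0]!r}"
            )
        return n_select


def discretize(X: np.ndarray, scheme: tuple[str, float]) -> np.ndarray:
    """Per-gene discretization into small integer states."""
    kind, param = scheme
    n, p = X.shape
    out = np.zeros((n, p), dtype=np.int8)
    if kind == "mean_std":
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        lo = mu - param * sd
        hi = mu + param * sd
        out = ((X > lo).astype(np.int8) + (X > hi).astype(np.int8))
    else:  # equal_frequency
        bins = int(param)
        qs = np.quantile(X, np.linspace(0, 1, bins + 1)[1:-1], axis=0)
        for j in range(p):
            out[:, j] = np.searchsorted(np.unique(qs[:, j]), X[:, j], side="right")
    return out


def _mi_from_joint(joint: np.ndarray) -> np.ndarray:
    """Mutual information (nats) from joint count arrays (..., A, B)."""
    joint = joint.astype(np.float64)
    n = joint.sum(axis=(-2, -1), keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        pj = joint / n
        pa = pj.sum(axis=-1, keepdims=True)
        pb = pj.sum(axis=-2, keepdims=True)
        term = pj * (np.log(pj) - np.log(pa) - np.log(pb))
    term = np.where(joint > 0, term, 0.0)
    return term.sum(axis=(-2, -1))


def _relevance(states: np.ndarray, y_onehot: np.ndarray, n_states: int) -> np.ndarray:
    """I(gene; label) for every gene, vectorized over genes."""
    p = states.shape[1]
    L = y_onehot.shape[1]
    joint = np.empty((p, n_states, L))
    for a in range(n_states):
        joint[:, a, :] = (states == a).astype(np.float64).T @ y_onehot
    return _mi_from_joint(joint)


def mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """MI (nats) between two discrete vectors; the brute-force definition."""
    av, ai = np.unique(a, return_inverse=True)
    bv, bi = np.unique(b, return_inverse=True)
    joint = np.zeros((len(av), len(bv)))
    np.add.at(joint, (ai, bi), 1.0)
    return float(_mi_from_joint(joint))


def rank_mrmr(dataset: LabeledDataset, params: MrmrParams | None = None) -> FeatureList:
    """Greedy minimum-redundancy maximum-relevance gene selection."""
    params = params or MrmrParams()
    n_select = params.validate(dataset.n_genes)
    states = discretize(dataset.matrix, params.discretization)
    n_states = int(states.max()) + 1
    y = dataset.label_codes()
    L = len(dataset.class_order)
    y_onehot = np.zeros((len(y), L))
    y_onehot[np.arange(len(y)), y] = 1.0

    relevance = _relevance(states, y_onehot, n_states)
    gene_ids = dataset.gene_ids
    p = dataset.n_genes

    # cost control: restrict the candidate pool to the most relevant genes
    if p > params.max_prefilter:
        pool_order = sorted(range(p), key=lambda i: (-relevance[i], gene_ids[i]))
        pool = np.asarray(pool_order[: params.max_prefilter])
    else:
        pool = np.arange(p)
    n_select = min(n_select, len(pool))

    onehots = [
        (states[:, pool] == a).astype(np.float64) for a in range(n_states)
    ]  # each n x |pool|
    selected: list[int] = []  # indices into pool
    selected_set: set[int] = set()
    scores_sel: list[float] = []
    red_sum = np.zeros(len(pool))  # sum of MI(g, s) over selected s
    eps = 1e-12
    for round_no in range(n_select):
        if round_no == 0:
            crit = relevance[pool].copy()
        else:
            mean_red = red_sum / len(selected)
            if params.criterion == "difference":
                crit = relevance[pool] - mean_red
            else:
                crit = relevance[pool] / (mean_red + eps)
        best = min(
            (i for i in range(len(pool)) if i not in selected_set),
            key=lambda i: (-crit[i], gene_ids[pool[i]]),
        )
        selected.append(best)
        selected_set.add(best)
        scores_sel.append(float(crit[best]))
        if round_no < n_select - 1:
            # update redundancy sums with MI(g, newly selected) for all g
            s_states = states[:, pool[best]]
            s_onehot = np.zeros((len(y), n_states))
            s_onehot[np.arange(len(y)), s_states] = 1.0
            joint = np.empty((len(pool), n_states, n_states))
            for a in range(n_states):
                joint[:, a, :] = onehots[a].T @ s_onehot
            red_sum += _mi_from_joint(joint)

    chosen = [int(pool[i]) for i in selected]
    rest = sorted(set(range(p)) - set(chosen), key=lambda i: gene_ids[i])
    return FeatureList(
        method="mrmr",
        genes=[gene_ids[i] for i in chosen] + [gene_ids[i] for i in rest],
        scores=scores_sel + [float("nan")] * len(rest),
    )


# --------------------------------------------------------------------------
# Random forest


def rank_rf(
    dataset: LabeledDataset,
    seed: int = 0,
    importance: str = "impurity",
    n_estimators: int = 100,
    n_repeats: int = 5,
) -> FeatureList:
    """Random-forest gene importance ranking.

    ``importance="impurity"`` (default) uses mean impurity decrease from a
    forest fit on all cells.  ``importance="permutation"`` fits on a
    stratified 2/3 split and scores each gene by the held-out accuracy drop
    when its values are shuffled.
    """
    if importance not in ("impurity", "permutation"):
        raise ValidationError(f"unknown importance type: {importance!r}")
    X = dataset.matrix
    y = dataset.label_codes()
    forest = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1
    )
    if importance == "impurity":
        forest.fit(X, y)
        scores = forest.feature_importances_
    else:
        counts = np.bincount(y)
        strat = y if counts.min() >= 2 else None
        Xtr, Xte, ytr, yte = train_test_split(
            X, y, train_size=2.0 / 3.0, random_state=seed, stratify=strat
        )
        forest.fit(Xtr, ytr)
        res = permutation_importance(
            forest, Xte, yte, n_repeats=n_repeats, random_state=seed, n_jobs=1
        )
        scores = res.importances_mean
    return _ordered("rf", dataset.gene_ids, np.asarray(scores, dtype=np.float64))


# --------------------------------------------------------------------------
# dispatch

RANKERS = ("lasso", "gbt", "mcfs", "mrmr", "rf")


def rank_features(
    dataset: LabeledDataset,
    method: str,
    seed: int = 0,
    mcfs_params: McfsParams | None = None,
    mrmr_params: MrmrParams | None = None,
    **kwargs,
) -> FeatureList:
    """Run one ranking scheme by name."""
    if method == "lasso":
        return rank_lasso(dataset, seed=seed, **kwargs)
    if method == "gbt":
        return rank_gbt(dataset, seed=seed, **kwargs)
    if method == "mcfs":
        params = mcfs_params or McfsParams(seed=seed)
        return rank_mcfs(dataset, params)
    if method == "mrmr":
        return rank_mrmr(dataset, mrmr_params)
    if method == "rf":
        return rank_rf(dataset, seed=seed, **kwargs)
    raise ValidationError(f"unknown ranking method: {method!r}")
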