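"""Decision-tree rule extraction and rule-group analysis.

A decision tree trained on selected genes is decompiled into one
classification rule per leaf: the conjunction of gene-threshold predicates
along the root-to-leaf path, predicting the leaf's majority class.  The
rules of one tree partition the feature space — every input satisfies
exactly one rule — so the rule group is an exact, human-readable rewriting
of the tree.  Rule groups are then summarized per class, as binary
class x gene incidence matrices, and by hierarchical clustering of cell
types on those matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from sklearn.tree import DecisionTreeClassifier

from .balance import smote_matrix
from .dataset import LabeledDataset, ValidationError

__all__ = [
    "Predicate",
    "Rule",
    "RuleGroup",
    "train_rule_tree",
    "extract_rules",
    "apply_rules",
    "rules_per_class",
    "rule_gene_matrix",
    "cluster_cell_types",
]


@dataclass(frozen=True)
class Predicate:
    """One gene-expression threshold test: ``gene <= threshold`` or ``>``."""

    gene: str
    op: str  # "<=" or ">"
    threshold: float

    def __post_init__(self) -> None:
        if self.op not in ("<=", ">"):
            raise ValidationError(f"predicate op must be '<=' or '>', got {self.op!r}")
        if not np.isfinite(self.threshold):
            raise ValidationError("predicate threshold must be finite")

    def holds(self, value: float) -> bool:
        return value <= self.threshold if self.op == "<=" else value > self.threshold

    def __str__(self) -> str:
        return f"{self.gene} {self.op} {self.threshold:.4g}"


@dataclass
class Rule:
    """One root-to-leaf path: a conjunction of predicates and its verdict."""

    rule_id: int
    predicates: list[Predicate]
    predicted_class: str
    support: int
    purity: float

    def __str__(self) -> str:
        cond = " AND ".join(str(p) for p in self.predicates) or "TRUE"
        return (
            f"IF {cond} THEN {self.predicted_class} "
            f"(support={self.support}, purity={self.purity:.4g})"
        )


@dataclass
class RuleGroup:
    """All rules of one tree; ``method`` names the feature list it came from."""

    method: str
    class_order: list[str]
    rules: list[Rule]
    genes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "class_order": list(self.class_order),
            "genes": list(self.genes),
            "rules": [
                {
                    "id": r.rule_id,
                    "predicates": [
                        {"gene": p.gene, "op": p.op, "threshold": p.threshold}
                        for p in r.predicates
                    ],
                    "class": r.predicted_class,
                    "support": r.support,
                    "purity": r.purity,
                }
                for r in self.rules
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RuleGroup":
        return cls(
            method=d["method"],
            class_order=list(d["class_order"]),
            genes=list(d.get("genes", [])),
            rules=[
                Rule(
                    rule_id=int(r["id"]),
                    predicates=[
                        Predicate(p["gene"], p["op"], float(p["threshold"]))
                        for p in r["predicates"]
                    ],
                    predicted_class=r["class"],
                    support=int(r["support"]),
                    purity=float(r["purity"]),
                )
                for r in d["rules"]
            ],
        )


def train_rule_tree(
    dataset: LabeledDataset,
    genes: list[str],
    seed: int = 0,
    oversample: bool = False,
    k_neighbors: int = 5,
    **tree_params,
) -> tuple[DecisionTreeClassifier, list[str]]:
    """Fit one decision tree on all cells restricted to ``genes``.

    With ``oversample=True`` the training matrix is SMOTE-balanced first; by
    default the tree sees the real cells only, so the extracted rules
    describe real expression patterns.  Returns the fitted tree and the gene
    order of its feature axis.
    """
    if not genes:
        raise ValidationError("train_rule_tree needs a nonempty gene list")
    X = dataset.submatrix(genes)
    y = dataset.labels
    if oversample:
        Xs, ls, _ = smote_matrix(X, y, k_neighbors, seed=seed)
        if len(ls):
            X = np.vstack([X, Xs])
            y = np.concatenate([y, ls])
    tree = DecisionTreeClassifier(random_state=seed, **tree_params)
    tree.fit(X, y)
    return tree, list(genes)


def extract_rules(
    tree: DecisionTreeClassifier, genes: list[str], method: str = "tree"
) -> RuleGroup:
    """Decompile a fitted tree into one rule per leaf (root-to-leaf order)."""
    t = tree.tree_
    classes = [str(c) for c in tree.classes_]
    rules: list[Rule] = []

    def walk(node: int, path: list[Predicate]) -> None:
        left, right = t.children_left[node], t.children_right[node]
        if left == -1:
            majority = int(np.argmax(t.value[node][0]))
            support = int(round(t.weighted_n_node_samples[node]))
            purity = float(t.value[node][0][majority] / t.value[node][0].sum())
            rules.append(
                Rule(
                    rule_id=len(rules) + 1,
                    predicates=list(path),
                    predicted_class=classes[majority],
                    support=support,
                    purity=purity,
                )
            )
            return
        gene = genes[int(t.feature[node])]
        thr = float(t.threshold[node])
        walk(left, path + [Predicate(gene, "<=", thr)])
        walk(right, path + [Predicate(gene, ">", thr)])

    walk(0, [])
    return RuleGroup(method=method, class_order=classes, rules=rules, genes=list(genes))


def apply_rules(group: RuleGroup, sample: dict[str, float] | "np.ndarray", genes: list[str] | None = None) -> str:
    """Classify one sample with a rule group.

    ``sample`` is a mapping gene -> expression value, or a vector parallel
    to ``genes``.  Exactly one rule must match; zero or multiple matches
    indicate a corrupted rule group and raise.
    """
    if not isinstance(sample, dict):
        if genes is None:
            raise ValidationError("vector samples require the genes argument")
        sample = {g: float(v) for g, v in zip(genes, sample)}
    matches = []
    for rule in group.rules:
        ok = True
        for pred in rule.predicates:
            if pred.gene not in sample:
                raise ValidationError(f"sample is missing gene {pred.gene!r}")
            if not pred.holds(sample[pred.gene]):
                ok = False
                break
        if ok:
            matches.append(rule)
    if len(matches) != 1:
        raise ValidationError(
            f"rule group must match exactly one rule, matched {len(matches)}"
        )
    return matches[0].predicted_class


def apply_rules_matrix(group: RuleGroup, X: np.ndarray, genes: list[str]) -> np.ndarray:
    """Vectorized :func:`apply_rules` over the rows of ``X``."""
    gene_idx = {g: i for i, g in enumerate(genes)}
    n = X.shape[0]
    pred = np.empty(n, dtype=object)
    matched = np.zeros(n, dtype=np.int64)
    for rule in group.rules:
        mask = np.ones(n, dtype=bool)
        for p in rule.predicates:
            if p.gene not in gene_idx:
                raise ValidationError(f"samples are missing gene {p.gene!r}")
            col = X[:, gene_idx[p.gene]]
            mask &= (col <= p.threshold) if p.op == "<=" else (col > p.threshold)
        pred[mask] = rule.predicted_class
        matched += mask
    if not np.all(matched == 1):
        raise ValidationError("rule group did not match every sample exactly once")
    return pred


def rules_per_class(group: RuleGroup) -> dict[str, int]:
    """Number of rules predicting each class (0 for classes with no rule)."""
    out = {c: 0 for c in group.class_order}
    for r in group.rules:
        out[r.predicted_class] = out.get(r.predicted_class, 0) + 1
    return out


def rule_gene_matrix(group: RuleGroup):
    """Binary class x gene incidence: 1 iff some rule for the class tests the gene.

    Columns cover only genes referenced by at least one rule; rows cover the
    classes (in ``class_order``) that received at least one rule.
    """
    import pandas as pd

    used_genes = sorted({p.gene for r in group.rules for p in r.predicates})
    classes = [c for c in group.class_order if any(r.predicted_class == c for r in group.rules)]
    mat = pd.DataFrame(0, index=classes, columns=used_genes, dtype=int)
    for r in group.rules:
        for p in r.predicates:
            mat.loc[r.predicted_class, p.gene] = 1
    return mat


def cluster_cell_types(matrix) -> tuple[np.ndarray, list[str]]:
    """Average-linkage hierarchical clustering of classes on Jaccard distance.

    ``matrix`` is the binary class x gene incidence (pandas DataFrame).
    Rows are sorted by class name first so ties merge deterministically.
    Returns the scipy linkage table and the dendrogram leaf order (class
    names).
    """
    mat = matrix.sort_index()
    names = [str(i) for i in mat.index]
    if len(names) < 2:
        raise ValidationError("clustering needs at least 2 classes")
    dense = mat.to_numpy().astype(bool)
    dist = pdist(dense, metric="jaccard")
    dist = np.nan_to_num(dist, nan=0.0)  # two all-zero rows are identical
    Z = linkage(dist, method="average")
    order = [names[i] for i in leaves_list(Z)]
    return Z, order
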