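"""Run-level reporting: top-list intersections and the end-to-end pipeline.

``intersect_top_features`` computes the full Venn decomposition of the five
rankers' top-k gene sets: for each of the 31 nonempty method combinations,
the genes exclusive to exactly that combination.  ``run_pipeline``
orchestrates the whole analysis — data, five feature lists, IFS with both
classifiers, optimal/feasible summary, rule groups, Venn table, cell-type
dendrograms — into a deterministic artifact directory with a JSON manifest.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dataio
from .dataset import LabeledDataset, ValidationError
from .ifs import IFSConfig, IFSResult, run_ifs
from .ranking import (
    FeatureList,
    McfsParams,
    MrmrParams,
    RANKERS,
    rank_features,
)
from .rules import (
    apply_rules_matrix,
    cluster_cell_types,
    extract_rules,
    rule_gene_matrix,
    rules_per_class,
    train_rule_tree,
)
from .synthdata import SyntheticSpec, generate_dataset

logger = logging.getLogger(__name__)

__all__ = ["intersect_top_features", "PipelineConfig", "run_pipeline"]


def intersect_top_features(
    lists: list[FeatureList], ks: list[int]
) -> pd.DataFrame:
    """Venn decomposition of the rankers' top-k gene sets.

    Returns one row per nonempty method combination (2^m - 1 rows) with the
    membership flags, the count of genes exclusive to that combination, and
    the gene ids themselves.  Region counts sum to the size of the union.
    """
    methods = [fl.method for fl in lists]
    if len(set(methods)) != len(methods):
        raise ValidationError(f"duplicate method names: {methods}")
    if len(ks) != len(lists):
        raise ValidationError("need one k per feature list")
    tops = []
    for fl, k in zip(lists, ks):
        if k > len(fl.genes):
            raise ValidationError(
                f"k={k} exceeds length of the {fl.method} list ({len(fl.genes)})"
            )
        tops.append(set(fl.top(k)))
    union = set().union(*tops)
    membership: dict[tuple[bool, ...], list[str]] = {}
    for g in union:
        key = tuple(g in t for t in tops)
        membership.setdefault(key, []).append(g)
    rows = []
    for r in range(len(methods), 0, -1):
        for combo in itertools.combinations(range(len(methods)), r):
            key = tuple(i in combo for i in range(len(methods)))
            genes = sorted(membership.get(key, []))
            row = {m: key[i] for i, m in enumerate(methods)}
            row["count"] = len(genes)
            row["genes"] = ";".join(genes)
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class PipelineConfig:
    """Configuration of one end-to-end run.

    Either ``synth`` (generate data) or the three ``data_*`` paths (load
    data) must be provided.  ``methods`` defaults to all five rankers.
    """

    synth: SyntheticSpec | None = None
    data_matrix: str | None = None
    data_labels: str | None = None
    data_genes: str | None = None
    data_cells: str | None = None
    transpose: bool = False
    methods: tuple[str, ...] = RANKERS
    mcfs: McfsParams | None = None
    mrmr: MrmrParams | None = None
    ifs: IFSConfig = field(default_factory=IFSConfig)
    dt_params: dict = field(default_factory=dict)
    rf_params: dict = field(default_factory=dict)
    rule_oversample: bool = False
    seed: int = 0

    def load_dataset(self) -> LabeledDataset:
        if self.synth is not None:
            return generate_dataset(self.synth)
        if self.data_matrix is None or self.data_labels is None:
            raise ValidationError("config needs either synth or data_matrix+data_labels")
        return dataio.read_labeled_dataset(
            self.data_matrix, self.data_labels, self.data_genes, self.data_cells,
            transpose=self.transpose,
        )


def _summary_row(method: str, classifier: str, rec, role: str) -> dict:
    s = rec.summary
    return {
        "feature_list": method,
        "classifier": classifier,
        "role": role,
        "n_features": rec.k,
        "acc": round(s.acc, 6),
        "mcc": round(s.mcc, 6),
        "macro_f1": round(s.macro_f1, 6),
        "weighted_f1": round(s.weighted_f1, 6),
    }


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Execute the full analysis and write a deterministic artifact directory.

    Artifacts: per-method feature lists and IFS curves (both classifiers), a
    15-row optimal/feasible summary table, per-method rule groups (JSON +
    text) with per-class rule counts and dendrograms, the Venn table of
    feasible top sets, and ``manifest.json`` recording all parameters.
    Stage failures abort with the stage name; partial outputs stay on disk
    and the manifest flags the run incomplete.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "methods": list(config.methods),
        "ifs": {
            "interval": config.ifs.interval,
            "cap": config.ifs.cap,
            "cv_folds": config.ifs.cv_folds,
            "feasible_delta": config.ifs.feasible_delta,
            "smote": vars(config.ifs.smote).copy(),
        },
        "complete": False,
    }
    stage = "setup"
    try:
        stage = "data"
        dataset = config.load_dataset()
        manifest["n_cells"] = dataset.n_cells
        manifest["n_genes"] = dataset.n_genes
        manifest["n_classes"] = len(dataset.class_order)
        logger.info("pipeline: %d cells x %d genes, %d classes",
                    dataset.n_cells, dataset.n_genes, len(dataset.class_order))

        stage = "ranking"
        lists: dict[str, FeatureList] = {}
        for method in config.methods:
            logger.info("ranking: %s", method)
            lists[method] = rank_features(
                dataset, method, seed=config.seed,
                mcfs_params=config.mcfs, mrmr_params=config.mrmr,
            )
            dataio.write_feature_list(lists[method], outdir / f"features_{method}.tsv")

        stage = "ifs"
        results: dict[tuple[str, str], IFSResult] = {}
        for clf in ("decision_tree", "random_forest"):
            cfg = IFSConfig(
                interval=config.ifs.interval,
                cap=config.ifs.cap,
                cv_folds=config.ifs.cv_folds,
                classifier=clf,
                classifier_params=dict(
                    config.dt_params if clf == "decision_tree" else config.rf_params
                ),
                smote=config.ifs.smote,
                feasible_delta=config.ifs.feasible_delta,
                seed=config.seed,
            )
            for method in config.methods:
                logger.info("IFS: %s x %s", method, clf)
                res = run_ifs(dataset, lists[method], cfg)
                results[(method, clf)] = res
                dataio.write_ifs_table(res, outdir / f"ifs_{method}_{clf}.csv")

        stage = "summary"
        rows = []
        for method in config.methods:
            dt = results[(method, "decision_tree")]
            rf = results[(method, "random_forest")]
            rows.append(_summary_row(method, "decision_tree", dt.optimal, "optimal"))
            rows.append(_summary_row(method, "random_forest", rf.optimal, "optimal"))
            rows.append(_summary_row(method, "random_forest", rf.feasible, "feasible"))
        pd.DataFrame(rows).to_csv(outdir / "classifier_summary.csv", index=False)

        stage = "rules"
        for method in config.methods:
            k = results[(method, "decision_tree")].optimal_k
            genes = lists[method].top(k)
            tree, gene_order = train_rule_tree(
                dataset, genes, seed=config.seed, oversample=config.rule_oversample
            )
            group = extract_rules(tree, gene_order, method=method)
            dataio.write_rules(
                group, outdir / f"rules_{method}.json", outdir / f"rules_{method}.txt"
            )
            counts = rules_per_class(group)
            pd.DataFrame(
                {"cell_type": list(counts), "n_rules": list(counts.values())}
            ).to_csv(outdir / f"rule_counts_{method}.csv", index=False)
            mat = rule_gene_matrix(group)
            mat.to_csv(outdir / f"rule_gene_matrix_{method}.csv", index_label="cell_type")
            if mat.shape[0] >= 2:
                Z, order = cluster_cell_types(mat)
                pd.DataFrame(
                    Z, columns=["node_a", "node_b", "distance", "n_leaves"]
                ).to_csv(outdir / f"dendrogram_{method}.csv", index=False)
                (outdir / f"dendrogram_order_{method}.txt").write_text(
                    "\n".join(order) + "\n", encoding="utf-8"
                )
            # sanity: the rule group must reproduce the tree on the data
            pred_rules = apply_rules_matrix(group, dataset.submatrix(gene_order), gene_order)
            pred_tree = tree.predict(dataset.submatrix(gene_order))
            if not np.array_equal(pred_rules.astype(str), pred_tree.astype(str)):
                raise ValidationError(f"rule group for {method} diverges from its tree")

        stage = "venn"
        feasible_ks = [results[(m, "random_forest")].feasible_k for m in config.methods]
        venn = intersect_top_features([lists[m] for m in config.methods], feasible_ks)
        venn.to_csv(outdir / "venn_feasible.csv", index=False)
        manifest["feasible_ks"] = dict(zip(config.methods, feasible_ks))
        manifest["optimal_ks_dt"] = {
            m: results[(m, "decision_tree")].optimal_k for m in config.methods
        }
        manifest["optimal_ks_rf"] = {
            m: results[(m, "random_forest")].optimal_k for m in config.methods
        }

        manifest["complete"] = True
    except Exception:
        manifest["failed_stage"] = stage
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True) + "\n", encoding="utf-8"
        )
        logger.exception("pipeline failed at stage %r", stage)
        raise
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
    return outdir
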