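"""Readers and writers for the formats the pipeline touches.

Expression matrices come in as MatrixMarket coordinate files with gene/cell
sidecar TSVs, or as dense TSVs (header row = gene ids, first column = cell
ids).  In memory the orientation is always cells-as-rows; ``transpose=True``
handles the genes-as-rows dialect used by CellRanger-style exports.  All
writers emit UTF-8 text with deterministic field order, and every
writer/reader pair is a bijection on valid content.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .dataset import LabeledDataset, ValidationError
from .ifs import IFSResult
from .ranking import FeatureList
from .rules import RuleGroup

__all__ = [
    "ParseError",
    "read_expression",
    "write_expression",
    "read_labels",
    "write_labels",
    "read_labeled_dataset",
    "write_labeled_dataset",
    "read_feature_list",
    "write_feature_list",
    "read_ifs_table",
    "write_ifs_table",
    "read_rules",
    "write_rules",
]


class ParseError(ValueError):
    """A file violated its format contract; the message names file and issue."""


def _read_id_column(path: Path) -> list[str]:
    ids = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    return ids


def read_expression(
    matrix_path,
    genes_path=None,
    cells_path=None,
    transpose: bool = False,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Load an expression matrix; returns (matrix, gene_ids, cell_ids).

    MatrixMarket input needs both sidecar paths; a dense TSV needs neither.
    The returned matrix is dense, cells x genes, finite and nonnegative.
    """
    matrix_path = Path(matrix_path)
    if matrix_path.suffix in (".mtx", ".gz") or matrix_path.name.endswith(".mtx.gz"):
        if genes_path is None or cells_path is None:
            raise ParseError(f"{matrix_path}: MatrixMarket input needs gene and cell sidecars")
        mat = spio.mmread(str(matrix_path))
        mat = np.asarray(mat.todense() if sparse.issparse(mat) else mat, dtype=np.float64)
        if transpose:
            mat = mat.T
        gene_ids = _read_id_column(Path(genes_path))
        cell_ids = _read_id_column(Path(cells_path))
        if mat.shape != (len(cell_ids), len(gene_ids)):
            raise ParseError(
                f"{matrix_path}: matrix is {mat.shape[0]} x {mat.shape[1]} but sidecars "
                f"declare {len(cell_ids)} cells x {len(gene_ids)} genes"
            )
    else:
        df = pd.read_csv(matrix_path, sep="\t", index_col=0)
        if transpose:
            df = df.T
        gene_ids = [str(g) for g in df.columns]
        cell_ids = [str(c) for c in df.index]
        mat = df.to_numpy(dtype=np.float64)
    if len(set(gene_ids)) != len(gene_ids):
        raise ParseError(f"{matrix_path}: duplicate gene ids")
    if len(set(cell_ids)) != len(cell_ids):
        raise ParseError(f"{matrix_path}: duplicate cell ids")
    if not np.all(np.isfinite(mat)):
        raise ParseError(f"{matrix_path}: non-finite expression values")
    if np.any(mat < 0):
        raise ParseError(f"{matrix_path}: negative expression values")
    return mat, gene_ids, cell_ids


def write_expression(
    matrix: np.ndarray,
    gene_ids: list[str],
    cell_ids: list[str],
    matrix_path,
    genes_path=None,
    cells_path=None,
) -> None:
    """Write a matrix as MatrixMarket + sidecars (.mtx) or dense TSV."""
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        if genes_path is None or cells_path is None:
            raise ParseError(f"{matrix_path}: MatrixMarket output needs sidecar paths")
        spio.mmwrite(str(matrix_path), sparse.coo_matrix(matrix))
        Path(genes_path).write_text("".join(f"{g}\n" for g in gene_ids), encoding="utf-8")
        Path(cells_path).write_text("".join(f"{c}\n" for c in cell_ids), encoding="utf-8")
    else:
        df = pd.DataFrame(matrix, index=list(cell_ids), columns=list(gene_ids))
        df.to_csv(matrix_path, sep="\t", index_label="cell_id")


def read_labels(path, cell_ids: list[str]) -> np.ndarray:
    """Read a labels TSV (cell_id <tab> cell_type) aligned to ``cell_ids``."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected two columns (cell_id, cell_type)")
    mapping = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    unknown = sorted(set(df.iloc[:, 0]) - set(cell_ids))
    if unknown:
        raise ParseError(f"{path}: label file names unknown cell ids: {unknown[:5]}")
    missing = [c for c in cell_ids if c not in mapping]
    if missing:
        raise ParseError(f"{path}: no label for cell ids: {missing[:5]}")
    return np.asarray([mapping[c] for c in cell_ids], dtype=object)


def write_labels(labels, cell_ids: list[str], path) -> None:
    pd.DataFrame({"cell_id": list(cell_ids), "cell_type": list(labels)}).to_csv(
        path, sep="\t", index=False
    )


def read_labeled_dataset(
    matrix_path, labels_path, genes_path=None, cells_path=None, transpose=False
) -> LabeledDataset:
    mat, gene_ids, cell_ids = read_expression(matrix_path, genes_path, cells_path, transpose)
    labels = read_labels(labels_path, cell_ids)
    return LabeledDataset(matrix=mat, gene_ids=gene_ids, cell_ids=cell_ids, labels=labels)


def write_labeled_dataset(
    dataset: LabeledDataset, matrix_path, labels_path, genes_path=None, cells_path=None
) -> None:
    write_expression(
        dataset.matrix, dataset.gene_ids, dataset.cell_ids, matrix_path, genes_path, cells_path
    )
    write_labels(dataset.labels, dataset.cell_ids, labels_path)


# --------------------------------------------------------------------------
# feature lists


def write_feature_list(flist: FeatureList, path) -> None:
    df = pd.DataFrame(
        {
            "rank": np.arange(1, len(flist.genes) + 1),
            "gene_id": flist.genes,
            "score": flist.scores,
            "method": flist.method,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_feature_list(path) -> FeatureList:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "method": str})
    for col in ("rank", "gene_id", "score", "method"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    ranks = df["rank"].to_numpy()
    if not np.array_equal(ranks, np.arange(1, len(df) + 1)):
        raise ParseError(f"{path}: ranks must be contiguous 1..n")
    genes = df["gene_id"].tolist()
    if len(set(genes)) != len(genes):
        raise ParseError(f"{path}: duplicate gene ids")
    scores = df["score"].to_numpy(dtype=float)
    method = str(df["method"].iloc[0]) if len(df) else "unknown"
    # mRMR lists are ordered by selection round, whose criterion values may
    # fluctuate; every other ranker's list must be sorted by score
    if method != "mrmr":
        finite = scores[np.isfinite(scores)]
        if np.any(np.diff(finite) > 1e-9):
            raise ParseError(f"{path}: scores must be non-increasing with rank")
    return FeatureList(method=method, genes=genes, scores=[float(s) for s in scores])


# --------------------------------------------------------------------------
# IFS result tables


def write_ifs_table(result: IFSResult, path) -> None:
    """IFS-curve CSV: one row per subset size with metrics and fold ACCs."""
    rows = []
    for rec in result.records:
        s = rec.summary
        row = {
            "k": rec.k,
            "acc": s.acc,
            "mcc": s.mcc,
            "macro_f1": s.macro_f1,
            "weighted_f1": s.weighted_f1,
            "optimal": int(rec.k == result.optimal_k),
            "feasible": int(rec.k == result.feasible_k),
        }
        for i, a in enumerate(s.per_fold_acc, start=1):
            row[f"fold{i}_acc"] = a
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


def read_ifs_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


# --------------------------------------------------------------------------
# rule groups


def write_rules(group: RuleGroup, json_path, txt_path=None) -> None:
    Path(json_path).write_text(
        json.dumps(group.to_dict(), indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
    if txt_path is not None:
        lines = [f"# rule group: {group.method} ({len(group.rules)} rules)"]
        lines += [str(r) for r in group.rules]
        Path(txt_path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_rules(json_path) -> RuleGroup:
    return RuleGroup.from_dict(json.loads(Path(json_path).read_text(encoding="utf-8")))
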