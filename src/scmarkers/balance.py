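"""SMOTE oversampling of minority classes up to the largest class size.

Each synthetic sample is ``x + lam * (x_nn - x)`` for a real minority sample
``x``, one of its k nearest same-class neighbors ``x_nn`` (Euclidean), and
``lam`` uniform in [0, 1).  Every class is grown until it matches the largest
original class count; original samples are preserved verbatim and synthetic
cell ids carry a ``synthetic:`` prefix.
"""

from __future__ import annotations

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .dataset import LabeledDataset, ValidationError

__all__ = ["smote", "smote_matrix"]


def smote_matrix(
    X: np.ndarray,
    labels: np.ndarray,
    k_neighbors: int = 5,
    seed: int = 0,
    on_singleton: str = "error",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """SMOTE on a raw matrix; returns (X_synth, labels_synth, parent_index).

    Only the synthetic rows are returned; callers stack them after the real
    rows.  ``parent_index`` gives, per synthetic row, the row index of the
    real sample it interpolates from.

    ``on_singleton`` controls classes with a single sample: ``"error"``
    raises (the standalone contract), ``"duplicate"`` replicates the lone
    sample — used for degenerate training folds inside cross-validation.
    """
    X = np.asarray(X, dtype=np.float64)
    labels = np.asarray(labels, dtype=object)
    if X.shape[0] == 0:
        raise ValidationError("cannot oversample an empty dataset")
    classes, counts = np.unique(labels, return_counts=True)
    target = int(counts.max())
    rng = np.random.default_rng(seed)
    new_rows: list[np.ndarray] = []
    new_labels: list[str] = []
    parents: list[int] = []
    for cls in sorted(classes, key=str):
        idx = np.flatnonzero(labels == cls)
        size = len(idx)
        deficit = target - size
        if deficit == 0:
            continue
        if size == 1:
            if on_singleton == "duplicate":
                new_rows.append(np.repeat(X[idx], deficit, axis=0))
                new_labels.extend([cls] * deficit)
                parents.extend([int(idx[0])] * deficit)
                continue
            raise ValidationError(
                f"class {cls!r} has a single sample; SMOTE needs >= 2 "
                "(drop the class or duplicate the sample)"
            )
        k_eff = min(k_neighbors, size - 1)
        Xc = X[idx]
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(Xc)
        neigh = nn.kneighbors(Xc, return_distance=False)[:, 1:]  # drop self
        base = rng.integers(0, size, deficit)
        pick = rng.integers(0, k_eff, deficit)
        lam = rng.random(deficit)
        x = Xc[base]
        x_nn = Xc[neigh[base, pick]]
        new_rows.append(x + lam[:, None] * (x_nn - x))
        new_labels.extend([cls] * deficit)
        parents.extend(int(i) for i in idx[base])
    if new_rows:
        return (
            np.vstack(new_rows),
            np.asarray(new_labels, dtype=object),
            np.asarray(parents, dtype=np.intp),
        )
    return (
        np.empty((0, X.shape[1])),
        np.asarray([], dtype=object),
        np.asarray([], dtype=np.intp),
    )


def smote(dataset: LabeledDataset, k_neighbors: int = 5, seed: int = 0) -> LabeledDataset:
    """Balance ``dataset`` so every class matches the largest class count.

    Returns the dataset unchanged (same object content, new container) when
    it is already balanced.
    """
    Xs, ls, _ = smote_matrix(dataset.matrix, dataset.labels, k_neighbors, seed)
    if len(ls) == 0:
        return LabeledDataset(
            matrix=dataset.matrix.copy(),
            gene_ids=list(dataset.gene_ids),
            cell_ids=list(dataset.cell_ids),
            labels=dataset.labels.copy(),
            class_order=list(dataset.class_order),
        )
    synth_ids = [f"synthetic:{l}:{i + 1}" for i, l in enumerate(ls)]
    return LabeledDataset(
        matrix=np.vstack([dataset.matrix, Xs]),
        gene_ids=list(dataset.gene_ids),
        cell_ids=list(dataset.cell_ids) + synth_ids,
        labels=np.concatenate([dataset.labels, ls]),
        class_order=list(dataset.class_order),
    )
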