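"""The labeled expression matrix container used throughout the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


@dataclass
class LabeledDataset:
    """A cells x genes expression matrix with a cell-type label per cell.

    Expression values are arbitrary nonnegative reals (typically
    log1p-transformed counts); all downstream stages are scale-free.

    Parameters
    ----------
    matrix
        Dense ``(n_cells, n_genes)`` array of finite, nonnegative values.
    gene_ids, cell_ids
        Unique string identifiers for columns and rows.
    labels
        Per-cell class identifier, one of ``class_order``.
    class_order
        Optional explicit class ordering; defaults to sorted unique labels.
    """

    matrix: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    labels: np.ndarray
    class_order: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.labels = np.asarray(self.labels, dtype=object)
        if self.matrix.ndim != 2:
            raise ValidationError("matrix must be two-dimensional (cells x genes)")
        n, p = self.matrix.shape
        if len(self.cell_ids) != n or len(self.labels) != n:
            raise ValidationError(
                f"row count {n} must equal len(cell_ids)={len(self.cell_ids)} "
                f"and len(labels)={len(self.labels)}"
            )
        if len(self.gene_ids) != p:
            raise ValidationError(
                f"column count {p} must equal len(gene_ids)={len(self.gene_ids)}"
            )
        if len(set(self.gene_ids)) != p:
            raise ValidationError("gene_ids must be unique")
        if len(set(self.cell_ids)) != n:
            raise ValidationError("cell_ids must be unique")
        if not np.all(np.isfinite(self.matrix)):
            raise ValidationError("matrix contains non-finite values")
        if np.any(self.matrix < 0):
            raise ValidationError("matrix contains negative values")
        present = sorted({str(l) for l in self.labels})
        if self.class_order is None:
            self.class_order = present
        else:
            self.class_order = [str(c) for c in self.class_order]
            unknown = set(present) - set(self.class_order)
            if unknown:
                raise ValidationError(f"labels not in class_order: {sorted(unknown)}")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    # -- basic views ---------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    def class_sizes(self) -> dict[str, int]:
        """Number of cells per class, in ``class_order``."""
        labels = self.labels
        return {c: int(np.sum(labels == c)) for c in self.class_order}

    def gene_indices(self, genes: list[str]) -> np.ndarray:
        """Column indices of ``genes``; unknown ids raise ValidationError."""
        missing = [g for g in genes if g not in self._gene_index]
        if missing:
            raise ValidationError(f"unknown gene ids: {missing[:5]}")
        return np.asarray([self._gene_index[g] for g in genes], dtype=np.intp)

    def submatrix(self, genes: list[str]) -> np.ndarray:
        """The expression matrix restricted to ``genes`` (in that order)."""
        return self.matrix[:, self.gene_indices(genes)]

    def label_codes(self) -> np.ndarray:
        """Integer-coded labels in ``class_order``."""
        lut = {c: i for i, c in enumerate(self.class_order)}
        return np.asarray([lut[str(l)] for l in self.labels], dtype=np.intp)
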