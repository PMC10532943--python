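"""Synthetic labeled expression matrices with planted marker genes.

The generator emulates the statistical structure of a cell-type-annotated
scRNA-seq expression matrix: many classes, severe class imbalance, a small
set of marker genes per class with elevated expression, and a large
background of uninformative genes.  Counts are drawn per gene from a
negative binomial (gamma-Poisson) distribution; each class's markers have
their mean multiplied by ``exp(effect_size)`` in cells of that class;
dropout zeroes entries independently; values are stored as ``log1p(count)``.

The ``"colon-immune"`` imbalance profile rescales the published cell counts
of the 25 immune cell subtypes in the Gut Cell Atlas normal-colon reference
(41,650 cells total, largest/smallest ratio 1252) to a requested total,
flooring at 2 cells per class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dataset import LabeledDataset, ValidationError

__all__ = [
    "COLON_IMMUNE_CELL_COUNTS",
    "SyntheticSpec",
    "scaled_class_sizes",
    "planted_markers",
    "generate_dataset",
]

# Published per-subtype cell counts of the Gut Cell Atlas normal-colon
# immune compartment (James et al., Nat. Immunol. 2020).  Used as the
# "colon-immune" imbalance profile and as printed reference numbers.
COLON_IMMUNE_CELL_COUNTS: dict[str, int] = {
    "Activated CD4 T": 1531,
    "B cell (cycling)": 15,
    "B cell (IgA Plasma)": 12522,
    "B cell (IgG Plasma)": 342,
    "B cell (memory)": 4508,
    "CD8 T": 3145,
    "cDC1": 38,
    "cDC2": 107,
    "cycling DCs": 47,
    "cycling gd T": 25,
    "Follicular B cell": 2582,
    "gd T": 548,
    "ILC": 832,
    "Lymphoid DC": 10,
    "LYVE1 Macrophage": 91,
    "Macrophage": 268,
    "Mast": 1151,
    "Monocyte": 98,
    "NK": 452,
    "pDC": 13,
    "Tcm": 3042,
    "Tfh": 1786,
    "Th1": 2833,
    "Th17": 3432,
    "Treg": 2232,
}


def scaled_class_sizes(total: int, counts: dict[str, int] | None = None) -> dict[str, int]:
    """Rescale a class-size profile to ``total`` cells, flooring at 2 per class.

    Proportional allocation with largest-remainder rounding; the result sums
    exactly to ``total`` (raising if ``total`` is too small to give every
    class its 2-cell floor).
    """
    counts = COLON_IMMUNE_CELL_COUNTS if counts is None else counts
    names = list(counts)
    if total < 2 * len(names):
        raise ValidationError(
            f"total={total} cannot give {len(names)} classes >= 2 cells each"
        )
    grand = sum(counts.values())
    quota = {c: total * counts[c] / grand for c in names}
    sizes = {c: max(2, int(math.floor(quota[c]))) for c in names}
    # Largest-remainder correction toward the exact total; deterministic
    # tie-break on (remainder, name).
    def remainder(c: str) -> tuple[float, str]:
        return (-(quota[c] - math.floor(quota[c])), c)

    excess = sum(sizes.values()) - total
    if excess < 0:
        for c in sorted(names, key=remainder):
            if excess == 0:
                break
            sizes[c] += 1
            excess += 1
    while excess > 0:
        # shrink the classes that overshoot their quota most, never below 2
        candidates = sorted(
            (c for c in names if sizes[c] > 2),
            key=lambda c: (quota[c] - sizes[c], c),
        )
        sizes[candidates[0]] -= 1
        excess -= 1
    return sizes


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    ``class_sizes`` is either an explicit list of per-class cell counts or a
    profile string ``"colon-immune:<total>"`` (for example
    ``"colon-immune:3000"``), which rescales the 25 published colon-immune
    subtype proportions to the given total.
    """

    n_classes: int = 25
    n_genes: int = 2000
    markers_per_class: int = 5
    class_sizes: list[int] | str = "colon-immune:3000"
    effect_size: float = 2.0
    baseline_mean: float = 2.0
    dispersion: float = 2.0
    dropout_rate: float = 0.1
    seed: int = 0
    class_names: list[str] = field(default=None)  # type: ignore[assignment]

    def resolved_sizes(self) -> tuple[list[str], list[int]]:
        """Class names and sizes after expanding a profile string."""
        if isinstance(self.class_sizes, str):
            profile, _, total = self.class_sizes.partition(":")
            if profile != "colon-immune":
                raise ValidationError(f"unknown imbalance profile: {profile!r}")
            sizes = scaled_class_sizes(int(total) if total else 3000)
            names = list(sizes)
            if len(names) != self.n_classes:
                raise ValidationError(
                    f"n_classes={self.n_classes} but profile has {len(names)} classes"
                )
            return names, [sizes[c] for c in names]
        sizes = [int(s) for s in self.class_sizes]
        if self.class_names is not None:
            names = list(self.class_names)
        else:
            width = len(str(max(len(sizes), 1)))
            names = [f"C{i + 1:0{width}d}" for i in range(len(sizes))]
        return names, sizes

    def validate(self) -> None:
        if self.n_classes < 2:
            raise ValidationError("n_classes must be >= 2")
        if self.markers_per_class * self.n_classes > self.n_genes:
            raise ValidationError(
                "markers_per_class x n_classes exceeds n_genes "
                f"({self.markers_per_class} x {self.n_classes} > {self.n_genes})"
            )
        if self.effect_size < 0:
            raise ValidationError("effect_size must be >= 0")
        if self.baseline_mean <= 0:
            raise ValidationError("baseline_mean must be > 0")
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be > 0")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValidationError("dropout_rate must lie in [0, 1]")
        names, sizes = self.resolved_sizes()
        if len(sizes) != self.n_classes:
            raise ValidationError(
                f"class_sizes has {len(sizes)} entries but n_classes={self.n_classes}"
            )
        if any(s < 2 for s in sizes):
            raise ValidationError("all class_sizes must be >= 2")
        if len(set(names)) != len(names):
            raise ValidationError("class names must be unique")


def _gene_ids(n_genes: int) -> list[str]:
    width = len(str(n_genes))
    return [f"G{i + 1:0{width}d}" for i in range(n_genes)]


def planted_markers(spec: SyntheticSpec) -> dict[str, list[str]]:
    """Ground-truth marker assignment: class name -> disjoint gene-id lists.

    Purely a function of (spec, seed); ``generate_dataset`` uses the same
    assignment, so recovery of these genes by the rankers can be scored.
    """
    spec.validate()
    names, _ = spec.resolved_sizes()
    genes = _gene_ids(spec.n_genes)
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0xA11]))
    perm = rng.permutation(spec.n_genes)
    out: dict[str, list[str]] = {}
    k = spec.markers_per_class
    for i, cls in enumerate(names):
        out[cls] = sorted(genes[j] for j in perm[i * k : (i + 1) * k])
    return out


def generate_dataset(spec: SyntheticSpec) -> LabeledDataset:
    """Draw one labeled expression matrix from ``spec``.

    Deterministic: identical spec (including seed) yields bit-identical
    output.
    """
    spec.validate()
    names, sizes = spec.resolved_sizes()
    n_cells = sum(sizes)
    gene_ids = _gene_ids(spec.n_genes)
    markers = planted_markers(spec)
    gene_index = {g: j for j, g in enumerate(gene_ids)}

    labels = np.repeat(np.asarray(names, dtype=object), sizes)
    mean = np.full((n_cells, spec.n_genes), spec.baseline_mean)
    row = 0
    for cls, size in zip(names, sizes):
        cols = [gene_index[g] for g in markers[cls]]
        mean[row : row + size, cols] *= math.exp(spec.effect_size)
        row += size

    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0xC0DE]))
    # negative binomial as gamma-Poisson: lam ~ Gamma(theta, mu/theta)
    lam = rng.gamma(shape=spec.dispersion, scale=mean / spec.dispersion)
    counts = rng.poisson(lam).astype(np.float64)
    if spec.dropout_rate > 0:
        keep = rng.random(counts.shape) >= spec.dropout_rate
        counts *= keep
    cell_ids = [f"cell{i + 1:06d}" for i in range(n_cells)]
    return LabeledDataset(
        matrix=np.log1p(counts),
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        labels=labels,
        class_order=list(names),
    )


def background_genes(spec: SyntheticSpec) -> list[str]:
    """Gene ids that are not planted markers of any class."""
    planted = {g for gs in planted_markers(spec).values() for g in gs}
    return [g for g in _gene_ids(spec.n_genes) if g not in planted]
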