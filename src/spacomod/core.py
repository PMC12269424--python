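"""Core in-memory containers shared by all pipeline stages.

The universal substrate is a cell-by-gene expression matrix with optional
per-cell spatial coordinates and categorical annotations. Expression may be
stored dense (``numpy.ndarray``) or sparse (any ``scipy.sparse`` matrix);
all statistics are defined on the logical dense values with implicit zeros,
and densification happens only on demand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp


class StructuralError(ValueError):
    """A dataset violates a structural invariant (shape, key or label)."""


def _as_str_list(values: Sequence) -> list[str]:
    return [str(v) for v in values]


def _check_unique(names: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    dupes = []
    for n in names:
        if n in seen:
            dupes.append(n)
        seen[n] = 1
    if dupes:
        raise StructuralError(f"duplicate {what}: {sorted(set(dupes))}")


@dataclass
class ExpressionDataset:
    """Cell-by-gene expression with identifiers and categorical annotations.

    Parameters
    ----------
    expression
        ``(n_cells, n_genes)`` matrix of non-negative reals; dense or sparse.
    gene_symbols
        Unique, case-sensitive gene symbols, one per column.
    cell_ids
        Unique cell identifiers, one per row.
    annotations
        Mapping from annotation-level name to a per-cell label vector.
        Missing labels are allowed only as an explicit sentinel category.
    """

    expression: np.ndarray | sp.spmatrix
    gene_symbols: list[str]
    cell_ids: list[str]
    annotations: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_symbols = _as_str_list(self.gene_symbols)
        self.cell_ids = _as_str_list(self.cell_ids)
        n, g = self.expression.shape
        if len(self.gene_symbols) != g:
            raise StructuralError(
                f"{g} expression columns but {len(self.gene_symbols)} gene symbols"
            )
        if len(self.cell_ids) != n:
            raise StructuralError(
                f"{n} expression rows but {len(self.cell_ids)} cell ids"
            )
        _check_unique(self.gene_symbols, "gene symbols")
        _check_unique(self.cell_ids, "cell ids")
        self.annotations = {
            k: np.asarray([str(x) for x in v], dtype=object)
            for k, v in self.annotations.items()
        }
        for level, labels in self.annotations.items():
            if labels.shape != (n,):
                raise StructuralError(
                    f"annotation level {level!r} has {labels.shape[0]} labels "
                    f"for {n} cells"
                )
        self._gene_index = {s: i for i, s in enumerate(self.gene_symbols)}

    @property
    def n_cells(self) -> int:
        return self.expression.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expression.shape[1]

    def gene_index(self, symbol: str) -> int:
        """Exact-match, case-sensitive column lookup."""
        try:
            return self._gene_index[symbol]
        except KeyError:
            raise KeyError(f"gene symbol {symbol!r} not in panel") from None

    def gene_values(self, symbol: str) -> np.ndarray:
        """Dense per-cell expression vector of one gene."""
        j = self.gene_index(symbol)
        col = self.expression[:, [j]] if sp.issparse(self.expression) else self.expression[:, j]
        if sp.issparse(col):
            return np.asarray(col.todense()).ravel().astype(float)
        return np.asarray(col, dtype=float).ravel()

    def dense(self) -> np.ndarray:
        """Logical dense expression matrix (copies sparse input)."""
        if sp.issparse(self.expression):
            return np.asarray(self.expression.todense(), dtype=float)
        return np.asarray(self.expression, dtype=float)

    def annotation_labels(self, level: str) -> np.ndarray:
        if level not in self.annotations:
            raise StructuralError(
                f"annotation level {level!r} unknown; available: "
                f"{sorted(self.annotations)}"
            )
        return self.annotations[level]


@dataclass
class ScRnaDataset(ExpressionDataset):
    """Annotated scRNA-seq dataset; structurally a coordinate-free dataset."""


@dataclass
class SpatialDataset(ExpressionDataset):
    """Spatially resolved transcriptomics dataset: expression + coordinates.

    ``coordinates`` is ``(n_cells, d)`` with ``d`` in {2, 3}, in the units of
    the source frame (CCF millimetres or pixels).
    """

    coordinates: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.coordinates is None:
            raise StructuralError("SpatialDataset requires coordinates")
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] not in (2, 3):
            raise StructuralError(
                f"coordinates must be (cells, 2|3), got {self.coordinates.shape}"
            )
        if self.coordinates.shape[0] != self.n_cells:
            raise StructuralError(
                f"{self.n_cells} expression rows but "
                f"{self.coordinates.shape[0]} coordinate rows"
            )

    @property
    def n_dims(self) -> int:
        return self.coordinates.shape[1]


@dataclass
class AnnotationAverages:
    """Per-annotation-category mean expression (categories x genes)."""

    categories: list[str]
    gene_symbols: list[str]
    means: np.ndarray

    def __post_init__(self) -> None:
        self.categories = _as_str_list(self.categories)
        self.gene_symbols = _as_str_list(self.gene_symbols)
        self.means = np.asarray(self.means, dtype=float)
        if self.means.shape != (len(self.categories), len(self.gene_symbols)):
            raise StructuralError(
                f"means shape {self.means.shape} does not match "
                f"{len(self.categories)} categories x {len(self.gene_symbols)} genes"
            )
        _check_unique(self.categories, "category labels")
        _check_unique(self.gene_symbols, "gene symbols")
        self._cat_index = {c: i for i, c in enumerate(self.categories)}
        self._gene_index = {g: i for i, g in enumerate(self.gene_symbols)}

    def category_index(self, label: str) -> int:
        return self._cat_index[label]

    def gene_index(self, symbol: str) -> int:
        return self._gene_index[symbol]


@dataclass
class CellSelection:
    """Ordered, duplicate-free set of cell indices with provenance.

    ``provenance`` is a JSON-serializable dict with a ``mode`` key of
    ``annotation``, ``floodfill`` or ``explicit`` plus the mode's parameters.
    """

    indices: np.ndarray
    provenance: dict
    dataset_ref: str = ""

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size == 0:
            raise StructuralError("cell selection is empty")
        if len(np.unique(self.indices)) != self.indices.size:
            raise StructuralError("cell selection contains duplicate indices")

    def __len__(self) -> int:
        return int(self.indices.size)

    def validate_against(self, ds: ExpressionDataset) -> None:
        if self.indices.min() < 0 or self.indices.max() >= ds.n_cells:
            raise StructuralError(
                f"selection indices out of range for {ds.n_cells} cells"
            )
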