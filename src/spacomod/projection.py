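"""Label-transfer projection of scRNA-seq annotation averages onto space.

Paired SRT and scRNA-seq datasets annotated in the same cell-type taxonomy
can be bridged without model-based imputation: the mean expression of every
annotation category is computed from the scRNA-seq data and assigned to each
spatial cell carrying that category's label. The result is an approximate
transcriptome-wide expression matrix on the spatial coordinates. Validity
rests on the taxonomy being fine-grained enough that the category mean is a
usable representative of its cells.

Two validation statistics are provided: the Pearson correlation of a gene's
per-category means between the two modalities (category level), and the
Pearson correlation between projected and measured expression across all
cells (cell level). The cell-level value is bounded by within-category
variance; a gene that is constant within every category correlates
perfectly with its own self-projection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .core import (
    AnnotationAverages,
    ExpressionDataset,
    SpatialDataset,
    StructuralError,
)


@dataclass
class ProjectedDataset:
    """A SpatialDataset whose expression is the projected category means.

    ``unmatched_cells`` lists indices of cells whose annotation label had no
    counterpart among the averages' categories; their rows are all zero.
    """

    dataset: SpatialDataset
    source_level: str
    unmatched_cells: list[int] = field(default_factory=list)


def compute_annotation_averages(
    scrna: ExpressionDataset, level: str, *, block_size: int = 8192
) -> AnnotationAverages:
    """Per-category arithmetic mean expression of every gene.

    Streams over cells in blocks of ``block_size`` rows so the full matrix
    never needs to be dense in memory at once. Category order is
    first-appearance order in the data, keeping results locale-independent.
    """
    labels = scrna.annotation_labels(level)
    categories = list(dict.fromkeys(labels))  # first-appearance order
    cat_codes = {c: i for i, c in enumerate(categories)}
    codes = np.asarray([cat_codes[l] for l in labels], dtype=int)

    n_cat, n_genes = len(categories), scrna.n_genes
    sums = np.zeros((n_cat, n_genes), dtype=float)
    counts = np.bincount(codes, minlength=n_cat).astype(float)
    X = scrna.expression
    for start in range(0, scrna.n_cells, block_size):
        stop = min(start + block_size, scrna.n_cells)
        block = X[start:stop]
        if sp.issparse(block):
            block = np.asarray(block.todense(), dtype=float)
        else:
            block = np.asarray(block, dtype=float)
        np.add.at(sums, codes[start:stop], block)
    means = sums / counts[:, None]
    return AnnotationAverages(
        categories=categories, gene_symbols=list(scrna.gene_symbols), means=means
    )


def project_to_spatial(
    srt: SpatialDataset,
    averages: AnnotationAverages,
    level: str,
    *,
    strict: bool = False,
) -> ProjectedDataset:
    """Assign each spatial cell its category's mean expression vector.

    Cells whose label is absent from ``averages`` receive an all-zero row and
    are reported in ``unmatched_cells`` (with a warning), or raise if
    ``strict``. Coordinates, cell order and annotations are unchanged; the
    gene dimension is the averages' (typically transcriptome-wide) panel.
    """
    labels = srt.annotation_labels(level)
    cat_index = {c: i for i, c in enumerate(averages.categories)}
    rows = np.asarray([cat_index.get(l, -1) for l in labels], dtype=int)
    unmatched = np.flatnonzero(rows < 0)
    if unmatched.size == srt.n_cells:
        raise StructuralError(
            f"no label of level {level!r} matches any averages category "
            "(taxonomy mismatch)"
        )
    if unmatched.size:
        msg = (
            f"{unmatched.size} of {srt.n_cells} cells have labels absent "
            "from the annotation averages; their projected rows are zero"
        )
        if strict:
            raise StructuralError(msg)
        warnings.warn(msg)
    expr = np.zeros((srt.n_cells, len(averages.gene_symbols)), dtype=float)
    matched = rows >= 0
    expr[matched] = averages.means[rows[matched]]
    projected = SpatialDataset(
        expression=expr,
        gene_symbols=list(averages.gene_symbols),
        cell_ids=list(srt.cell_ids),
        annotations=dict(srt.annotations),
        coordinates=srt.coordinates.copy(),
    )
    return ProjectedDataset(
        dataset=projected, source_level=level, unmatched_cells=[int(i) for i in unmatched]
    )


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r; NaN sentinel when either vector is constant."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.sqrt(a @ a), np.sqrt(b @ b)
    if na == 0.0 or nb == 0.0:
        return float("nan")
    return float((a @ b) / (na * nb))


def cluster_level_correlation(
    srt: SpatialDataset, averages: AnnotationAverages, level: str, gene: str
) -> float:
    """Pearson r between per-category SRT means and scRNA category means.

    Computed over the categories shared by the SRT annotation level and the
    averages. Returns NaN when either side has zero variance across
    categories (undefined statistic, not silently 0).
    """
    labels = srt.annotation_labels(level)
    shared = [c for c in dict.fromkeys(labels) if c in averages._cat_index]
    if len(shared) < 2:
        raise StructuralError(
            f"need >= 2 shared categories, found {len(shared)}"
        )
    x = srt.gene_values(gene)
    srt_means = np.asarray(
        [x[labels == c].mean() for c in shared], dtype=float
    )
    gj = averages.gene_index(gene)
    ref_means = np.asarray(
        [averages.means[averages.category_index(c), gj] for c in shared]
    )
    return _pearson(srt_means, ref_means)


def cell_level_spatial_correlation(
    srt: SpatialDataset, projected: ProjectedDataset, gene: str
) -> float:
    """Pearson r across all cells between measured and projected expression.

    NaN sentinel when either per-cell vector is constant.
    """
    measured = srt.gene_values(gene)
    proj = projected.dataset.gene_values(gene)
    if measured.shape != proj.shape:
        raise StructuralError("measured and projected cell counts differ")
    return _pearson(measured, proj)
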