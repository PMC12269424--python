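"""Grouping filtered genes into local co-expression modules.

Retained genes are clustered by agglomerative hierarchical clustering on the
pairwise correlation distance 1 - Pearson(r) of their expression over the
selected cells (0 for perfectly correlated profiles, 2 for perfectly
anticorrelated ones). The tree is cut into exactly k flat clusters; k is a
user parameter with no automatic model selection. Average linkage (UPGMA)
is the default partner for correlation distances; complete linkage is
available. Pearson already centers and scales each gene, so no further
standardization is applied.

Module ids are relabeled deterministically: descending module size, ties by
the lexicographically smallest member gene. Each module carries a mean
spatial map (per-cell average over member genes) and a min-max normalized
variant in [0, 1] within the selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .core import CellSelection, SpatialDataset, StructuralError
from .filters import GeneScoreTable

LINKAGES = ("average", "complete")


def correlation_distance(g1: np.ndarray, g2: np.ndarray) -> float:
    """1 - Pearson correlation of two expression vectors; range [0, 2]."""
    a = np.asarray(g1, dtype=float)
    b = np.asarray(g2, dtype=float)
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.sqrt(a @ a), np.sqrt(b @ b)
    if na == 0.0 or nb == 0.0:
        raise StructuralError(
            "correlation distance undefined for a constant vector; "
            "constant genes must be excluded at filtering"
        )
    return float(1.0 - (a @ b) / (na * nb))


@dataclass
class GeneModuleSet:
    """Hard partition of the retained genes into k co-expression modules."""

    gene_symbols: list[str]
    labels: np.ndarray  # per-gene module id in 0..k-1
    k: int
    linkage: str
    mean_maps: np.ndarray  # (k, n_selected_cells)
    normalized_maps: np.ndarray  # same shape, min-max scaled per module
    selection_indices: np.ndarray

    def members(self, module_id: int) -> list[str]:
        return [g for g, l in zip(self.gene_symbols, self.labels) if l == module_id]

    def assignment_table(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.gene_symbols, "module": self.labels})

    def maps_table(self, cell_ids: list[str]) -> pd.DataFrame:
        """Per-selected-cell mean and normalized maps, one column pair per module."""
        data = {"cell_id": [cell_ids[i] for i in self.selection_indices]}
        for m in range(self.k):
            data[f"module_{m}_mean"] = self.mean_maps[m]
            data[f"module_{m}_norm"] = self.normalized_maps[m]
        return pd.DataFrame(data)


def _minmax(v: np.ndarray) -> np.ndarray:
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def cluster_genes(
    table: GeneScoreTable,
    ds: SpatialDataset,
    selection: CellSelection,
    k: int,
    linkage_method: str = "average",
) -> GeneModuleSet:
    """Cut the correlation-distance dendrogram of retained genes into k modules."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if linkage_method not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    selection.validate_against(ds)
    genes = table.retained_genes()
    if len(genes) < k:
        raise StructuralError(
            f"k={k} exceeds the {len(genes)} retained genes"
        )
    idx = selection.indices
    E = np.stack([ds.gene_values(g)[idx] for g in genes])  # genes x cells

    if len(genes) == 1:
        raw = np.zeros(1, dtype=int)
    else:
        C = np.corrcoef(E)
        D = np.clip(1.0 - C, 0.0, 2.0)
        np.fill_diagonal(D, 0.0)
        Z = linkage(squareform(D, checks=False), method=linkage_method)
        raw = fcluster(Z, t=k, criterion="maxclust") - 1
    n_found = len(np.unique(raw))
    if n_found != k:
        raise StructuralError(
            f"dendrogram cut produced {n_found} clusters instead of {k} "
            "(degenerate distances); lower k"
        )

    # deterministic relabeling: descending size, ties by smallest member gene
    groups: dict[int, list[int]] = {}
    for gi, lab in enumerate(raw):
        groups.setdefault(int(lab), []).append(gi)
    ordered = sorted(
        groups.values(), key=lambda g: (-len(g), min(genes[i] for i in g))
    )
    labels = np.empty(len(genes), dtype=int)
    for new_id, members in enumerate(ordered):
        labels[members] = new_id

    mean_maps = np.stack(
        [E[labels == m].mean(axis=0) for m in range(k)]
    )
    normalized = np.stack([_minmax(m) for m in mean_maps])
    return GeneModuleSet(
        gene_symbols=genes,
        labels=labels,
        k=k,
        linkage=linkage_method,
        mean_maps=mean_maps,
        normalized_maps=normalized,
        selection_indices=np.asarray(idx, dtype=int),
    )


def module_mean_map(
    modules: GeneModuleSet, module_id: int
) -> tuple[np.ndarray, np.ndarray]:
    """(mean map, min-max normalized map) over the selected cells.

    The normalized map is all-zero when the mean map is constant.
    """
    if not (0 <= module_id < modules.k):
        raise KeyError(f"module id {module_id} out of range for k={modules.k}")
    return modules.mean_maps[module_id], modules.normalized_maps[module_id]
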