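"""Cell subset selection: by annotation label, flood-fill, or explicit list.

Flood-fill emulates the interactive walk over transcriptomically similar
cells: a kNN graph is built on the expression rows (transcriptome space, not
spatial space), and a breadth-first traversal from a seed cell expands the
frontier a fixed number of steps. "Flood nodes" maps to the graph's k and
"flood steps" to the BFS depth; the defaults (k=10, steps=10) match common
interactive settings. The traversal follows directed out-edges — a cell
floods to *its* k nearest neighbours — which is well defined without
symmetrizing the graph.
"""

from __future__ import annotations

import difflib
import warnings
from collections import deque
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.neighbors import NearestNeighbors

from .core import CellSelection, SpatialDataset, StructuralError

#: Above this cell count the kNN search switches from exact brute force
#: (with deterministic index tie-breaks) to a tree-based search.
EXACT_KNN_THRESHOLD = 5000

KNN_METRICS = ("euclidean", "cosine", "correlation")


@dataclass
class KnnGraph:
    """Directed kNN graph over cells in transcriptome space.

    ``neighbors[i]`` holds cell ``i``'s k nearest cells (self excluded),
    sorted by ascending distance with lower-index tie-break.
    """

    neighbors: np.ndarray  # (n_cells, k) int
    k: int
    metric: str
    exact: bool = True

    @property
    def n_cells(self) -> int:
        return self.neighbors.shape[0]


def select_by_annotation(
    ds: SpatialDataset, level: str, label: str
) -> CellSelection:
    """All cells carrying ``label`` at annotation ``level``, in dataset order."""
    labels = ds.annotation_labels(level)
    idx = np.flatnonzero(labels == str(label))
    if idx.size == 0:
        near = difflib.get_close_matches(str(label), sorted(set(labels)), n=3)
        raise StructuralError(
            f"label {label!r} not present at level {level!r}; "
            f"near matches: {near}"
        )
    return CellSelection(
        indices=idx,
        provenance={"mode": "annotation", "level": level, "label": str(label)},
    )


def build_knn_graph(
    ds: SpatialDataset,
    k: int,
    metric: str = "euclidean",
    *,
    exact_threshold: int = EXACT_KNN_THRESHOLD,
) -> KnnGraph:
    """kNN graph on expression rows.

    Exact brute-force search (deterministic lower-index tie-break) for
    datasets up to ``exact_threshold`` cells; larger datasets use a
    tree-based search and the graph records ``exact=False``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if metric not in KNN_METRICS:
        raise ValueError(f"metric must be one of {KNN_METRICS}")
    n = ds.n_cells
    if k >= n:
        warnings.warn(f"k={k} >= n_cells={n}; clipped to {n - 1}")
        k = n - 1
    X = ds.dense()
    if n <= exact_threshold:
        D = cdist(X, X, metric=metric)
        np.fill_diagonal(D, np.inf)
        # argsort of (distance, index) pairs: stable kind keeps index order on ties
        order = np.argsort(D, axis=1, kind="stable")
        neighbors = order[:, :k]
        return KnnGraph(neighbors=neighbors, k=k, metric=metric, exact=True)
    nn = NearestNeighbors(n_neighbors=k + 1, metric=metric).fit(X)
    _, idx = nn.kneighbors(X)
    neighbors = np.empty((n, k), dtype=int)
    for i in range(n):
        row = idx[i][idx[i] != i][:k]
        neighbors[i] = row
    return KnnGraph(neighbors=neighbors, k=k, metric=metric, exact=False)


def flood_fill(graph: KnnGraph, seed: int, steps: int) -> CellSelection:
    """Breadth-first expansion from ``seed`` over directed kNN out-edges.

    The frontier is expanded ``steps`` times; the selection is every visited
    cell in BFS order, seed first. ``steps=0`` selects only the seed, and
    once the reachable component is exhausted further steps are a no-op.
    """
    if not (0 <= seed < graph.n_cells):
        raise StructuralError(f"seed {seed} out of range for {graph.n_cells} cells")
    if steps < 0:
        raise ValueError("steps must be >= 0")
    visited = {int(seed)}
    order = [int(seed)]
    frontier = deque([int(seed)])
    for _ in range(steps):
        if not frontier:
            break
        next_frontier: deque[int] = deque()
        while frontier:
            node = frontier.popleft()
            for nb in graph.neighbors[node]:
                nb = int(nb)
                if nb not in visited:
                    visited.add(nb)
                    order.append(nb)
                    next_frontier.append(nb)
        frontier = next_frontier
    return CellSelection(
        indices=np.asarray(order, dtype=int),
        provenance={
            "mode": "floodfill",
            "seed": int(seed),
            "k_neighbors": graph.k,
            "steps": int(steps),
            "metric": graph.metric,
            "exact_knn": bool(graph.exact),
        },
    )


def select_explicit(ds: SpatialDataset, indices: Sequence[int]) -> CellSelection:
    """Order-preserving, de-duplicated selection from an explicit index list."""
    if len(indices) == 0:
        raise StructuralError("explicit selection is empty")
    seen: set[int] = set()
    out: list[int] = []
    for i in indices:
        i = int(i)
        if not (0 <= i < ds.n_cells):
            raise StructuralError(
                f"index {i} out of range for {ds.n_cells} cells"
            )
        if i not in seen:
            seen.add(i)
            out.append(i)
    return CellSelection(
        indices=np.asarray(out, dtype=int), provenance={"mode": "explicit"}
    )
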