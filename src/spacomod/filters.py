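"""Gene filtering within a cell selection.

Three per-gene metrics identify informative genes inside a selected cell
subset before module clustering:

* **differential** — difference between the gene's mean expression over the
  selected cells and its mean over the whole dataset; targets genes highly
  expressed in the selection (cell-type markers).
* **moran** — Moran's I spatial autocorrelation of the gene over the
  selection, with a Z-score against the null expectation E(I) = -1/(N-1);
  flags non-random spatial patterning (|Z| > 1.96 corresponds to p < 0.05
  under the normal approximation).
* **spatial-axis** — Pearson correlation between the gene's expression and
  one spatial coordinate axis; finds gradients along anatomical axes.

Moran's I for expression values x over N selected cells with spatial weight
matrix w (total weight W = sum of all w_ij) is::

    I = (N / W) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2

The Z-score uses the closed-form variance of I under the normality
assumption. Genes with zero variance over the selection have an undefined
statistic (NaN sentinel) and are excluded from ranking rather than scored 0,
so constant housekeeping genes cannot displace informative genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial.distance import cdist, pdist, squareform

from .core import CellSelection, SpatialDataset, StructuralError

AXES = {"x": 0, "y": 1, "z": 2}


@dataclass
class SpatialWeightMatrix:
    """Non-negative spatial weights over the selected cells, zero diagonal.

    Built from Euclidean distances of the selected cells' coordinates only.
    Schemes: ``knn-binary(k)`` (w_ij = 1 iff j is among i's k spatially
    nearest; generally asymmetric) or ``inverse-distance(cutoff)``
    (w_ij = 1/d_ij for d_ij <= cutoff, else 0).
    """

    weights: np.ndarray | sp.spmatrix
    scheme: str

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    @property
    def total(self) -> float:
        """W = sum over all i, j of w_ij."""
        return float(self.weights.sum())

    def dense(self) -> np.ndarray:
        w = self.weights
        return np.asarray(w.todense()) if sp.issparse(w) else np.asarray(w)


@dataclass
class MoransIResult:
    """Moran's I statistic with its null expectation and Z-score."""

    I: float
    expected: float  # -1/(N-1)
    z: float
    N: int
    W: float

    @property
    def variance(self) -> float:
        if np.isnan(self.z) or self.z == 0.0:
            return float("nan")
        return ((self.I - self.expected) / self.z) ** 2


@dataclass
class GeneScoreTable:
    """Per-gene scores for one metric with a total ranking and top-N mask."""

    gene_symbols: list[str]
    metric: str
    score: np.ndarray
    ranking_key: np.ndarray
    retained: np.ndarray
    params: dict

    def to_dataframe(self) -> pd.DataFrame:
        """Ranked table (descending ranking_key, ties by gene symbol)."""
        df = pd.DataFrame(
            {
                "gene": self.gene_symbols,
                "score": self.score,
                "ranking_key": self.ranking_key,
                "retained": self.retained,
            }
        )
        return df.iloc[_rank_order(self.ranking_key, self.gene_symbols)].reset_index(
            drop=True
        )

    def retained_genes(self) -> list[str]:
        df = self.to_dataframe()
        return list(df.loc[df["retained"], "gene"])


def differential_score(
    ds: SpatialDataset, selection: CellSelection, gene: str
) -> float:
    """Mean expression over selected cells minus mean over all cells."""
    selection.validate_against(ds)
    x = ds.gene_values(gene)
    return float(x[selection.indices].mean() - x.mean())


def build_weights(
    coords: np.ndarray,
    scheme: str = "knn",
    *,
    k: int = 15,
    cutoff: float | None = None,
) -> SpatialWeightMatrix:
    """Spatial weight matrix from Euclidean distances of selected cells.

    ``scheme="knn"`` gives binary k-nearest-neighbour weights (default
    k=15, bounded cost on large selections); ``scheme="invdist"`` gives
    1/d weights truncated at ``cutoff``.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 3:
        raise StructuralError("need >= 3 selected cells for spatial weights")
    if not np.all(np.isfinite(coords)):
        raise StructuralError("coordinates must be finite")
    if scheme in ("knn", "knn-binary"):
        kk = min(k, n - 1)
        D = cdist(coords, coords)
        np.fill_diagonal(D, np.inf)
        order = np.argsort(D, axis=1, kind="stable")[:, :kk]
        w = sp.csr_matrix(
            (
                np.ones(n * kk),
                (np.repeat(np.arange(n), kk), order.ravel()),
            ),
            shape=(n, n),
        )
        return SpatialWeightMatrix(weights=w, scheme=f"knn-binary(k={kk})")
    if scheme in ("invdist", "inverse-distance"):
        if cutoff is None:
            raise ValueError("inverse-distance scheme requires a cutoff")
        D = squareform(pdist(coords))
        mask = (D <= cutoff) & ~np.eye(n, dtype=bool)
        if np.any(D[mask] == 0.0):
            raise StructuralError(
                "coincident points give infinite inverse-distance weights; "
                "use the knn-binary scheme instead"
            )
        w = np.zeros_like(D)
        w[mask] = 1.0 / D[mask]
        if w.sum() == 0.0:
            raise StructuralError(
                f"cutoff {cutoff} smaller than all pairwise distances (W = 0)"
            )
        return SpatialWeightMatrix(weights=w, scheme=f"inverse-distance(cutoff={cutoff})")
    raise ValueError(f"unknown weight scheme {scheme!r}")


def _moran_stats(
    values: np.ndarray, weights: SpatialWeightMatrix
) -> MoransIResult:
    """Moran's I with normality-assumption Z-score for one value vector."""
    x = np.asarray(values, dtype=float)
    N = x.size
    if N != weights.n:
        raise StructuralError("value vector length does not match weight matrix")
    W = weights.total
    z = x - x.mean()
    denom = float(z @ z)
    expected = -1.0 / (N - 1)
    if denom == 0.0:
        return MoransIResult(
            I=float("nan"), expected=expected, z=float("nan"), N=N, W=W
        )
    w = weights.weights
    num = float(z @ (w @ z))
    I = (N / W) * num / denom

    # Var(I) under the normality assumption:
    #   S1 = 1/2 sum_ij (w_ij + w_ji)^2
    #   S2 = sum_i (row_i + col_i)^2
    #   Var = (N^2 S1 - N S2 + 3 W^2) / (W^2 (N^2 - 1)) - E(I)^2
    if sp.issparse(w):
        ws = w + w.T
        S1 = 0.5 * float(ws.multiply(ws).sum())
        sums = np.asarray(w.sum(axis=1)).ravel() + np.asarray(w.sum(axis=0)).ravel()
    else:
        ws = w + w.T
        S1 = 0.5 * float((ws * ws).sum())
        sums = w.sum(axis=1) + w.sum(axis=0)
    S2 = float((sums**2).sum())
    var = (N**2 * S1 - N * S2 + 3 * W**2) / (W**2 * (N**2 - 1)) - expected**2
    zscore = (I - expected) / np.sqrt(var) if var > 0 else float("nan")
    return MoransIResult(I=float(I), expected=expected, z=float(zscore), N=N, W=W)


def morans_i(
    ds: SpatialDataset,
    selection: CellSelection,
    gene: str,
    weights: SpatialWeightMatrix,
) -> MoransIResult:
    """Moran's I of one gene over the selected cells."""
    selection.validate_against(ds)
    x = ds.gene_values(gene)[selection.indices]
    return _moran_stats(x, weights)


def axis_correlation(
    ds: SpatialDataset, selection: CellSelection, gene: str, axis: str
) -> float:
    """Pearson r between a gene's expression and one coordinate axis.

    Computed over the selected cells only; NaN sentinel when either vector
    is constant.
    """
    selection.validate_against(ds)
    if len(selection) < 3:
        raise StructuralError("axis correlation needs >= 3 selected cells")
    if axis not in AXES:
        raise ValueError(f"axis must be one of {sorted(AXES)}")
    dim = AXES[axis]
    if dim >= ds.n_dims:
        raise StructuralError(
            f"axis {axis!r} not available in {ds.n_dims}-D coordinates"
        )
    x = ds.gene_values(gene)[selection.indices]
    c = ds.coordinates[selection.indices, dim]
    xc = x - x.mean()
    cc = c - c.mean()
    nx, nc = np.sqrt(xc @ xc), np.sqrt(cc @ cc)
    if nx == 0.0 or nc == 0.0:
        return float("nan")
    return float((xc @ cc) / (nx * nc))


def _rank_order(ranking_key: np.ndarray, symbols: list[str]) -> np.ndarray:
    """Total order: descending key, NaN last, ties by ascending symbol."""
    key = np.where(np.isnan(ranking_key), -np.inf, ranking_key)
    return np.lexsort((symbols, -key))


def filter_genes(
    ds: SpatialDataset,
    selection: CellSelection,
    metric: str,
    *,
    n_keep: int,
    axis: str | None = None,
    weights: SpatialWeightMatrix | None = None,
    weights_scheme: str = "knn",
    weights_k: int = 15,
    weights_cutoff: float | None = None,
    log1p: bool = False,
) -> GeneScoreTable:
    """Score every gene by one metric and retain the top ``n_keep``.

    Ranking keys: signed score, descending, for ``differential`` (the filter
    targets genes high in the selection); |Z| for ``moran`` and |r| for
    ``spatial-axis`` so both pattern directions survive. Ties are broken by
    gene symbol, making the ranking a reproducible total order. Genes with
    an undefined statistic are never retained.
    """
    if n_keep < 1:
        raise ValueError("n_keep must be >= 1")
    selection.validate_against(ds)
    idx = selection.indices
    X = ds.dense()
    if log1p:
        X = np.log1p(X)
    Xsel = X[idx]
    n_genes = ds.n_genes

    params: dict = {"metric": metric, "n_keep": int(n_keep), "log1p": bool(log1p)}
    if metric == "differential":
        score = Xsel.mean(axis=0) - X.mean(axis=0)
        ranking = score.copy()
    elif metric == "moran":
        if weights is None:
            weights = build_weights(
                ds.coordinates[idx],
                weights_scheme,
                k=weights_k,
                cutoff=weights_cutoff,
            )
        params["weights_scheme"] = weights.scheme
        score = np.empty(n_genes)
        for j in range(n_genes):
            score[j] = _moran_stats(Xsel[:, j], weights).z
        ranking = np.abs(score)
    elif metric in ("spatial-axis", "axis"):
        if axis is None:
            raise ValueError("spatial-axis metric requires an axis")
        params["axis"] = axis
        dim = AXES[axis]
        if dim >= ds.n_dims:
            raise StructuralError(
                f"axis {axis!r} not available in {ds.n_dims}-D coordinates"
            )
        c = ds.coordinates[idx, dim]
        cc = c - c.mean()
        nc = np.sqrt(cc @ cc)
        Xc = Xsel - Xsel.mean(axis=0)
        norms = np.sqrt((Xc**2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            score = (Xc.T @ cc) / (norms * nc)
        score[(norms == 0.0) | (nc == 0.0)] = np.nan
        ranking = np.abs(score)
    else:
        raise ValueError(
            f"unknown metric {metric!r}; use differential, moran or spatial-axis"
        )

    finite = np.isfinite(ranking)
    n_finite = int(finite.sum())
    if n_keep > n_finite:
        warnings.warn(
            f"n_keep={n_keep} exceeds the {n_finite} genes with a finite "
            "score; retaining all of them"
        )
    order = _rank_order(ranking, ds.gene_symbols)
    retained = np.zeros(n_genes, dtype=bool)
    kept = [i for i in order if finite[i]][: min(n_keep, n_finite)]
    retained[kept] = True
    return GeneScoreTable(
        gene_symbols=list(ds.gene_symbols),
        metric=metric if metric != "axis" else "spatial-axis",
        score=np.asarray(score, dtype=float),
        ranking_key=np.asarray(ranking, dtype=float),
        retained=retained,
        params=params,
    )
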