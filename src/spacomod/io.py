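"""Reading and writing datasets and tabular outputs.

Two on-disk layouts are supported for expression data: the AnnData ``h5ad``
layout (expression in ``X``, coordinates under an ``obsm`` key, annotations
as ``obs`` columns) and generic HDF5 with explicit dataset paths supplied by
the caller. Readers never reorder cells or genes relative to file order.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import anndata as ad
import h5py
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core import (
    AnnotationAverages,
    ScRnaDataset,
    SpatialDataset,
    StructuralError,
)

# Floats are serialized with 17 significant digits so that CSV/JSON
# round-trips reproduce float64 values exactly.
_FLOAT_FORMAT = "%.17g"


def _annotations_from_obs(obs: pd.DataFrame) -> dict[str, np.ndarray]:
    return {
        str(col): np.asarray([str(x) for x in obs[col]], dtype=object)
        for col in obs.columns
    }


def read_spatial(
    path: str | Path,
    layout: str = "h5ad",
    *,
    coords_key: str = "spatial",
    h5_paths: Mapping[str, str] | None = None,
) -> SpatialDataset:
    """Read a spatially resolved dataset from ``h5ad`` or generic ``h5``.

    Parameters
    ----------
    path
        Input file.
    layout
        ``"h5ad"`` (AnnData on-disk layout) or ``"h5"`` (generic HDF5 with
        dataset paths given in ``h5_paths``).
    coords_key
        ``obsm`` key holding the per-cell coordinates for the h5ad layout.
    h5_paths
        For the generic layout: mapping with keys ``expression``,
        ``coordinates``, ``gene_symbols``, ``cell_ids`` and optionally
        ``annotations`` (a sub-mapping level-name -> dataset path).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if layout == "h5ad":
        adata = ad.read_h5ad(path)
        if coords_key not in adata.obsm:
            raise StructuralError(
                f"coordinate key {coords_key!r} missing from obsm; "
                f"available: {sorted(adata.obsm.keys())}"
            )
        return SpatialDataset(
            expression=adata.X,
            gene_symbols=list(adata.var_names),
            cell_ids=list(adata.obs_names),
            annotations=_annotations_from_obs(adata.obs),
            coordinates=np.asarray(adata.obsm[coords_key], dtype=float),
        )
    if layout == "h5":
        if h5_paths is None:
            raise StructuralError("generic h5 layout requires explicit h5_paths")
        with h5py.File(path, "r") as f:
            for key in ("expression", "coordinates", "gene_symbols", "cell_ids"):
                if key not in h5_paths:
                    raise StructuralError(f"h5_paths missing required key {key!r}")
                if h5_paths[key] not in f:
                    raise StructuralError(
                        f"dataset path {h5_paths[key]!r} (for {key}) not in file"
                    )
            expr = np.asarray(f[h5_paths["expression"]])
            coords = np.asarray(f[h5_paths["coordinates"]], dtype=float)
            genes = [_decode(x) for x in f[h5_paths["gene_symbols"]][()]]
            cells = [_decode(x) for x in f[h5_paths["cell_ids"]][()]]
            annotations = {}
            for level, dset in dict(h5_paths.get("annotations", {})).items():
                annotations[level] = np.asarray(
                    [_decode(x) for x in f[dset][()]], dtype=object
                )
        return SpatialDataset(
            expression=expr,
            gene_symbols=genes,
            cell_ids=cells,
            annotations=annotations,
            coordinates=coords,
        )
    raise ValueError(f"unknown layout {layout!r}; use 'h5ad' or 'h5'")


def read_scrna(path: str | Path) -> ScRnaDataset:
    """Read an annotated scRNA-seq dataset from an ``h5ad`` file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    adata = ad.read_h5ad(path)
    return ScRnaDataset(
        expression=adata.X,
        gene_symbols=list(adata.var_names),
        cell_ids=list(adata.obs_names),
        annotations=_annotations_from_obs(adata.obs),
    )


def _decode(x) -> str:
    return x.decode() if isinstance(x, bytes) else str(x)


def write_spatial(ds: SpatialDataset, path: str | Path, *, coords_key: str = "spatial") -> None:
    """Write a SpatialDataset to the h5ad layout."""
    adata = _to_anndata(ds)
    adata.obsm[coords_key] = ds.coordinates
    adata.write_h5ad(Path(path))


def write_scrna(ds: ScRnaDataset, path: str | Path) -> None:
    _to_anndata(ds).write_h5ad(Path(path))


def _to_anndata(ds) -> ad.AnnData:
    obs = pd.DataFrame(index=pd.Index(ds.cell_ids, name="cell_id"))
    for level, labels in ds.annotations.items():
        obs[level] = pd.Categorical([str(x) for x in labels])
    X = ds.expression
    if not sp.issparse(X):
        X = np.asarray(X)
    return ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=pd.Index(ds.gene_symbols)))


def read_annotation_averages(path: str | Path) -> AnnotationAverages:
    """Read a pre-computed category x gene average-expression matrix.

    Accepts CSV (first column = category label, header = gene symbols)
    or h5ad (obs_names = categories).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".h5ad":
        adata = ad.read_h5ad(path)
        cats = list(adata.obs_names)
        genes = list(adata.var_names)
        means = np.asarray(
            adata.X.todense() if sp.issparse(adata.X) else adata.X, dtype=float
        )
    else:
        df = pd.read_csv(path, index_col=0)
        cats = [str(c) for c in df.index]
        genes = [str(g) for g in df.columns]
        means = df.to_numpy(dtype=float)
    if len(set(cats)) != len(cats):
        dupes = sorted({c for c in cats if cats.count(c) > 1})
        raise StructuralError(f"duplicate category labels: {dupes}")
    return AnnotationAverages(categories=cats, gene_symbols=genes, means=means)


def write_annotation_averages(av: AnnotationAverages, path: str | Path) -> None:
    """Write averages as CSV or h5ad, chosen by file suffix."""
    path = Path(path)
    if path.suffix == ".h5ad":
        adata = ad.AnnData(
            X=av.means,
            obs=pd.DataFrame(index=pd.Index(av.categories)),
            var=pd.DataFrame(index=pd.Index(av.gene_symbols)),
        )
        adata.write_h5ad(path)
    else:
        df = pd.DataFrame(av.means, index=av.categories, columns=av.gene_symbols)
        df.to_csv(path, float_format=_FLOAT_FORMAT)


def write_table(table: pd.DataFrame, path: str | Path, format: str = "csv") -> None:
    """Write a tabular artifact with deterministic column order.

    ``format="csv"`` writes RFC-4180 UTF-8 CSV; ``format="json"`` writes one
    record per row with keys equal to column names. Floats carry enough
    digits for exact round-trips.
    """
    path = Path(path)
    if format == "csv":
        table.to_csv(path, index=False, float_format=_FLOAT_FORMAT)
    elif format == "json":
        records = []
        for _, row in table.iterrows():
            records.append({k: _jsonable(v) for k, v in row.items()})
        path.write_text(json.dumps(records, indent=1) + "\n")
    else:
        raise ValueError(f"unknown table format {format!r}")


def _jsonable(v):
    if isinstance(v, (np.floating, float)):
        f = float(v)
        return None if np.isnan(f) else f
    if isinstance(v, (np.integer, int)):
        return int(v)
    if isinstance(v, (np.bool_, bool)):
        return bool(v)
    return str(v)
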