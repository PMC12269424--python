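"""Synthetic paired SRT + pseudo-scRNA data with planted structure.

The generator emulates the structures an exploratory spatial co-expression
workflow is meant to find: axis-aligned expression gradients, localized
hotspots, annotation-specific marker genes, and pure noise genes. Cells sit
on an integer 2D/3D grid jittered uniformly in (-0.3, 0.3) per axis to
avoid degenerate spatial distance ties. Annotation regions are contiguous
voxel blocks along the first grid axis, giving a simple mosaic taxonomy
shared by the SRT dataset and a pseudo-scRNA companion.

The SRT dataset carries only a limited shared panel (the leading genes),
mimicking an imaging-based assay; the pseudo-scRNA dataset carries the full
panel, with cells drawn per annotation from the same generative rules at
fresh in-region positions. Noise is Gaussian truncated at zero (expression
is non-negative); the statistics under test are correlations and means, so
count realism is deliberately not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ScRnaDataset, SpatialDataset
from .io import write_scrna, write_spatial

ANNOTATION_LEVEL = "region"
FINE_ANNOTATION_LEVEL = "subregion"


@dataclass
class GradientGenes:
    """``n`` genes varying linearly along one axis: a * coord * sign + noise."""

    n: int = 5
    axis: str = "x"
    sign: int = 1
    amplitude: float = 10.0


@dataclass
class HotspotGenes:
    """``n`` genes with a Gaussian bump: a * exp(-d^2 / 2r^2) + noise."""

    n: int = 0
    center: tuple = (0.0, 0.0, 0.0)
    radius: float = 2.0
    amplitude: float = 10.0


@dataclass
class MarkerGenes:
    """``n`` genes expressed only in one annotation region: a * 1[region]."""

    n: int = 0
    annotation: str = "region_0"
    amplitude: float = 10.0


@dataclass
class SynthSpec:
    """Parameters of one synthetic dataset pair.

    Defaults give a 10 x 10 x 5 grid (500 cells), 4 annotation regions
    (each split into two finer subregions along the second axis, giving a
    two-level taxonomy), and five +x and five -x gradient genes among 140
    noise genes. The first 120 genes form the SRT panel — a desk-scale
    stand-in for a limited imaging panel versus a transcriptome-wide
    reference of 150 genes.
    """

    grid_shape: tuple = (10, 10, 5)
    n_annotations: int = 4
    gradients: list = field(
        default_factory=lambda: [
            GradientGenes(n=5, axis="x", sign=+1),
            GradientGenes(n=5, axis="x", sign=-1),
        ]
    )
    hotspots: list = field(default_factory=list)
    markers: list = field(default_factory=list)
    n_noise_genes: int = 140
    noise_sd: float = 0.5
    shared_panel_size: int = 120
    scrna_cells_per_annotation: int = 50
    seed: int = 0

    def full_panel_size(self) -> int:
        return (
            sum(g.n for g in self.gradients)
            + sum(h.n for h in self.hotspots)
            + sum(m.n for m in self.markers)
            + self.n_noise_genes
        )


_AXIS = {"x": 0, "y": 1, "z": 2}


def _region_labels(coords_grid: np.ndarray, grid_shape: tuple, n_regions: int) -> np.ndarray:
    """Contiguous blocks along axis 0: region_0 ... region_{n-1}."""
    edges = np.linspace(0, grid_shape[0], n_regions + 1)
    block = np.searchsorted(edges, coords_grid[:, 0], side="right") - 1
    block = np.clip(block, 0, n_regions - 1)
    return np.asarray([f"region_{b}" for b in block], dtype=object)


def _subregion_labels(
    coords_grid: np.ndarray, grid_shape: tuple, regions: np.ndarray
) -> np.ndarray:
    """Each region split into two halves along axis 1: region_Ra / region_Rb."""
    half = np.where(coords_grid[:, 1] < grid_shape[1] / 2, "a", "b")
    return np.asarray([f"{r}{h}" for r, h in zip(regions, half)], dtype=object)


def _gene_plan(spec: SynthSpec) -> list[tuple[str, str, object]]:
    """Ordered (name, class, params) triples defining every gene."""
    plan: list[tuple[str, str, object]] = []
    for gi, g in enumerate(spec.gradients):
        tag = "pos" if g.sign > 0 else "neg"
        for j in range(g.n):
            plan.append((f"grad_{g.axis}_{tag}_{gi}_{j:02d}", "gradient", g))
    for hi, h in enumerate(spec.hotspots):
        for j in range(h.n):
            plan.append((f"hotspot_{hi}_{j:02d}", "hotspot", h))
    for mi, m in enumerate(spec.markers):
        for j in range(m.n):
            plan.append((f"marker_{m.annotation}_{mi}_{j:02d}", "marker", m))
    for j in range(spec.n_noise_genes):
        plan.append((f"noise_{j:03d}", "noise", None))
    return plan


def _signal_matrix(
    plan: list, coords: np.ndarray, labels: np.ndarray, grid_shape: tuple
) -> np.ndarray:
    """Noise-free signal for every (cell, gene) pair."""
    n = coords.shape[0]
    sig = np.zeros((n, len(plan)))
    for j, (_, cls, p) in enumerate(plan):
        if cls == "gradient":
            ax = _AXIS[p.axis]
            c = coords[:, ax]
            base = c if p.sign > 0 else (grid_shape[ax] - 1) - c
            sig[:, j] = p.amplitude * base / max(grid_shape[ax] - 1, 1)
        elif cls == "hotspot":
            center = np.asarray(p.center[: coords.shape[1]], dtype=float)
            d2 = ((coords - center) ** 2).sum(axis=1)
            sig[:, j] = p.amplitude * np.exp(-d2 / (2 * p.radius**2))
        elif cls == "marker":
            sig[:, j] = p.amplitude * (labels == p.annotation)
    return sig


def generate(spec: SynthSpec) -> tuple[SpatialDataset, ScRnaDataset, pd.DataFrame]:
    """Generate the (SRT, pseudo-scRNA, ground-truth) triple.

    Deterministic given ``spec.seed``. The ground-truth table records every
    gene's planted class and parameters, and whether it is on the shared
    (SRT) panel.
    """
    rng = np.random.default_rng(spec.seed)
    plan = _gene_plan(spec)
    n_genes = len(plan)
    if spec.shared_panel_size > n_genes:
        raise ValueError(
            f"shared_panel_size {spec.shared_panel_size} exceeds the "
            f"{n_genes} genes defined by the spec"
        )
    for m in spec.markers:
        region_ids = {f"region_{i}" for i in range(spec.n_annotations)}
        if m.annotation not in region_ids:
            raise ValueError(
                f"marker annotation {m.annotation!r} outside the "
                f"{spec.n_annotations}-region mosaic"
            )

    grid = np.stack(
        np.meshgrid(*[np.arange(s) for s in spec.grid_shape], indexing="ij"),
        axis=-1,
    ).reshape(-1, len(spec.grid_shape)).astype(float)
    n_cells = grid.shape[0]
    coords = grid + rng.uniform(-0.3, 0.3, size=grid.shape)
    labels = _region_labels(grid, spec.grid_shape, spec.n_annotations)

    signal = _signal_matrix(plan, grid, labels, spec.grid_shape)
    expr = np.clip(signal + rng.normal(0.0, spec.noise_sd, size=signal.shape), 0.0, None)

    gene_symbols = [name for name, _, _ in plan]
    sublabels = _subregion_labels(grid, spec.grid_shape, labels)
    srt = SpatialDataset(
        expression=expr[:, : spec.shared_panel_size],
        gene_symbols=gene_symbols[: spec.shared_panel_size],
        cell_ids=[f"cell_{i:05d}" for i in range(n_cells)],
        annotations={ANNOTATION_LEVEL: labels, FINE_ANNOTATION_LEVEL: sublabels},
        coordinates=coords,
    )

    # pseudo-scRNA: per annotation, fresh in-region grid positions, full panel
    sc_rows, sc_labels, sc_positions = [], [], []
    edges = np.linspace(0, spec.grid_shape[0], spec.n_annotations + 1)
    for r in range(spec.n_annotations):
        lo, hi = edges[r], edges[r + 1]
        pos = np.column_stack(
            [rng.uniform(lo, hi - 1e-9, size=spec.scrna_cells_per_annotation)]
            + [
                rng.uniform(0, s - 1, size=spec.scrna_cells_per_annotation)
                for s in spec.grid_shape[1:]
            ]
        )
        lab = np.asarray([f"region_{r}"] * spec.scrna_cells_per_annotation, dtype=object)
        sig = _signal_matrix(plan, pos, lab, spec.grid_shape)
        sc_rows.append(sig)
        sc_labels.append(lab)
        sc_positions.append(pos)
    sc_signal = np.vstack(sc_rows)
    sc_expr = np.clip(
        sc_signal + rng.normal(0.0, spec.noise_sd, size=sc_signal.shape), 0.0, None
    )
    sc_lab = np.concatenate(sc_labels)
    sc_sub = _subregion_labels(np.vstack(sc_positions), spec.grid_shape, sc_lab)
    scrna = ScRnaDataset(
        expression=sc_expr,
        gene_symbols=gene_symbols,
        cell_ids=[f"sc_{i:05d}" for i in range(sc_expr.shape[0])],
        annotations={ANNOTATION_LEVEL: sc_lab, FINE_ANNOTATION_LEVEL: sc_sub},
    )

    truth = pd.DataFrame(
        {
            "gene": gene_symbols,
            "class": [cls for _, cls, _ in plan],
            "axis": [getattr(p, "axis", "") for _, _, p in plan],
            "sign": [getattr(p, "sign", 0) for _, _, p in plan],
            "annotation": [getattr(p, "annotation", "") for _, _, p in plan],
            "amplitude": [getattr(p, "amplitude", 0.0) for _, _, p in plan],
            "shared_panel": [j < spec.shared_panel_size for j in range(n_genes)],
        }
    )
    return srt, scrna, truth


def write_fixture(
    srt: SpatialDataset,
    scrna: ScRnaDataset,
    truth: pd.DataFrame,
    outdir: str | Path,
) -> dict[str, Path]:
    """Emit srt.h5ad, scrna.h5ad and ground_truth.csv into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "srt": outdir / "srt.h5ad",
        "scrna": outdir / "scrna.h5ad",
        "ground_truth": outdir / "ground_truth.csv",
    }
    write_spatial(srt, paths["srt"])
    write_scrna(scrna, paths["scrna"])
    truth.to_csv(paths["ground_truth"], index=False)
    return paths
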