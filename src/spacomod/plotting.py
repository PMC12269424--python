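"""Static plot export of module mean maps (replaces interactive rendering)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .clustering import GeneModuleSet
from .core import SpatialDataset


def plot_module_map(
    modules: GeneModuleSet,
    ds: SpatialDataset,
    module_id: int,
    path: str | Path,
    *,
    normalized: bool = True,
    axes: tuple[int, int] = (0, 1),
) -> Path:
    """Scatter of one module's mean expression over the selected cells.

    Unselected cells are drawn in light gray for spatial context; selected
    cells are colored by the module's (normalized) mean map.
    """
    values = (
        modules.normalized_maps[module_id]
        if normalized
        else modules.mean_maps[module_id]
    )
    sel = modules.selection_indices
    ax0, ax1 = axes
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(
        ds.coordinates[:, ax0], ds.coordinates[:, ax1],
        s=4, c="0.85", linewidths=0,
    )
    sc = ax.scatter(
        ds.coordinates[sel, ax0], ds.coordinates[sel, ax1],
        s=8, c=values, cmap="YlOrRd", linewidths=0,
    )
    fig.colorbar(sc, ax=ax, label="normalized mean" if normalized else "mean")
    ax.set_xlabel(f"axis {ax0}")
    ax.set_ylabel(f"axis {ax1}")
    ax.set_title(f"module {module_id} ({len(modules.members(module_id))} genes)")
    ax.set_aspect("equal")
    path = Path(path)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path
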