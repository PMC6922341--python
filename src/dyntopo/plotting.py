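"""Figures: 3-D set-point clouds and support heat maps with vector overlays.

All functions write static image files and return the path; they use the
Agg backend so they run headless.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .forest import QuantileForestModel  # noqa: E402

__all__ = ["plot_setpoints_3d", "plot_heatmap_vectors", "CLASS_COLORS"]

#: attraction blue, repulsion green, transience tan
CLASS_COLORS = {
    "attractor": "blue",
    "repeller": "green",
    "transient": "tan",
    "cycle": "purple",
    "unclassified": "gray",
}


def plot_setpoints_3d(
    setpoints: pd.DataFrame,
    path: Union[str, Path],
    axes: Tuple[str, str, str] = ("a", "b", "y"),
    class_column: str = "dynamics_class",
) -> Path:
    """3-D scatter of set points colored by dynamics class.

    ``setpoints`` is the tabular form (see ``setpoints_to_frame``); for the
    cusp study the default axes render the recovered equilibrium sheet in
    (A, B, Y) space.
    """
    path = Path(path)
    fig = plt.figure(figsize=(7, 6))
    ax = fig.add_subplot(projection="3d")
    present = []
    if len(setpoints):
        classes = (
            setpoints[class_column]
            if class_column in setpoints.columns
            else pd.Series(["unclassified"] * len(setpoints))
        )
        for cls in CLASS_COLORS:
            sub = setpoints[classes == cls]
            if len(sub):
                present.append(cls)
                ax.scatter(
                    sub[axes[0]],
                    sub[axes[1]],
                    sub[axes[2]],
                    c=CLASS_COLORS[cls],
                    s=6,
                    label=cls,
                    depthshade=False,
                )
    ax.set_xlabel(axes[0])
    ax.set_ylabel(axes[1])
    ax.set_zlabel(axes[2])
    if present:
        ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_heatmap_vectors(
    sweep: pd.DataFrame,
    models: Sequence[QuantileForestModel],
    path: Union[str, Path],
    axes: Tuple[str, str] = ("x", "y"),
    vector_points: Optional[pd.DataFrame] = None,
    max_arrows: int = 400,
) -> Path:
    """Support-count heat map with a predicted-change vector overlay.

    ``sweep`` is the output of ``quantile_sweep`` over a 2-D grid (darker
    cells were flagged by more quantile pairs, i.e. are likelier set points).
    Arrows show the change the two models predict: at the grid coordinates
    by default, or at the rows of ``vector_points`` (e.g. the observed test
    rows of one activity) when given.
    """
    if len(models) != 2:
        raise ValueError("heat-map vector plot requires exactly two models")
    path = Path(path)
    xname, yname = axes
    xs = np.sort(sweep[xname].unique())
    ys = np.sort(sweep[yname].unique())
    Z = (
        sweep.pivot_table(index=yname, columns=xname, values="support_count")
        .reindex(index=ys, columns=xs)
        .to_numpy()
    )
    fig, ax = plt.subplots(figsize=(7, 6))
    mesh = ax.pcolormesh(xs, ys, Z, cmap="Greys", shading="nearest")
    fig.colorbar(mesh, ax=ax, label="quantile pairs including zero")

    pts = sweep if vector_points is None else vector_points
    if len(pts) > max_arrows:
        idx = np.linspace(0, len(pts) - 1, max_arrows).astype(int)
        pts = pts.iloc[idx]
    if len(pts):
        u = models[0].predict_mean(pts)
        v = models[1].predict_mean(pts)
        ax.quiver(
            pts[xname],
            pts[yname],
            u,
            v,
            angles="xy",
            color="tab:red",
            width=0.003,
            alpha=0.8,
        )
    ax.set_xlabel(xname)
    ax.set_ylabel(yname)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
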