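"""Heatmap rendering of detection maps: one facet per (ratio, shading)."""

from __future__ import annotations

import numpy as np

from .detection import DetectionMap

__all__ = ["plot_detection_map"]


def plot_detection_map(dm: DetectionMap, channel: str, path=None):
    """Render a facet grid of max-detection-distance heatmaps.

    Rows: coaxial:non-coaxial ratio categories; columns: shading
    categories; within each facet, spark radius (x) against spark band-mean
    radiance (y). Cells where no distance crosses the threshold are white.
    Returns the matplotlib figure; saves to ``path`` if given.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    sub = dm.table[dm.table["channel"] == channel]
    if sub.empty:
        raise ValueError(f"no rows for channel {channel!r}")
    ratios = sorted(sub["ratio"].unique(), reverse=True)
    shadings = [s.value for s in dm.config.shading_categories]
    radii = sorted(sub["spark_radius_mm"].unique())
    radiances = sorted(sub["spark_radiance_mean"].unique())

    fig, axes = plt.subplots(
        len(ratios),
        len(shadings),
        figsize=(3 * len(shadings), 2.6 * len(ratios)),
        squeeze=False,
        sharex=True,
        sharey=True,
    )
    cmap = plt.get_cmap("viridis").copy()
    cmap.set_bad("white")
    vmin, vmax = 5, 45
    im = None
    for i, ratio in enumerate(ratios):
        for j, shading in enumerate(shadings):
            cell = sub[(sub["ratio"] == ratio) & (sub["shading"] == shading)]
            grid = np.full((len(radiances), len(radii)), np.nan)
            for _, row in cell.iterrows():
                yi = radiances.index(row["spark_radiance_mean"])
                xi = radii.index(row["spark_radius_mm"])
                grid[yi, xi] = row["max_distance_mm"]
            ax = axes[i][j]
            im = ax.imshow(
                np.ma.masked_invalid(grid),
                origin="lower",
                aspect="auto",
                cmap=cmap,
                vmin=vmin,
                vmax=vmax,
                extent=(min(radii), max(radii), min(radiances), max(radiances)),
            )
            if i == 0:
                ax.set_title(f"shading: {shading}", fontsize=9)
            if j == 0:
                ax.set_ylabel(f"ratio {ratio:g}\nspark radiance", fontsize=8)
            if i == len(ratios) - 1:
                ax.set_xlabel("spark radius (mm)", fontsize=8)
    fig.colorbar(im, ax=[a for row in axes for a in row], label="max detection distance (mm)")
    fig.suptitle(f"Maximum detection distance — {channel}", fontsize=11)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
    return fig
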