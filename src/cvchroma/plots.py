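"""Chromaticity-diagram scatter plots of specimen measurements.

The plot is a zoomed (x, y) scatter, one marker per specimen coloured by
condition, with auto-fitted axis ranges — the standard way these staining
series are presented, showing the point cloud drifting as immersion time
grows.  No spectral-locus horseshoe is drawn: the region of interest is a
small neighbourhood of the white point where the stain shifts live.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_chromaticity"]


def plot_chromaticity(
    measurements: pd.DataFrame,
    out_path,
    title: str = "xy chromaticity by condition",
) -> Path:
    """Scatter the (x, y) of each specimen, coloured by condition.

    Axis limits auto-fit the data with 10% padding.  The figure carries no
    timestamps, so reruns produce identical files.
    """
    out_path = Path(out_path)
    fig, ax = plt.subplots(figsize=(5, 5))
    for cond, grp in measurements.groupby("condition", sort=False):
        ax.scatter(grp["x"], grp["y"], label=str(cond), s=36, alpha=0.85)
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    ax.set_title(title)
    ax.legend(fontsize=8)
    ax.margins(0.1)
    ax.set_aspect("equal", adjustable="datalim")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150, metadata={"Software": None})
    plt.close(fig)
    return out_path
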