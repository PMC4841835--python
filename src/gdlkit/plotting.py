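"""Plots: feature traces with key-frame color bars, and PCA scatter.

The timeline plot mirrors the classic presentation of a recognized
technique: numeric feature time series below, and a horizontal bar on top
whose colors encode the key frame each sample was assigned to (brown,
yellow, cyan for key frames 1-3; blue for unassigned "N").
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import ListedColormap

from .engine import UNASSIGNED, KeyFrameTimeline

__all__ = ["plot_timeline", "plot_pca", "KEYFRAME_COLORS"]

#: Key-frame bar colors: index 0 = unassigned, then key frames 1, 2, 3, ...
KEYFRAME_COLORS = ["#2040c0", "#8b4513", "#ffd700", "#00c0c0",
                   "#40a040", "#c040c0", "#c04040", "#808080"]


def plot_timeline(times: Sequence[float],
                  feature_values: dict[str, Sequence[float]],
                  timeline: KeyFrameTimeline,
                  path: str | Path) -> None:
    """Feature traces plus the per-frame key-frame assignment bar."""
    order = {name: i + 1 for i, name in enumerate(
        dict.fromkeys(l for l in timeline.labels if l != UNASSIGNED))}
    # stable mapping: use sequence position when label names carry it
    codes = np.array([0 if l == UNASSIGNED else order[l] for l in timeline.labels])
    n_colors = max(int(codes.max()) + 1, 1) if len(codes) else 1
    cmap = ListedColormap(KEYFRAME_COLORS[:max(n_colors, 2)])

    fig, (ax_bar, ax) = plt.subplots(
        2, 1, figsize=(10, 5), sharex=True,
        gridspec_kw={"height_ratios": [1, 6], "hspace": 0.05})
    if len(times):
        ax_bar.imshow(codes[None, :], aspect="auto", cmap=cmap,
                      vmin=0, vmax=max(n_colors - 1, 1),
                      extent=(times[0], times[-1], 0, 1))
    ax_bar.set_yticks([])
    ax_bar.set_title(f"key frames: {timeline.class_name}")
    for name, vals in feature_values.items():
        ax.plot(times, vals, label=name, linewidth=1)
    ax.set_xlabel("time [s]")
    ax.set_ylabel("angle [deg]")
    ax.legend(loc="upper right", fontsize=8, ncol=3)
    fig.savefig(path, dpi=110, bbox_inches="tight")
    plt.close(fig)


def plot_pca(coords: np.ndarray, assignments: np.ndarray,
             explained: np.ndarray, path: str | Path) -> None:
    """2-D or 3-D scatter of the projected feature cloud, colored by cluster."""
    dims = coords.shape[1]
    fig = plt.figure(figsize=(7, 6))
    if dims >= 3:
        ax = fig.add_subplot(111, projection="3d")
        sc = ax.scatter(coords[:, 0], coords[:, 1], coords[:, 2],
                        c=assignments, cmap="viridis", s=8)
        ax.set_zlabel("PC3")
    else:
        ax = fig.add_subplot(111)
        sc = ax.scatter(coords[:, 0], coords[:, 1], c=assignments,
                        cmap="viridis", s=8)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.set_title("feature space, PCA projection "
                 f"({100 * explained[:dims].sum():.1f}% variance)")
    fig.colorbar(sc, ax=ax, label="key-frame cluster")
    fig.savefig(path, dpi=110, bbox_inches="tight")
    plt.close(fig)
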