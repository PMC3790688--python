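"""Rendering: electrode-row t-map rasters and glass-brain scatters."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .erp import StatMap
from .montage import Montage
from .source import Spm

#: raster row order, frontal at the top, occipital at the bottom
ROW_ORDER = ["F", "FC", "C", "CP", "P", "PO", "O", "other"]


def plot_tmap_raster(
    stat_map: StatMap, montage: Montage, path: str | Path, masked: bool = True
) -> Path:
    """Electrode x time image of t values, rows ordered front to back."""
    order = []
    for row in ROW_ORDER:
        for name, lbl, role in zip(montage.names, montage.row_labels, montage.roles):
            if role == "scalp" and lbl == row and name in stat_map.channels:
                order.append(stat_map.channels.index(name))
    t = stat_map.t[order]
    if masked:
        t = np.where(stat_map.sig[order], t, 0.0)
    vmax = max(np.abs(t).max(), 1e-9)
    fig, ax = plt.subplots(figsize=(8, 6))
    im = ax.imshow(
        t,
        aspect="auto",
        cmap="RdBu_r",
        vmin=-vmax,
        vmax=vmax,
        extent=[stat_map.times_ms[0], stat_map.times_ms[-1], len(order), 0],
    )
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("electrodes (frontal at top)")
    fig.colorbar(im, ax=ax, label="t (thresholded)" if masked else "t")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return Path(path)


def plot_glass_brain(spm: Spm, path: str | Path) -> Path:
    """Three orthogonal projections of the voxel statistic map."""
    pts = spm.grid.points_mm
    stat = np.nan_to_num(spm.f, nan=0.0)
    fig, axes = plt.subplots(1, 3, figsize=(11, 4))
    views = [(0, 1, "x (mm)", "y (mm)"), (0, 2, "x (mm)", "z (mm)"), (1, 2, "y (mm)", "z (mm)")]
    for ax, (i, j, xl, yl) in zip(axes, views):
        sc = ax.scatter(
            pts[:, i], pts[:, j], c=stat, s=14, cmap="viridis", alpha=0.7
        )
        if spm.sig.any():
            ax.scatter(
                pts[spm.sig, i], pts[spm.sig, j], facecolors="none",
                edgecolors="red", s=40, label="significant",
            )
        ax.set_xlabel(xl)
        ax.set_ylabel(yl)
        ax.set_aspect("equal")
    fig.colorbar(sc, ax=axes, label="F", shrink=0.8)
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return Path(path)
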