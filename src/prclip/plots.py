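"""Plotting helpers: region distribution, motif tracks, binding isotherms."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from prclip.bli import isotherm


def plot_region_proportions(props: pd.Series, path: str) -> None:
    """Stacked horizontal bar of genomic-region class proportions."""
    fig, ax = plt.subplots(figsize=(6, 1.6))
    left = 0.0
    for cls, frac in props.items():
        ax.barh(0, frac, left=left, label=cls)
        left += frac
    ax.set_xlim(0, 1)
    ax.set_yticks([])
    ax.set_xlabel("fraction of crosslink events")
    ax.legend(loc="upper center", bbox_to_anchor=(0.5, -0.6), ncol=3, fontsize=7)
    fig.savefig(path, bbox_inches="tight", dpi=150)
    plt.close(fig)


def plot_motif_track(track: pd.DataFrame, path: str, title: str = "") -> None:
    """Gene-browser style panel: CPM crosslink track above motif-start marks."""
    fig, (ax1, ax2) = plt.subplots(
        2, 1, figsize=(8, 2.4), sharex=True, height_ratios=[4, 1], constrained_layout=True
    )
    if "cpm" in track:
        ax1.fill_between(track.offset, track.cpm, step="mid", color="#2c6fbb")
    ax1.set_ylabel("CPM")
    ax1.set_title(title, fontsize=9)
    starts = track.offset[track.motif_start]
    ax2.vlines(starts, 0, 1, color="#c23b22", lw=0.6)
    ax2.set_yticks([])
    ax2.set_xlabel("position in gene (nt, transcript orientation)")
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_normalized_isotherm(fits: list, path: str, labels: list[str] | None = None) -> None:
    """Normalized equilibrium response vs concentration with fitted curves."""
    fig, ax = plt.subplots(figsize=(4, 3))
    for i, fit in enumerate(fits):
        pts = fit.points
        lab = labels[i] if labels else f"replicate {i}"
        ax.semilogx(pts.concentration_M, pts.req_normalized, "o", label=lab)
        grid = np.geomspace(pts.concentration_M.min() / 3, pts.concentration_M.max() * 3, 100)
        ax.semilogx(grid, isotherm(grid, fit.kd, fit.rmax) / fit.rmax, "-", lw=0.8)
    ax.set_xlabel("concentration (M)")
    ax.set_ylabel("response / Rmax")
    ax.legend(fontsize=7)
    fig.savefig(path, bbox_inches="tight", dpi=150)
    plt.close(fig)
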