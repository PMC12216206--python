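"""Figure helpers: V-map segment plots, center profiles, Rg panels."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.collections import LineCollection

__all__ = [
    "plot_vmap",
    "plot_center_profile",
    "plot_rg_distribution",
    "plot_distance_distributions",
]


def plot_vmap(vmap, path=None, ax=None, cmap="viridis"):
    """Position-versus-length segment plot of a fragment frequency map.

    Each fragment species is a horizontal segment from start to end at
    height = length, colored and weighted by its mean frequency.
    """
    t = vmap.table
    if ax is None:
        fig, ax = plt.subplots(figsize=(8, 4))
    segs = [((s, l), (e, l)) for s, e, l in zip(t["start"], t["end"], t["length"])]
    freq = t["mean_freq"].to_numpy()
    norm = matplotlib.colors.Normalize(0, freq.max() if freq.size else 1)
    lc = LineCollection(
        segs, cmap=cmap, norm=norm,
        linewidths=0.5 + 4 * freq / (freq.max() or 1),
    )
    lc.set_array(freq)
    ax.add_collection(lc)
    ax.autoscale()
    ax.set_xlabel("position (bp, transcription-oriented)")
    ax.set_ylabel("fragment length (bp)")
    ax.set_title(vmap.locus_name)
    plt.colorbar(lc, ax=ax, label="mean frequency")
    if path:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_center_profile(profile, path=None, ax=None, **kwargs):
    if ax is None:
        fig, ax = plt.subplots(figsize=(7, 3))
    ax.plot(profile.positions, profile.counts, **kwargs)
    ax.axvline(0, color="k", lw=0.5, ls="--")
    ax.set_xlabel("position relative to TSS (bp)")
    ax.set_ylabel(f"fragment centers (pool of {profile.pool_n})")
    ax.set_title(profile.locus_name)
    if path:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_rg_distribution(rgs_by_label: dict, path=None, ax=None, bins=40):
    """Overlaid Rg histograms for named ensembles."""
    if ax is None:
        fig, ax = plt.subplots(figsize=(5, 3.5))
    for label, rgs in rgs_by_label.items():
        ax.hist(np.asarray(rgs), bins=bins, alpha=0.5, density=True, label=label)
    ax.set_xlabel("radius of gyration (nm)")
    ax.set_ylabel("density")
    ax.legend()
    if path:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_distance_distributions(dists, path=None, bins=40):
    """Panel of inter-nucleosome distance histograms, one per pair."""
    pairs = list(dists.distances)
    n = len(pairs)
    ncol = min(3, n)
    nrow = int(np.ceil(n / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.5 * nrow), squeeze=False)
    for ax, pair in zip(axes.flat, pairs):
        ax.hist(dists.distances[pair], bins=bins, density=True)
        ax.set_title(f"{pair[0]} - {pair[1]}", fontsize=9)
        ax.set_xlabel("distance (nm)")
    for ax in axes.flat[n:]:
        ax.axis("off")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
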