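"""Matplotlib figure helpers for the atlas outputs."""

from __future__ import annotations

import numpy as np

from .profiles import AggregateMap, DistanceHistogram, InterChromMatrix


def _get_ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_distance_histogram(hist: DistanceHistogram, ax=None, label=None):
    """Contact-distance distribution on a log-x axis."""
    ax = _get_ax(ax)
    frac = hist.counts / max(hist.total, 1)
    ax.step(hist.centers, frac, where="mid", label=label)
    ax.set_xscale("log")
    ax.set_xlabel("genomic distance (bp)")
    ax.set_ylabel("fraction of intra contacts")
    if label:
        ax.legend()
    return ax


def plot_map(amap: AggregateMap, ax=None, log: bool = True, vmax=None):
    """Aggregated contact map as a heatmap."""
    ax = _get_ax(ax)
    M = amap.to_dense()
    if log:
        M = np.log10(M + 1)
    im = ax.imshow(M, cmap="Reds", vmax=vmax, interpolation="nearest")
    ax.figure.colorbar(im, ax=ax, shrink=0.8)
    ax.set_title(amap.group or "aggregate map")
    return ax


def plot_interchrom(enr: InterChromMatrix, ax=None, vmax: float = 3.0):
    """Inter-chromosomal enrichment heatmap (obs/exp, diagonal masked)."""
    ax = _get_ax(ax)
    im = ax.imshow(enr.enrichment, cmap="coolwarm", vmin=0, vmax=vmax)
    ax.set_xticks(range(len(enr.labels)), enr.labels, rotation=90, fontsize=7)
    ax.set_yticks(range(len(enr.labels)), enr.labels, fontsize=7)
    ax.figure.colorbar(im, ax=ax, shrink=0.8, label="obs / exp")
    return ax


def plot_embedding(coords: np.ndarray, labels=None, ax=None):
    """2D cell embedding coloured by a label vector."""
    ax = _get_ax(ax)
    if labels is None:
        ax.scatter(coords[:, 0], coords[:, 1], s=8)
    else:
        labels = np.asarray(labels)
        for lab in sorted(np.unique(labels)):
            m = labels == lab
            ax.scatter(coords[m, 0], coords[m, 1], s=8, label=str(lab))
        ax.legend(markerscale=2, fontsize=8)
    ax.set_xlabel("dim 1")
    ax.set_ylabel("dim 2")
    return ax
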