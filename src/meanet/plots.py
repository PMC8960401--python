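"""Figure export: raster plots, burst-shape heat maps, canonical score plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .discriminant import DiscriminantResult
from .types import Burst, BurstShape, NetworkBurst, WellRecording

__all__ = ["raster_plot", "burst_shape_heatmap", "canonical_score_plot"]


def raster_plot(
    well: WellRecording,
    bursts_by_channel: dict[str, list[Burst]] | None = None,
    network_bursts: list[NetworkBurst] | None = None,
    t_range: tuple[float, float] | None = None,
    ax=None,
):
    """Spike raster with burst (red) and network-burst (shaded) overlays."""
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 4))
    channels = well.channel_ids
    for i, ch in enumerate(channels):
        t = well.trains[ch]
        ax.vlines(t, i + 0.6, i + 1.4, color="black", lw=0.4)
        for b in (bursts_by_channel or {}).get(ch, []):
            ax.hlines(i + 1, b.start_s, b.end_s, color="crimson", lw=2.5)
    for nb in network_bursts or []:
        ax.axvspan(nb.start_s, nb.end_s, color="mediumpurple", alpha=0.25)
    if t_range:
        ax.set_xlim(*t_range)
    ax.set_yticks(range(1, len(channels) + 1), channels)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("channel")
    ax.set_title(well.well_id)
    return ax


def burst_shape_heatmap(shape: BurstShape, ax=None):
    """Per-burst heat map of aligned binned spike counts (bursts x bins)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    if shape.n_bursts == 0:
        ax.set_title("no network bursts")
        return ax
    extent = (0, shape.n_bins * shape.bin_width_ms, shape.n_bursts, 0)
    im = ax.imshow(shape.counts, aspect="auto", extent=extent, cmap="inferno")
    plt.colorbar(im, ax=ax, label="# spikes")
    ax.set_xlabel("time from network-burst start (ms)")
    ax.set_ylabel("network burst")
    return ax


def _covariance_ellipse(ax, mean, cov, n_sd: float, **kwargs):
    from matplotlib.patches import Ellipse

    vals, vecs = np.linalg.eigh(cov)
    angle = np.degrees(np.arctan2(vecs[1, -1], vecs[0, -1]))
    w, h = 2 * n_sd * np.sqrt(np.clip(vals[::-1], 0, None))
    ax.add_patch(Ellipse(mean, w, h, angle=angle, fill=False, **kwargs))


def canonical_score_plot(result: DiscriminantResult, n_sd: float = 2.447, ax=None):
    """Canonical scores on the first two functions with per-group
    concentration ellipses centered on the group centroids.

    ``n_sd`` scales the ellipse; the default corresponds to a ~95%
    concentration region of a bivariate normal score cloud.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    scores = result.scores
    if scores.shape[1] < 2:
        scores = np.column_stack([scores[:, 0], np.zeros(len(scores))])
    for i, grp in enumerate(result.groups):
        pts = scores[result.score_labels == grp]
        ax.scatter(pts[:, 0], pts[:, 1], s=14, label=str(grp))
        if len(pts) >= 3:
            _covariance_ellipse(
                ax, pts.mean(axis=0), np.cov(pts.T), n_sd=1.0, lw=1.2,
                edgecolor=ax.collections[-1].get_facecolor()[0],
            )
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("canonical function 1")
    ax.set_ylabel("canonical function 2")
    ax.legend(frameon=False)
    return ax
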