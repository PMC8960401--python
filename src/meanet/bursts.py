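"""Single-channel burst detection and well-level network-burst detection.

The burst detector is the classic maximum-ISI rule used by multi-well MEA
analysis software, applied in three fixed stages:

1. *Detect*: maximal runs of consecutive spikes in which every inter-spike
   interval is at most ``max_isi_ms`` become candidate bursts, spanning
   their first to their last spike (ISI exactly at the boundary continues
   the burst).
2. *Merge*: consecutive candidates whose gap (next start minus previous
   end) is smaller than ``merge_gap_ms`` are merged, transitively.
3. *Filter*: merged candidates shorter than ``min_duration_ms`` or with
   fewer than ``min_spikes`` spikes are discarded.

Merging runs before filtering, so short candidates can survive by merging.

A network burst is a well-level epoch during which strictly more than
``nb_channel_fraction`` of the *active* channels (mean firing rate strictly
above ``active_mfr_hz``) are simultaneously inside a burst. Simultaneity is
evaluated instantaneously with a sweep line over burst boundaries, not on a
binned grid. The network-burst window is the union of all single-channel
bursts intersecting the supra-threshold seed interval — the most inclusive
defensible reading, since the network-burst duration is a headline metric;
passing ``window="seed"`` restricts windows to the seed interval itself.
"""

from __future__ import annotations

import logging

import numpy as np

from .types import Burst, BurstParams, NetworkBurst, SpikeTrain, WellRecording

__all__ = ["detect_bursts", "active_channels", "detect_network_bursts", "detect_well"]

logger = logging.getLogger(__name__)


def detect_bursts(train: SpikeTrain, params: BurstParams | None = None) -> list[Burst]:
    """Detect single-channel bursts with the detect → merge → filter rule."""
    params = params or BurstParams()
    params.validate()
    t = np.asarray(train.spike_times_s, dtype=float)
    if len(t) and np.any(np.diff(t) < 0):
        raise ValueError(f"channel {train.channel_id}: spike times must be sorted")
    if len(t) == 0:
        return []

    max_isi_s = params.max_isi_ms / 1000.0
    merge_gap_s = params.merge_gap_ms / 1000.0
    min_dur_s = params.min_duration_ms / 1000.0

    # stage 1: maximal runs with every ISI <= max_isi
    isi = np.diff(t)
    breaks = np.flatnonzero(isi > max_isi_s)
    start_idx = np.concatenate(([0], breaks + 1))
    end_idx = np.concatenate((breaks, [len(t) - 1]))
    candidates = [
        (t[i], t[j], int(j - i + 1)) for i, j in zip(start_idx, end_idx)
    ]

    # stage 2: transitive merge of candidates closer than the merge gap
    merged: list[list] = []
    for start, end, n in candidates:
        if merged and start - merged[-1][1] < merge_gap_s:
            merged[-1][1] = end
            merged[-1][2] += n
        else:
            merged.append([start, end, n])

    # stage 3: duration / spike-count filter
    return [
        Burst(train.channel_id, start, end, n)
        for start, end, n in merged
        if (end - start) >= min_dur_s and n >= params.min_spikes
    ]


def active_channels(
    well: WellRecording, params: BurstParams | None = None
) -> set[str]:
    """Channels whose mean firing rate strictly exceeds the activity threshold."""
    params = params or BurstParams()
    return {
        ch
        for ch, t in well.trains.items()
        if len(t) / well.duration_s > params.active_mfr_hz
    }


def detect_network_bursts(
    well: WellRecording,
    bursts_by_channel: dict[str, list[Burst]],
    params: BurstParams | None = None,
    window: str = "union",
) -> list[NetworkBurst]:
    """Detect network bursts by sweep-line coincidence over channel bursts.

    Parameters
    ----------
    bursts_by_channel:
        Output of :func:`detect_bursts` per channel of the well.
    window:
        ``"union"`` (default) extends each supra-threshold seed interval to
        the union of all intersecting single-channel bursts; ``"seed"``
        keeps the seed interval itself.
    """
    params = params or BurstParams()
    if window not in ("union", "seed"):
        raise ValueError("window must be 'union' or 'seed'")
    active = active_channels(well, params)
    n_active = len(active)
    if n_active == 0:
        logger.warning("well %s: no active channels; no network bursts", well.well_id)
        return []
    threshold = params.nb_channel_fraction * n_active

    all_bursts = [
        b for ch, bs in bursts_by_channel.items() if ch in active for b in bs
    ]
    if not all_bursts:
        return []

    # sweep line: +1 at burst starts, -1 at ends; half-open intervals, so
    # ends are processed before coincident starts
    events = sorted(
        [(b.start_s, 1) for b in all_bursts] + [(b.end_s, -1) for b in all_bursts],
        key=lambda e: (e[0], e[1]),
    )
    seeds: list[tuple[float, float]] = []
    count = 0
    open_start: float | None = None
    for time, delta in events:
        count += delta
        if count > threshold and open_start is None:
            open_start = time
        elif count <= threshold and open_start is not None:
            if time > open_start:
                seeds.append((open_start, time))
            open_start = None

    if not seeds:
        return []

    if window == "union":
        windows = []
        for s, e in seeds:
            hits = [b for b in all_bursts if b.start_s < e and b.end_s > s]
            windows.append(
                (min(b.start_s for b in hits), max(b.end_s for b in hits))
            )
    else:
        windows = list(seeds)

    # merge overlapping / touching windows
    windows.sort()
    merged: list[list[float]] = []
    for s, e in windows:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])

    result = []
    for s, e in merged:
        participants = frozenset(
            ch
            for ch, bs in bursts_by_channel.items()
            if any(b.start_s < e and b.end_s > s for b in bs)
        )
        n_spikes = int(
            sum(
                np.searchsorted(t, e, side="right") - np.searchsorted(t, s, side="left")
                for t in well.trains.values()
            )
        )
        result.append(NetworkBurst(s, e, participants, n_spikes))
    return result


def detect_well(
    well: WellRecording, params: BurstParams | None = None, window: str = "union"
) -> tuple[dict[str, list[Burst]], list[NetworkBurst]]:
    """Convenience: run burst and network-burst detection on a whole well."""
    params = params or BurstParams()
    bursts = {
        ch: detect_bursts(well.spike_train(ch), params) for ch in well.channel_ids
    }
    nbs = detect_network_bursts(well, bursts, params, window=window)
    return bursts, nbs
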