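"""Well-level network parameters, burst shapes, and per-bin group comparison.

The nine parameters exported for every well are: mean firing rate (MFR,
averaged over all electrodes), percentage of random spikes (PRS), and —
from burst/network-burst detection — single-channel burst rate, duration,
firing rate in burst and inter-burst interval (IBI), plus network-burst
rate (NBR), duration (NBD) and network IBI (NIBI).
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from .types import Burst, BurstParams, BurstShape, NetworkBurst, WellFeatures, WellRecording

__all__ = [
    "compute_features",
    "burst_shape",
    "holm_sidak",
    "compare_shapes",
]


def _in_intervals(times: np.ndarray, intervals: list[tuple[float, float]]) -> np.ndarray:
    """Boolean mask: which times fall inside any closed interval."""
    mask = np.zeros(len(times), dtype=bool)
    for s, e in intervals:
        lo = np.searchsorted(times, s, side="left")
        hi = np.searchsorted(times, e, side="right")
        mask[lo:hi] = True
    return mask


def compute_features(
    well: WellRecording,
    bursts_by_channel: dict[str, list[Burst]],
    network_bursts: list[NetworkBurst],
    params: BurstParams | None = None,
    prs_scope: str = "burst_or_network",
) -> WellFeatures:
    """Compute the nine network parameters of one well.

    Conventions
    -----------
    * MFR averages spikes/duration over *all* electrodes of the well,
      silent ones included.
    * PRS counts a spike as non-random when it lies inside a burst on its
      own channel or inside any network-burst window
      (``prs_scope="burst_or_network"``, default); with
      ``prs_scope="own_burst"`` only the channel's own bursts count.
    * Single-channel burst statistics are averaged over channels that have
      at least one burst; IBIs are end-to-next-start.
    * A well with no network bursts reports NBR = 0 and NaN for NBD/NIBI
      (missing, not zero). A well with no spikes reports all NaN.
    """
    params = params or BurstParams()
    if prs_scope not in ("burst_or_network", "own_burst"):
        raise ValueError("prs_scope must be 'burst_or_network' or 'own_burst'")
    meta = dict(well.metadata)
    total = well.total_spikes()
    if total == 0:
        return WellFeatures(well_id=well.well_id, metadata=meta)

    minutes = well.duration_s / 60.0
    mfr = float(
        np.mean([len(t) / well.duration_s for t in well.trains.values()])
    )

    nb_windows = [(nb.start_s, nb.end_s) for nb in network_bursts]
    non_random = 0
    for ch, t in well.trains.items():
        own = [(b.start_s, b.end_s) for b in bursts_by_channel.get(ch, [])]
        mask = _in_intervals(t, own)
        if prs_scope == "burst_or_network" and nb_windows:
            mask |= _in_intervals(t, nb_windows)
        non_random += int(mask.sum())
    prs = 100.0 * (total - non_random) / total

    # single-channel burst statistics over channels having >= 1 burst
    rates, durations, in_rates, ibis = [], [], [], []
    for ch, bs in bursts_by_channel.items():
        if not bs:
            continue
        rates.append(len(bs) / minutes)
        durations.append(float(np.mean([b.duration_ms for b in bs])))
        burst_time = sum(b.end_s - b.start_s for b in bs)
        burst_spikes = sum(b.n_spikes for b in bs)
        if burst_time > 0:
            in_rates.append(burst_spikes / burst_time)
        if len(bs) >= 2:
            ibis.append(
                float(
                    np.mean(
                        [b2.start_s - b1.end_s for b1, b2 in zip(bs, bs[1:])]
                    )
                )
            )

    def mean_or_nan(values: list) -> float:
        return float(np.mean(values)) if values else math.nan

    nbr = len(network_bursts) / minutes
    if network_bursts:
        nbd = float(np.mean([nb.duration_ms for nb in network_bursts]))
        nibi = (
            float(
                np.mean(
                    [
                        b2.start_s - b1.end_s
                        for b1, b2 in zip(network_bursts, network_bursts[1:])
                    ]
                )
            )
            if len(network_bursts) >= 2
            else math.nan
        )
    else:
        nbd = math.nan
        nibi = math.nan

    return WellFeatures(
        well_id=well.well_id,
        mfr_hz=mfr,
        prs_pct=prs,
        burst_rate_per_min=mean_or_nan(rates),
        burst_duration_ms=mean_or_nan(durations),
        fr_in_burst_hz=mean_or_nan(in_rates),
        ibi_s=mean_or_nan(ibis),
        nbr_per_min=nbr,
        nbd_ms=nbd,
        nibi_s=nibi,
        metadata=meta,
    )


def burst_shape(
    well: WellRecording,
    network_bursts: list[NetworkBurst],
    bin_width_ms: float = 10.0,
) -> BurstShape:
    """Aligned, binned spike-count profiles of a well's network bursts.

    Every network burst is aligned at its window start; spikes from all
    channels are binned at ``bin_width_ms`` out to the longest window. The
    mean profile is the per-bin mean across bursts. A well without network
    bursts yields an empty (0-row) shape.
    """
    if bin_width_ms <= 0:
        raise ValueError("bin_width_ms must be positive")
    if not network_bursts:
        return BurstShape(bin_width_ms, np.zeros((0, 0)), np.zeros(0))
    bw_s = bin_width_ms / 1000.0
    longest = max(nb.end_s - nb.start_s for nb in network_bursts)
    n_bins = max(1, int(math.ceil(longest / bw_s - 1e-12)))
    edges = np.arange(n_bins + 1) * bw_s
    rows = np.zeros((len(network_bursts), n_bins))
    for i, nb in enumerate(network_bursts):
        rel = []
        for t in well.trains.values():
            lo = np.searchsorted(t, nb.start_s, side="left")
            hi = np.searchsorted(t, nb.end_s, side="right")
            rel.append(t[lo:hi] - nb.start_s)
        rel = np.concatenate(rel) if rel else np.empty(0)
        # clip spikes landing exactly on the outer edge into the last bin
        rel = np.minimum(rel, edges[-1] - 1e-12)
        rows[i], _ = np.histogram(rel, bins=edges)
    return BurstShape(bin_width_ms, rows, rows.mean(axis=0))


def holm_sidak(p_values: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Holm–Šidák step-down significance flags for a vector of p-values.

    P-values are ordered ascending; the hypothesis at step *i* (1-based) is
    significant iff p_(i) <= 1 - (1 - alpha)^(1/(m - i + 1)) and all
    earlier steps were significant. Returns a boolean array in the input
    order. NaN p-values are treated as 1 (never significant).
    """
    p = np.asarray(p_values, dtype=float)
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    m = len(p)
    flags = np.zeros(m, dtype=bool)
    if m == 0:
        return flags
    p_filled = np.where(np.isnan(p), 1.0, p)
    order = np.argsort(p_filled, kind="stable")
    for step, idx in enumerate(order):  # step is 0-based
        remaining = m - step
        # remaining == 1 reduces to alpha exactly; avoid the float residue
        # of 1 - (1 - alpha)**1
        threshold = alpha if remaining == 1 else 1.0 - (1.0 - alpha) ** (1.0 / remaining)
        if p_filled[idx] <= threshold:
            flags[idx] = True
        else:
            break
    return flags


def compare_shapes(
    profiles_a: np.ndarray,
    profiles_b: np.ndarray,
    alpha: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin two-sample t-tests across wells with Holm–Šidák correction.

    Parameters
    ----------
    profiles_a, profiles_b:
        Arrays of shape (wells, bins) holding one mean burst-shape profile
        per well, binned identically in both groups.

    Returns
    -------
    (p_values, significant):
        Raw per-bin p-values and the Holm–Šidák step-down significance
        flags at level ``alpha``.
    """
    a = np.atleast_2d(np.asarray(profiles_a, dtype=float))
    b = np.atleast_2d(np.asarray(profiles_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError(
            f"bin count mismatch between groups ({a.shape[1]} vs {b.shape[1]}); "
            "profiles must share a bin width and length"
        )
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs at least 2 wells")
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(a, b, axis=0)
    p = np.where(np.isnan(p), 1.0, p)
    return p, holm_sidak(p, alpha)
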