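"""Core containers shared across the analysis stages.

Times are stored in seconds throughout the package; durations that mirror
vendor-software conventions (burst and network-burst durations, ISI windows)
are expressed in milliseconds in parameter objects and feature tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "FilterSpec",
    "RawTrace",
    "SpikeTrain",
    "BurstParams",
    "Burst",
    "NetworkBurst",
    "WellRecording",
    "WellFeatures",
    "BurstShape",
    "QCResult",
]


@dataclass(frozen=True)
class FilterSpec:
    """Band-limiting filter applied to raw extracellular traces.

    The defaults reproduce the acquisition chain of a standard multi-well
    MEA system: a 2nd-order Butterworth high-pass at 100 Hz followed by a
    4th-order Butterworth low-pass at 3500 Hz.
    """

    hp_order: int = 2
    hp_cutoff_hz: float = 100.0
    lp_order: int = 4
    lp_cutoff_hz: float = 3500.0

    def validate(self, sampling_rate_hz: float) -> None:
        nyq = sampling_rate_hz / 2.0
        if not (0 < self.hp_cutoff_hz < self.lp_cutoff_hz):
            raise ValueError(
                f"hp_cutoff_hz ({self.hp_cutoff_hz}) must be positive and below "
                f"lp_cutoff_hz ({self.lp_cutoff_hz})"
            )
        if self.lp_cutoff_hz >= nyq:
            raise ValueError(
                f"lp_cutoff_hz ({self.lp_cutoff_hz}) must be below the Nyquist "
                f"frequency ({nyq})"
            )
        if self.hp_order < 1 or self.lp_order < 1:
            raise ValueError("filter orders must be positive")


@dataclass
class RawTrace:
    """A single-channel extracellular voltage trace in microvolts."""

    channel_id: str
    samples: np.ndarray
    sampling_rate_hz: float = 10_000.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sampling_rate_hz


@dataclass
class SpikeTrain:
    """Sorted spike timestamps (seconds) of one electrode."""

    channel_id: str
    spike_times_s: np.ndarray

    def __post_init__(self) -> None:
        self.spike_times_s = np.asarray(self.spike_times_s, dtype=float)
        if self.spike_times_s.ndim != 1:
            raise ValueError("spike_times_s must be one-dimensional")
        if len(self.spike_times_s) and self.spike_times_s[0] < 0:
            raise ValueError("spike times must be non-negative")

    def __len__(self) -> int:
        return len(self.spike_times_s)


@dataclass(frozen=True)
class BurstParams:
    """Parameters of the ISI burst detector and the network-burst rule.

    Defaults follow the standard multi-well analysis convention: bursts are
    maximal spike runs with inter-spike intervals of at most ``max_isi_ms``;
    bursts closer than ``merge_gap_ms`` are merged; merged bursts shorter
    than ``min_duration_ms`` or with fewer than ``min_spikes`` spikes are
    discarded. A network burst requires simultaneous bursting on strictly
    more than ``nb_channel_fraction`` of the active channels, where a
    channel is active when its mean firing rate strictly exceeds
    ``active_mfr_hz``.
    """

    max_isi_ms: float = 30.0
    merge_gap_ms: float = 65.0
    min_duration_ms: float = 50.0
    min_spikes: int = 4
    nb_channel_fraction: float = 0.8
    active_mfr_hz: float = 0.1

    def validate(self) -> None:
        for name in ("max_isi_ms", "merge_gap_ms", "min_duration_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_spikes < 1:
            raise ValueError("min_spikes must be at least 1")
        if not (0 < self.nb_channel_fraction < 1):
            raise ValueError("nb_channel_fraction must be in (0, 1)")
        if self.active_mfr_hz < 0:
            raise ValueError("active_mfr_hz must be non-negative")


@dataclass(frozen=True)
class Burst:
    """A single-channel burst spanning its first to its last spike."""

    channel_id: str
    start_s: float
    end_s: float
    n_spikes: int

    @property
    def duration_ms(self) -> float:
        return (self.end_s - self.start_s) * 1000.0


@dataclass(frozen=True)
class NetworkBurst:
    """A well-level epoch of coincident bursting across channels."""

    start_s: float
    end_s: float
    participating_channels: frozenset
    n_spikes: int

    @property
    def duration_ms(self) -> float:
        return (self.end_s - self.start_s) * 1000.0


@dataclass
class WellRecording:
    """All spike trains of one MEA well, plus experiment metadata.

    ``trains`` maps channel id to a sorted array of spike times in seconds.
    ``metadata`` carries free-form labels such as the group name, DIV and
    culture composition tag.
    """

    well_id: str
    duration_s: float
    trains: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        clean: dict[str, np.ndarray] = {}
        for ch in sorted(self.trains):
            t = np.asarray(self.trains[ch], dtype=float)
            if len(t):
                if t.min() < 0 or t.max() > self.duration_s:
                    raise ValueError(
                        f"channel {ch}: spike times must lie in [0, duration_s]"
                    )
                if np.any(np.diff(t) < 0):
                    raise ValueError(f"channel {ch}: spike times must be sorted")
            clean[ch] = t
        self.trains = clean

    @property
    def channel_ids(self) -> list[str]:
        return list(self.trains)

    @property
    def n_channels(self) -> int:
        return len(self.trains)

    def total_spikes(self) -> int:
        return int(sum(len(t) for t in self.trains.values()))

    def spike_train(self, channel_id: str) -> SpikeTrain:
        return SpikeTrain(channel_id, self.trains[channel_id])


@dataclass
class WellFeatures:
    """The nine well-level network parameters.

    Missing values (e.g. network-burst duration of a well with no network
    bursts) are represented as NaN rather than zero so that group averages
    are not biased toward zero.
    """

    well_id: str
    mfr_hz: float = math.nan
    prs_pct: float = math.nan
    burst_rate_per_min: float = math.nan
    burst_duration_ms: float = math.nan
    fr_in_burst_hz: float = math.nan
    ibi_s: float = math.nan
    nbr_per_min: float = math.nan
    nbd_ms: float = math.nan
    nibi_s: float = math.nan
    metadata: Mapping = field(default_factory=dict)

    #: canonical ordering of the nine parameters, used by the feature table
    #: exporter and the discriminant analysis.
    PARAMETERS = (
        "mfr_hz",
        "prs_pct",
        "burst_rate_per_min",
        "burst_duration_ms",
        "fr_in_burst_hz",
        "ibi_s",
        "nbr_per_min",
        "nbd_ms",
        "nibi_s",
    )

    def as_dict(self) -> dict:
        row = {"well_id": self.well_id}
        row.update({k: getattr(self, k) for k in self.PARAMETERS})
        row.update(self.metadata)
        return row


@dataclass
class BurstShape:
    """Aligned, binned spike-count profiles of a well's network bursts.

    ``counts`` has one row per network burst; bursts are aligned at their
    window start and binned at ``bin_width_ms`` out to the longest window.
    """

    bin_width_ms: float
    counts: np.ndarray  # (n_bursts, n_bins) spike counts summed over channels
    mean_profile: np.ndarray  # (n_bins,)

    @property
    def n_bursts(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]


@dataclass(frozen=True)
class QCResult:
    """Outcome of the well inclusion/exclusion rules."""

    well_id: str
    included: bool
    violated: tuple[str, ...]
    notes: tuple[str, ...] = ()
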