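"""Synthetic multi-well MEA activity with planted, recoverable structure.

The generator emulates the activity classes seen in excitatory/inhibitory
(E/I) neuronal co-cultures on micro-electrode arrays: tonic random spiking
on every electrode, plus network-wide bursts during which recruited
electrodes fire at a high rate. An ``inhibitory_fraction`` knob maps the
fraction of GABAergic neurons in the culture to burst statistics: more
inhibition shortens network bursts, lowers the within-burst firing rate and
raises the tonic (random) rate, mirroring the qualitative effect of
inhibitory neurons on cultured network dynamics.

The network-burst process is a renewal process with exponential gaps and
gamma-distributed durations. This is not a biophysical model — it is the
simplest point-process description under which every planted quantity
(window positions, recruited channels, spike labels) is exactly known, so
the downstream detectors can be validated against ground truth.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import RawTrace, WellRecording

__all__ = [
    "SyntheticNetworkSpec",
    "EIMapEndpoints",
    "GroundTruth",
    "generate_well",
    "ei_spec",
    "generate_ei_series",
    "generate_raw_trace",
    "generate_psc_events",
    "default_spike_template",
]

#: Minimum admissible mean inter-burst gap (seconds). Specs whose burst rate
#: and duration would leave a smaller mean gap are rejected, because their
#: planted windows could be merged by the 65-ms burst-merge rule of the
#: detector and the ground truth would stop being identifiable.
MIN_MEAN_GAP_S = 0.2


@dataclass(frozen=True)
class SyntheticNetworkSpec:
    """Planted parameters of one generated well.

    Parameters
    ----------
    n_channels:
        Electrodes per well (12 matches a 24-well MEA plate layout).
    duration_s:
        Recording length in seconds (600 s = the standard 10-min session).
    tonic_rate_hz:
        Per-channel Poisson background rate, active for the whole recording.
    nb_rate_per_min:
        Rate of the renewal process that places network-burst windows.
    nb_duration_ms, nb_duration_cv:
        Mean and coefficient of variation of the gamma-distributed window
        durations.
    in_burst_rate_hz:
        Per-channel Poisson rate inside a network-burst window.
    participation_frac:
        Probability that a channel is recruited into a given window.
    onset_jitter_ms:
        SD of the Gaussian per-channel shift of the burst window.
    inhibitory_fraction:
        Dimensionless knob in [0, 0.35] recording which point of the E/I
        titration this spec represents; it does not by itself alter the
        rates (see :func:`ei_spec`).
    """

    n_channels: int = 12
    duration_s: float = 600.0
    tonic_rate_hz: float = 0.3
    nb_rate_per_min: float = 4.0
    nb_duration_ms: float = 1200.0
    nb_duration_cv: float = 0.2
    in_burst_rate_hz: float = 150.0
    participation_frac: float = 1.0
    onset_jitter_ms: float = 10.0
    inhibitory_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be a positive integer")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        for name in ("tonic_rate_hz", "nb_rate_per_min", "in_burst_rate_hz"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0 < self.participation_frac <= 1):
            raise ValueError("participation_frac must lie in (0, 1]")
        if self.nb_duration_ms <= 0:
            raise ValueError("nb_duration_ms must be positive")
        if self.nb_duration_cv < 0:
            raise ValueError("nb_duration_cv must be non-negative")
        if self.onset_jitter_ms < 0:
            raise ValueError("onset_jitter_ms must be non-negative")
        if not (0 <= self.inhibitory_fraction <= 0.35):
            raise ValueError("inhibitory_fraction must lie in [0, 0.35]")
        if self.nb_rate_per_min > 0:
            mean_gap_s = 60.0 / self.nb_rate_per_min - self.nb_duration_ms / 1000.0
            if mean_gap_s < MIN_MEAN_GAP_S:
                raise ValueError(
                    "nb_rate_per_min and nb_duration_ms leave a mean inter-burst "
                    f"gap of {mean_gap_s:.3f} s (< {MIN_MEAN_GAP_S} s); planted "
                    "windows would not be identifiable"
                )

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class EIMapEndpoints:
    """Endpoints of the linear map from inhibitory fraction to burst statistics.

    The defaults place a purely excitatory network (fraction 0) at long
    (1200 ms), intense (150 Hz) network bursts with sparse tonic activity
    (0.3 Hz), and the strongest titrated inhibition (fraction 0.35) at
    short (300 ms), weaker (60 Hz) bursts with more random spiking
    (0.8 Hz) — the direction of change observed when GABAergic neurons are
    titrated into cultured networks.
    """

    fraction_max: float = 0.35
    nbd_ms_at_0: float = 1200.0
    nbd_ms_at_max: float = 300.0
    in_burst_hz_at_0: float = 150.0
    in_burst_hz_at_max: float = 60.0
    tonic_hz_at_0: float = 0.3
    tonic_hz_at_max: float = 0.8


@dataclass
class GroundTruth:
    """Planted structure of a generated well.

    ``windows`` is a DataFrame with columns ``start_s``, ``end_s`` and
    ``channels`` (frozenset of recruited channel ids); start/end enclose
    every in-burst spike of the window, including per-channel onset jitter.
    ``in_burst`` maps channel id to a boolean array aligned with the
    channel's sorted spike times (True = spike generated inside a window).
    """

    spec: SyntheticNetworkSpec
    windows: pd.DataFrame
    in_burst: dict[str, np.ndarray]

    @property
    def n_windows(self) -> int:
        return len(self.windows)


def _channel_ids(n: int) -> list[str]:
    return [f"ch{i:02d}" for i in range(n)]


def _draw_windows(spec: SyntheticNetworkSpec, rng: np.random.Generator):
    """Renewal process: exponential gaps at nb_rate_per_min, gamma durations."""
    if spec.nb_rate_per_min == 0:
        return []
    rate_hz = spec.nb_rate_per_min / 60.0
    mean_dur_s = spec.nb_duration_ms / 1000.0
    cv = spec.nb_duration_cv
    windows = []
    t = rng.exponential(1.0 / rate_hz)
    while t < spec.duration_s:
        if cv == 0:
            dur = mean_dur_s
        else:
            shape = 1.0 / cv**2
            dur = rng.gamma(shape, mean_dur_s / shape)
        end = min(t + dur, spec.duration_s)
        if end > t:
            windows.append((t, end))
        t = end + rng.exponential(1.0 / rate_hz)
    return windows


def generate_well(spec: SyntheticNetworkSpec) -> tuple[WellRecording, GroundTruth]:
    """Generate one well of spike trains with planted network bursts.

    The global seed feeds a splittable RNG (`numpy.random.SeedSequence`):
    one child stream draws the network-burst windows, and each channel owns
    its own stream, so increasing ``n_channels`` leaves the spike trains of
    existing channels unchanged.

    Returns the recording together with the :class:`GroundTruth` holding
    the planted windows, per-spike labels and the spec itself.
    """
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    window_ss, *channel_ss = root.spawn(1 + spec.n_channels)
    window_rng = np.random.Generator(np.random.PCG64(window_ss))

    windows = _draw_windows(spec, window_rng)
    channels = _channel_ids(spec.n_channels)

    trains: dict[str, np.ndarray] = {}
    in_burst: dict[str, np.ndarray] = {}
    recruited: list[set] = [set() for _ in windows]
    # realized per-window envelope over recruited channels (jitter included)
    env_start = [s for s, _ in windows]
    env_end = [e for _, e in windows]

    for ch, ss in zip(channels, channel_ss):
        rng = np.random.Generator(np.random.PCG64(ss))
        n_tonic = rng.poisson(spec.tonic_rate_hz * spec.duration_s)
        tonic = rng.uniform(0.0, spec.duration_s, size=n_tonic)
        burst_spikes = []
        for w, (w_start, w_end) in enumerate(windows):
            recruit = rng.random() < spec.participation_frac
            jitter = rng.normal(0.0, spec.onset_jitter_ms / 1000.0)
            if not recruit:
                continue
            start = max(0.0, w_start + jitter)
            end = min(spec.duration_s, w_end + jitter)
            if end <= start:
                continue
            n_in = rng.poisson(spec.in_burst_rate_hz * (end - start))
            if n_in == 0:
                continue
            recruited[w].add(ch)
            env_start[w] = min(env_start[w], start)
            env_end[w] = max(env_end[w], end)
            burst_spikes.append(rng.uniform(start, end, size=n_in))
        burst = (
            np.concatenate(burst_spikes) if burst_spikes else np.empty(0)
        )
        times = np.concatenate([tonic, burst])
        labels = np.concatenate(
            [np.zeros(len(tonic), dtype=bool), np.ones(len(burst), dtype=bool)]
        )
        order = np.argsort(times, kind="stable")
        trains[ch] = times[order]
        in_burst[ch] = labels[order]

    gt_windows = pd.DataFrame(
        {
            "start_s": env_start,
            "end_s": env_end,
            "channels": [frozenset(r) for r in recruited],
        }
    )
    well = WellRecording(
        well_id=f"synthetic-seed{spec.seed}",
        duration_s=spec.duration_s,
        trains=trains,
        metadata={"inhibitory_fraction": spec.inhibitory_fraction},
    )
    return well, GroundTruth(spec=spec, windows=gt_windows, in_burst=in_burst)


def ei_spec(
    base: SyntheticNetworkSpec,
    inhibitory_fraction: float,
    endpoints: EIMapEndpoints | None = None,
    seed: int | None = None,
) -> SyntheticNetworkSpec:
    """Map an inhibitory fraction to a concrete spec by linear interpolation.

    Network-burst duration and in-burst rate decrease, and the tonic rate
    increases, linearly between the endpoint values as the fraction goes
    from 0 to ``endpoints.fraction_max``. All other fields are copied from
    ``base``.
    """
    ep = endpoints or EIMapEndpoints()
    if not (0 <= inhibitory_fraction <= ep.fraction_max):
        raise ValueError(
            f"inhibitory_fraction {inhibitory_fraction} outside [0, {ep.fraction_max}]"
        )
    x = inhibitory_fraction / ep.fraction_max

    def lerp(a: float, b: float) -> float:
        return a + (b - a) * x

    return replace(
        base,
        inhibitory_fraction=inhibitory_fraction,
        nb_duration_ms=lerp(ep.nbd_ms_at_0, ep.nbd_ms_at_max),
        in_burst_rate_hz=lerp(ep.in_burst_hz_at_0, ep.in_burst_hz_at_max),
        tonic_rate_hz=lerp(ep.tonic_hz_at_0, ep.tonic_hz_at_max),
        seed=base.seed if seed is None else seed,
    )


def generate_ei_series(
    base: SyntheticNetworkSpec,
    inhibitory_fractions: Sequence[float],
    endpoints: EIMapEndpoints | None = None,
) -> list[tuple[WellRecording, GroundTruth]]:
    """Generate a titration series of wells over ascending inhibitory fractions."""
    fracs = list(inhibitory_fractions)
    if any(b < a for a, b in zip(fracs, fracs[1:])):
        raise ValueError("inhibitory_fractions must be sorted ascending")
    return [generate_well(ei_spec(base, f, endpoints)) for f in fracs]


def default_spike_template(
    sampling_rate_hz: float = 10_000.0,
    amplitude: float = 1.0,
    width_ms: float = 1.0,
) -> np.ndarray:
    """Biphasic extracellular spike template (negative-leading), peak −amplitude."""
    n = max(3, int(round(width_ms / 1000.0 * sampling_rate_hz)))
    t = np.linspace(-1.0, 1.0, n)
    wave = -np.exp(-((t / 0.35) ** 2)) + 0.35 * np.exp(-(((t - 0.55) / 0.45) ** 2))
    return amplitude * wave / np.abs(wave).max()


def generate_raw_trace(
    spike_times_s: Iterable[float],
    template: np.ndarray,
    noise_sd: float,
    sampling_rate_hz: float = 10_000.0,
    duration_s: float | None = None,
    seed: int = 0,
    channel_id: str = "ch00",
) -> RawTrace:
    """Raw trace = i.i.d. Gaussian noise plus a spike template at each spike time.

    Template peaks land on the sample nearest each spike time. Templates
    closer together than one template length overlap; a warning is emitted
    and superposition is still applied.
    """
    times = np.sort(np.asarray(list(spike_times_s), dtype=float))
    template = np.asarray(template, dtype=float)
    if duration_s is None:
        duration_s = (times.max() if len(times) else 0.0) + 0.1
    n = int(round(duration_s * sampling_rate_hz))
    if len(times) and times.max() >= duration_s:
        raise ValueError("spike times must lie within the trace duration")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    trace = (
        rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    )
    tmpl_len = len(template)
    peak_off = int(np.argmax(np.abs(template)))
    if len(times) > 1 and np.any(np.diff(times) * sampling_rate_hz < tmpl_len):
        warnings.warn(
            "spike templates overlap (closer than one template length); "
            "superposition applied",
            stacklevel=2,
        )
    for t in times:
        peak_idx = int(round(t * sampling_rate_hz))
        lo = peak_idx - peak_off
        hi = lo + tmpl_len
        s0, s1 = max(lo, 0), min(hi, n)
        trace[s0:s1] += template[s0 - lo : tmpl_len - (hi - s1)]
    return RawTrace(channel_id=channel_id, samples=trace, sampling_rate_hz=sampling_rate_hz)


def generate_psc_events(
    n_glu: int,
    n_gaba: int,
    glu_decay_ms: tuple[float, float] = (2.0, 0.5),
    gaba_decay_ms: tuple[float, float] = (7.0, 1.5),
    duration_s: float = 300.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-population postsynaptic-current event stream with true class labels.

    Decay times are drawn from normal distributions truncated at zero
    (mean, SD in milliseconds per class); event times are Poisson
    (uniform order statistics) over ``duration_s``; amplitudes are
    log-normal plumbing so the table is shaped like a real event export.
    """
    if n_glu < 0 or n_gaba < 0:
        raise ValueError("event counts must be non-negative")
    for name, (mean, sd) in (("glu", glu_decay_ms), ("gaba", gaba_decay_ms)):
        if mean <= 0:
            raise ValueError(f"{name} decay mean must be positive")
        if sd < 0:
            raise ValueError(f"{name} decay SD must be non-negative")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))

    def draw_decays(n: int, mean: float, sd: float) -> np.ndarray:
        if n == 0:
            return np.empty(0)
        if sd == 0:
            return np.full(n, mean)
        a = (0.0 - mean) / sd
        return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)

    n_total = n_glu + n_gaba
    decay = np.concatenate(
        [draw_decays(n_glu, *glu_decay_ms), draw_decays(n_gaba, *gaba_decay_ms)]
    )
    true_class = np.array(["glutamatergic"] * n_glu + ["GABAergic"] * n_gaba)
    times = np.sort(rng.uniform(0.0, duration_s, size=n_total))
    order = rng.permutation(n_total)  # interleave the two classes in time
    df = pd.DataFrame(
        {
            "time_s": times,
            "amplitude_pA": rng.lognormal(math.log(25.0), 0.4, size=n_total),
            "decay_ms": decay[order],
            "true_class": true_class[order],
        }
    )
    return df
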