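"""File formats: spike-table CSV/HDF5, raw-trace HDF5, configs and manifests.

The spike-table CSV schema is fixed to avoid dialect drift: header row
required, columns ``well_id, channel_id, time_s``, UTF-8, '.' decimal,
times in seconds. HDF5 recordings hold one dataset per channel under
``/spikes`` with ``well_id`` and ``duration_s`` as root attributes. Run
configurations are flat YAML. Every pipeline run writes a JSON manifest
recording package version, parameters and input hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .types import Burst, NetworkBurst, WellFeatures, WellRecording

__all__ = [
    "save_recording",
    "load_recording",
    "save_raw_traces",
    "load_raw_traces",
    "bursts_table",
    "network_bursts_table",
    "features_table",
    "load_config",
    "write_manifest",
    "sha256_of",
]

logger = logging.getLogger(__name__)

SPIKE_CSV_COLUMNS = ["well_id", "channel_id", "time_s"]


def save_recording(well: WellRecording, path: str | Path, format: str | None = None) -> None:
    """Write a well to CSV or HDF5 (format inferred from the suffix)."""
    path = Path(path)
    format = format or ("hdf5" if path.suffix in (".h5", ".hdf5") else "csv")
    if format == "csv":
        rows = [
            {"well_id": well.well_id, "channel_id": ch, "time_s": t}
            for ch, times in well.trains.items()
            for t in times
        ]
        df = pd.DataFrame(rows, columns=SPIKE_CSV_COLUMNS)
        # 17 significant digits: lossless binary64 round-trip
        df.to_csv(path, index=False, float_format="%.17g")
        meta = {"duration_s": well.duration_s, **well.metadata}
        path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta))
    elif format == "hdf5":
        with h5py.File(path, "w") as f:
            f.attrs["well_id"] = well.well_id
            f.attrs["duration_s"] = well.duration_s
            f.attrs["metadata"] = json.dumps(well.metadata)
            grp = f.create_group("spikes")
            for ch, times in well.trains.items():
                grp.create_dataset(ch, data=np.asarray(times, dtype=float))
    else:
        raise ValueError(f"unknown format {format!r}")


def load_recording(
    path: str | Path, format: str | None = None, duration_s: float | None = None
) -> WellRecording:
    """Load a well from CSV or HDF5, validating and sorting channels.

    For CSV, the duration comes from (in order) the ``duration_s``
    argument, a ``<file>.meta.json`` sidecar, or — with a logged note —
    the maximum spike time rounded up to the next second. Channels arrive
    sorted by id; an unsorted channel is sorted with a logged warning;
    negative spike times raise with the offending row number.
    """
    path = Path(path)
    format = format or ("hdf5" if path.suffix in (".h5", ".hdf5") else "csv")
    if format == "hdf5":
        with h5py.File(path, "r") as f:
            trains = {ch: f["spikes"][ch][...] for ch in f["spikes"]}
            meta = json.loads(f.attrs.get("metadata", "{}"))
            return WellRecording(
                well_id=str(f.attrs["well_id"]),
                duration_s=float(f.attrs["duration_s"]),
                trains=trains,
                metadata=meta,
            )
    if format != "csv":
        raise ValueError(f"unknown format {format!r}")

    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in SPIKE_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    metadata: dict = {}
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        metadata = json.loads(sidecar.read_text())
        duration_s = duration_s if duration_s is not None else metadata.pop("duration_s", None)
    if df.empty:
        logger.warning("%s: empty spike table; returning empty well", path)
        return WellRecording(
            well_id=path.stem, duration_s=duration_s or 1.0, trains={}, metadata=metadata
        )
    bad = df.index[df["time_s"] < 0]
    if len(bad):
        raise ValueError(f"{path}: negative spike time at row {int(bad[0]) + 2}")
    well_ids = df["well_id"].unique()
    if len(well_ids) != 1:
        raise ValueError(f"{path}: expected a single well, found {list(well_ids)}")
    if duration_s is None:
        duration_s = float(np.ceil(df["time_s"].max()))
        logger.info("%s: duration not given; inferred %.0f s from spikes", path, duration_s)
    trains = {}
    for ch, sub in df.groupby("channel_id", sort=True):
        t = sub["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) < 0):
            logger.warning("%s: channel %s unsorted; sorting", path, ch)
            t = np.sort(t)
        trains[str(ch)] = t
    return WellRecording(
        well_id=str(well_ids[0]), duration_s=duration_s, trains=trains, metadata=metadata
    )


def save_raw_traces(traces, path: str | Path) -> None:
    """One HDF5 dataset per channel; sampling rate stored as an attribute."""
    with h5py.File(path, "w") as f:
        for tr in traces:
            ds = f.create_dataset(tr.channel_id, data=tr.samples)
            ds.attrs["sampling_rate_hz"] = tr.sampling_rate_hz


def load_raw_traces(path: str | Path):
    from .types import RawTrace

    out = []
    with h5py.File(path, "r") as f:
        for ch in sorted(f):
            out.append(
                RawTrace(
                    channel_id=ch,
                    samples=f[ch][...],
                    sampling_rate_hz=float(f[ch].attrs["sampling_rate_hz"]),
                )
            )
    return out


def bursts_table(well_id: str, bursts_by_channel: dict[str, list[Burst]]) -> pd.DataFrame:
    rows = [
        {
            "well_id": well_id,
            "channel_id": ch,
            "start_s": b.start_s,
            "end_s": b.end_s,
            "n_spikes": b.n_spikes,
        }
        for ch, bs in bursts_by_channel.items()
        for b in bs
    ]
    return pd.DataFrame(rows, columns=["well_id", "channel_id", "start_s", "end_s", "n_spikes"])


def network_bursts_table(well_id: str, network_bursts: list[NetworkBurst]) -> pd.DataFrame:
    rows = [
        {
            "well_id": well_id,
            "start_s": nb.start_s,
            "end_s": nb.end_s,
            "n_channels": len(nb.participating_channels),
            "n_spikes": nb.n_spikes,
        }
        for nb in network_bursts
    ]
    return pd.DataFrame(
        rows, columns=["well_id", "start_s", "end_s", "n_channels", "n_spikes"]
    )


def features_table(features: list[WellFeatures]) -> pd.DataFrame:
    """Tidy feature table: one row per well with the nine parameters + metadata."""
    return pd.DataFrame([f.as_dict() for f in features])


def load_config(path: str | Path) -> dict:
    """Load a flat YAML run configuration."""
    with open(path) as f:
        cfg = yaml.safe_load(f) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: str | Path, parameters: dict, inputs: list[str | Path], outputs: list[str]) -> None:
    from . import __version__

    manifest = {
        "package": "meanet",
        "version": __version__,
        "parameters": parameters,
        "inputs": {str(p): sha256_of(p) for p in inputs if Path(p).exists()},
        "outputs": outputs,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
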