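"""Well inclusion/exclusion rules applied before any group analysis.

A well is kept only when, over its recorded development (days in vitro,
DIV), it is active, fires on enough channels, shows network bursts by
DIV 28 and across enough channels, and does not lose firing rate over
development. Control wells additionally need an MFR of at least 1 Hz.
Each rule is evaluated independently and every violated rule is reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .bursts import active_channels
from .types import Burst, BurstParams, NetworkBurst, QCResult, WellRecording

__all__ = ["CRITERIA", "WellDivSummary", "summarize_for_qc", "evaluate_well", "qc_report"]

logger = logging.getLogger(__name__)

#: criterion codes, in the order the rules are stated
CRITERIA = (
    "INACTIVE",            # fewer than 3 channels with MFR > 0.1 Hz
    "CONTROL_LOW_MFR",     # control well with MFR < 1 Hz
    "FEW_SPIKING_CHANNELS",  # < 80% of channels detected spikes
    "NO_NB_AT_DIV28",      # no network bursts at DIV 28
    "NB_FEW_CHANNELS",     # network bursts detected in < 80% of channels
    "MFR_DECREASING",      # well MFR decreased over development
)

MIN_ACTIVE_CHANNELS = 3
CONTROL_MIN_MFR_HZ = 1.0
MIN_SPIKING_CHANNEL_FRACTION = 0.8
MIN_NB_CHANNEL_FRACTION = 0.8


@dataclass(frozen=True)
class WellDivSummary:
    """Per-DIV quantities the exclusion rules consume."""

    well_id: str
    div: int
    mfr_hz: float
    n_channels: int
    n_active_channels: int
    n_spiking_channels: int
    n_network_bursts: int
    n_channels_with_nb: int


def summarize_for_qc(
    well: WellRecording,
    bursts_by_channel: dict[str, list[Burst]],
    network_bursts: list[NetworkBurst],
    params: BurstParams | None = None,
    div: int | None = None,
) -> WellDivSummary:
    """Build the per-DIV summary for one well from its detection output."""
    params = params or BurstParams()
    mfr = float(
        np.mean([len(t) / well.duration_s for t in well.trains.values()])
    )
    with_nb = set()
    for nb in network_bursts:
        with_nb |= set(nb.participating_channels)
    return WellDivSummary(
        well_id=well.well_id,
        div=int(div if div is not None else well.metadata.get("div", -1)),
        mfr_hz=mfr,
        n_channels=well.n_channels,
        n_active_channels=len(active_channels(well, params)),
        n_spiking_channels=sum(1 for t in well.trains.values() if len(t) > 0),
        n_network_bursts=len(network_bursts),
        n_channels_with_nb=len(with_nb),
    )


def evaluate_well(
    summaries: Sequence[WellDivSummary],
    role: str = "treated",
) -> QCResult:
    """Apply all exclusion rules to one well's development series.

    Parameters
    ----------
    summaries:
        One :class:`WellDivSummary` per recorded DIV of the well.
    role:
        ``"control"`` or ``"treated"``; the 1-Hz minimum-MFR rule applies
        to control wells only, exactly as stated.

    Notes
    -----
    Per-DIV rules (activity, spiking-channel fraction, control MFR,
    network-burst channel fraction) flag the well when violated at *any*
    recorded DIV. The network-burst channel fraction is only assessed at
    DIVs that have at least one network burst, so a silent early DIV is
    not double-counted. The firing-rate-over-development rule compares the
    last recorded DIV against the first. When DIV 28 was not recorded, the
    DIV-28 network-burst rule is not assessable and is logged, not counted
    as a violation.
    """
    if role not in ("control", "treated"):
        raise ValueError("role must be 'control' or 'treated'")
    rows = sorted(summaries, key=lambda s: s.div)
    if not rows:
        raise ValueError("evaluate_well needs at least one per-DIV summary")
    well_id = rows[0].well_id
    violated: list[str] = []
    notes: list[str] = []

    if any(s.n_active_channels < MIN_ACTIVE_CHANNELS for s in rows):
        violated.append("INACTIVE")
    if role == "control" and any(s.mfr_hz < CONTROL_MIN_MFR_HZ for s in rows):
        violated.append("CONTROL_LOW_MFR")
    if any(
        s.n_spiking_channels < MIN_SPIKING_CHANNEL_FRACTION * s.n_channels
        for s in rows
    ):
        violated.append("FEW_SPIKING_CHANNELS")

    at_28 = [s for s in rows if s.div == 28]
    if at_28:
        if all(s.n_network_bursts == 0 for s in at_28):
            violated.append("NO_NB_AT_DIV28")
    else:
        msg = f"well {well_id}: DIV 28 not recorded; NO_NB_AT_DIV28 not assessable"
        logger.info(msg)
        notes.append(msg)

    if any(
        s.n_network_bursts > 0
        and s.n_channels_with_nb < MIN_NB_CHANNEL_FRACTION * s.n_channels
        for s in rows
    ):
        violated.append("NB_FEW_CHANNELS")

    if len(rows) >= 2 and rows[-1].mfr_hz < rows[0].mfr_hz:
        violated.append("MFR_DECREASING")

    return QCResult(
        well_id=well_id,
        included=not violated,
        violated=tuple(violated),
        notes=tuple(notes),
    )


def qc_report(results: Iterable[QCResult]) -> pd.DataFrame:
    """Tidy QC table: one row per well with the violated criterion codes."""
    return pd.DataFrame(
        [
            {
                "well_id": r.well_id,
                "included": r.included,
                "violated": ";".join(r.violated),
                "notes": ";".join(r.notes),
            }
            for r in results
        ]
    )
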