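"""Postsynaptic-current event classification and the cell-adhesion ratio.

Spontaneous postsynaptic currents (sPSCs) recorded in whole-cell patch
clamp mix fast glutamatergic and slow GABAergic events. Because the two
receptor families differ in channel kinetics, a single decay-time cutoff
separates them to high confidence; the default cutoff is 3.8 ms, with
events decaying at or below the cutoff called glutamatergic and slower
events called GABAergic.
"""

from __future__ import annotations

import logging
import math

import pandas as pd

__all__ = ["classify_psc", "aggregation_ratio", "DEFAULT_CUTOFF_MS"]

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF_MS = 3.8


def classify_psc(
    events: pd.DataFrame, cutoff_ms: float = DEFAULT_CUTOFF_MS
) -> tuple[pd.DataFrame, dict]:
    """Label PSC events by decay time and tally per-class counts.

    Events with ``decay_ms <= cutoff_ms`` are labeled ``glutamatergic``,
    slower events ``GABAergic`` (an event exactly at the cutoff goes to
    the fast class). Events with non-positive decay are dropped with a log
    entry.

    Returns the labeled table (``assigned_class`` column added) and a
    summary dict with counts and fractions; fractions are NaN when no
    event survives.
    """
    if cutoff_ms <= 0:
        raise ValueError("cutoff_ms must be positive")
    if "decay_ms" not in events.columns:
        raise ValueError("events table needs a 'decay_ms' column")
    valid = events["decay_ms"] > 0
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.warning("dropping %d events with non-positive decay time", n_dropped)
    out = events.loc[valid].copy()
    out["assigned_class"] = (out["decay_ms"] <= cutoff_ms).map(
        {True: "glutamatergic", False: "GABAergic"}
    )
    n_glu = int((out["assigned_class"] == "glutamatergic").sum())
    n_gaba = int((out["assigned_class"] == "GABAergic").sum())
    n = n_glu + n_gaba
    summary = {
        "n_glutamatergic": n_glu,
        "n_GABAergic": n_gaba,
        "n_dropped": n_dropped,
        "fraction_glutamatergic": n_glu / n if n else math.nan,
        "fraction_GABAergic": n_gaba / n if n else math.nan,
    }
    return out, summary


def aggregation_ratio(particles_t0: float, particles_t60: float) -> float:
    """Cell-adhesion aggregation ratio: particle count after vs before incubation.

    ``particles_t60 / particles_t0`` — aggregating cells merge into fewer
    particles, so values well below 1 indicate strong adhesion and values
    near 1 indicate none.
    """
    if particles_t0 <= 0:
        raise ValueError("particles_t0 must be positive")
    if particles_t60 < 0:
        raise ValueError("particles_t60 must be non-negative")
    return particles_t60 / particles_t0
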