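# meanet

Network-activity analysis for multi-well micro-electrode array (MEA)
recordings of neuronal cultures, built for studying excitation/inhibition
(E/I) balance in excitatory/inhibitory co-cultures (e.g. human
iPSC-derived glutamatergic + GABAergic networks).

MEA wells record spontaneous spiking on ~12 extracellular electrodes.
Mature cultures organize this activity into *bursts* (high-frequency
spike runs on one electrode) and *network bursts* (epochs of coincident
bursting across the well), and the statistics of these events are the
readout through which inhibitory modulation — cell ratio, genetic
perturbation, pharmacology — is quantified. `meanet` implements the full
chain from raw trace to group-level statistics:

- **Spike detection** — 2nd-order 100-Hz high-pass + 4th-order 3500-Hz
  low-pass Butterworth filtering, spikes at local extrema beyond ±4.5
  robust noise SDs.
- **Burst detection** — maximal spike runs with ISI ≤ 30 ms; bursts
  < 65 ms apart merged; bursts shorter than 50 ms or with < 4 spikes
  removed (in that order).
- **Network-burst detection** — sweep-line coincidence: a network burst
  wherever strictly more than 80% of the active channels (MFR > 0.1 Hz)
  are simultaneously bursting; the window is the union of the
  contributing bursts.
- **Nine network parameters** per well: MFR, PRS (% random spikes),
  single-channel burst rate / duration / in-burst firing rate / IBI,
  NBR, NBD, network IBI.
- **Well QC** — six independent inclusion rules (activity, control MFR,
  spiking-channel fraction, network bursts at DIV 28 and across
  channels, non-decreasing MFR over development).
- **Burst shapes** — aligned, binned spike-count profiles with per-bin
  two-sample t-tests under Holm–Šidák step-down correction.
- **Canonical discriminant analysis** — `B a = λ W a` over the nine
  parameters, with canonical correlations, group centroids and the
  pooled within-group structure matrix that ranks which parameters drive
  group separation.
- **PSC classification** — glutamatergic vs GABAergic postsynaptic
  events split at a 3.8-ms decay-time cutoff; plus the cell-adhesion
  aggregation ratio T60/T0.
- **Synthetic data** — a seeded point-process generator that plants
  known network bursts, spike labels, raw traces and PSC mixtures, with
  an `inhibitory_fraction` knob emulating E/I titration, so every stage
  is testable against ground truth without any recording download.

See `docs/methods.md` for the precise definitions and conventions.

## Worked example

```python
from meanet import (SyntheticNetworkSpec, ei_spec, generate_well,
                    detect_well, compute_features)

base = SyntheticNetworkSpec(n_channels=12, duration_s=600.0, seed=1)
for frac in (0.0, 0.35):
    well, gt = generate_well(ei_spec(base, frac))
    bursts, nbs = detect_well(well)
    f = compute_features(well, bursts, nbs)
    print(f"inhibitory_fraction={frac}: planted {gt.n_windows} network bursts, "
          f"detected {len(nbs)}")
    print(f"  MFR {f.mfr_hz:.2f} Hz | PRS {f.prs_pct:.1f} % | "
          f"NBR {f.nbr_per_min:.2f}/min | NBD {f.nbd_ms:.0f} ms")
```

prints

```
inhibitory_fraction=0.0: planted 36 network bursts, detected 36
  MFR 10.66 Hz | PRS 2.5 % | NBR 3.60/min | NBD 1191 ms
inhibitory_fraction=0.35: planted 40 network bursts, detected 40
  MFR 1.95 Hz | PRS 39.5 % | NBR 4.00/min | NBD 321 ms
```

Every planted network burst is recovered in both wells. Moving the
inhibition knob from 0 to 0.35 shortens the network bursts (NBD 1191 →
321 ms), lowers the overall firing rate (10.66 → 1.95 Hz) and pushes a
large fraction of spikes out of bursts into random activity (PRS 2.5 →
39.5%) — the signature of functional inhibitory control in an E/I
network.

A command-line interface wraps the same stages:

```bash
meanet simulate --out well.csv --seed 1 --inhibitory-fraction 0.35
meanet all well.csv --out results/
```

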