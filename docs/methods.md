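# Methods

`meanet` analyzes spontaneous network activity of neuronal cultures —
typically excitatory/inhibitory (E/I) co-cultures of human iPSC-derived
neurons — recorded on multi-well micro-electrode arrays (MEAs). This note
documents the models and procedures the package implements, the choices
made where conventions are genuinely open, and what the synthetic-data
generator does and does not emulate.

## Spike detection from raw traces

Raw extracellular signals (10 kHz by default) are band-limited with a
2nd-order Butterworth high-pass at 100 Hz followed by a 4th-order
Butterworth low-pass at 3500 Hz. Filtering is applied forward–backward
(`sosfiltfilt`), so the effective magnitude response is the square of the
single-pass response and the phase is zero: spike timestamps are not
shifted by group delay. This is a deliberate choice — acquisition systems
filter causally, but zero-phase filtering keeps detected spike times
aligned with the underlying waveform, which matters when detections are
compared against planted ground truth at millisecond tolerance.

Spikes are detected at local extrema of the rectified filtered signal
exceeding ±4.5 noise standard deviations. The noise SD is estimated
robustly as `median(|x|)/0.6745`, which is insensitive to the spikes
themselves (a plain SD is inflated by them, raising the threshold and
losing events). Events closer together than a 1-ms dead time (a standard
refractory assumption; configurable) are collapsed to the larger
extremum. The threshold is applied to the whole recording, not a sliding
window; spike times are reported at the extremum sample because the
extremum is more jitter-stable than the threshold-crossing instant.

## Burst and network-burst detection

The single-channel burst detector applies three stages in fixed order:

1. **Detect** — maximal runs of spikes with every inter-spike interval
   (ISI) ≤ 30 ms, spanning first to last spike. The boundary ISI of
   exactly 30 ms continues the burst (the inclusive reading of an
   otherwise ambiguous boundary; documented, deterministic).
2. **Merge** — consecutive candidates whose gap (end-to-next-start) is
   < 65 ms are merged transitively. Merging precedes filtering so merged
   bursts can survive the next stage.
3. **Filter** — candidates shorter than 50 ms *or* with fewer than 4
   spikes are discarded.

A channel is *active* when its mean firing rate strictly exceeds 0.1 Hz.
A **network burst** is a maximal epoch during which strictly more than
80% of the active channels are simultaneously inside a burst.
Simultaneity is evaluated instantaneously with a sweep line over burst
start/end events (half-open intervals; ends processed before coincident
starts), avoiding any bin-width parameter. The network-burst *window* is
the union of all single-channel bursts intersecting the supra-threshold
seed interval; overlapping windows are merged. The union is the most
inclusive defensible definition of the window extent — network-burst
duration (NBD) is a headline metric and the union captures the full
epoch of coordinated activity; the bare seed interval is available via
`window="seed"`. The inter-burst merge gap is measured end-to-start.

## The nine network parameters

Per well: mean firing rate (MFR, spikes/s averaged over all electrodes,
silent ones included); percentage of random spikes (PRS, spikes in
neither a burst on their own channel nor any network-burst window —
the inclusive reading; an own-channel-burst-only variant is available via
`prs_scope`); single-channel burst rate (/min), mean burst duration (ms),
firing rate within bursts (Hz) and mean inter-burst interval (IBI, s;
end-to-next-start), each averaged over channels with at least one burst;
network-burst rate (NBR, /min); mean NBD (ms; window duration, not the
mean of per-channel burst durations inside it); and mean network IBI (s).
Wells with no network bursts report NBR = 0 and NBD/NIBI as missing
(NaN), not zero, so group averages are not dragged toward zero; wells
with no spikes report everything missing.

## Burst shapes and per-bin comparison

Each network burst is aligned at its window start and all channels'
spikes are binned at 10 ms (configurable; the shape is robust to the
choice over 5–50 ms) out to the longest window, giving a bursts × bins
count matrix and its per-bin mean profile. Two groups of per-well mean
profiles are compared bin-wise with two-sample t-tests corrected by the
Holm–Šidák step-down procedure: order the m p-values ascending and call
step i significant iff p(i) ≤ 1 − (1 − α)^(1/(m − i + 1)) and all
earlier steps were significant. The final-step threshold is computed as
exactly α (the algebraic value of the formula at m − i + 1 = 1), not via
the float expression `1 − (1 − α)**1`, whose rounding residue would
break the single-bin case. Degenerate bins with zero variance in both
groups yield NaN p-values and are treated as never significant.

## Quality control

Before group analysis each well's development series (one record per
recorded day in vitro, DIV) passes six independent rules; all violations
are reported, and inclusion means none fired: (1) ≥ 3 channels active
(MFR > 0.1 Hz); (2) control wells only: MFR ≥ 1 Hz; (3) spikes on ≥ 80%
of channels; (4) network bursts present at DIV 28; (5) network bursts on
≥ 80% of channels; (6) MFR not lower at the last recorded DIV than at
the first. Per-DIV rules exclude on violation at any recorded DIV; rule
(5) is only assessed at DIVs that have at least one network burst so a
silent early DIV is not double-counted; rule (4) is *not assessable*
(logged, not a violation) when DIV 28 was never recorded. Rule (6) uses
the last-vs-first comparison; a regression-slope variant would be more
powerful but introduces a model where the stated rule has none.

## Canonical discriminant analysis

For g groups over p = 9 parameters the analysis solves the generalized
eigenproblem `B a = λ W a` (B between-group, W pooled within-group
scatter), yielding min(g − 1, p) canonical functions. Coefficients are
scaled so scores have unit pooled within-group variance; scores are
centered on the grand centroid; the canonical correlation per function
is √(λ/(1+λ)). The **structure matrix** — the pooled within-group
correlation of each variable with each canonical score — is the quantity
used to rank which parameters drive group separation; with the unit
score variance scaling it is `(S_w A) / sd_w` where `S_w = W/(n−g)`.
Column signs are fixed so each function's largest-magnitude loading is
positive, making results reproducible across runs. Rows with missing
values (wells without network bursts) are dropped with a logged count
rather than imputed. A singular within-group scatter (collinear
variables, or fewer than p within-group degrees of freedom) raises an
error that names the remedy; a ridge `regularization` flag is available.
The analysis is descriptive — no priors, no classification step. Score
plots draw per-group covariance concentration ellipses centered on the
group centroids.

## PSC classification and the aggregation ratio

Spontaneous postsynaptic currents are classified by decay time with a
3.8-ms cutoff: decay ≤ cutoff → glutamatergic, decay > cutoff →
GABAergic. The boundary goes to the fast class — the convention must be
fixed somewhere, and AMPA-receptor kinetics put 3.8 ms at the slow edge
of the fast population. The decay metric is understood as the fitted
single-exponential time constant τ. Non-positive decays are dropped and
counted. The cell-adhesion aggregation ratio is `particles_t60 /
particles_t0`: aggregating cells merge into fewer particles, so values
well below 1 mean strong adhesion (≈ 0.58 for a strong homophilic binder
such as CDH2) and values near 1 mean none (≈ 0.94 for an inert control).

## The synthetic-data generator

The generator is a point-process emulator, not a biophysical model. Per
well it draws network-burst windows from a renewal process (exponential
gaps at `nb_rate_per_min`, gamma durations with mean `nb_duration_ms`
and CV `nb_duration_cv`), recruits each channel into each window with
probability `participation_frac`, shifts each recruited channel's window
by Gaussian onset jitter (SD `onset_jitter_ms`), and superimposes
homogeneous Poisson spiking: `in_burst_rate_hz` inside the (jittered)
window and `tonic_rate_hz` throughout. Raw traces are i.i.d. Gaussian
noise plus a biphasic template at each spike time; PSC streams are
two-population truncated-normal decay mixtures with true labels.

Defaults describe a mature, strongly bursting culture on a 12-electrode
well recorded for 600 s: 4 network bursts/min, 1200-ms bursts at 150 Hz
per channel, 0.3 Hz tonic background, 10-ms onset jitter, duration
CV 0.2. The `inhibitory_fraction` knob (0–0.35, the plating range of
interest) maps linearly to NBD 1200 → 300 ms, in-burst rate 150 → 60 Hz
and tonic rate 0.3 → 0.8 Hz — the direction and rough magnitude of the
effect of titrating GABAergic neurons into an excitatory network
(shorter, weaker network bursts; more desynchronized spiking).
Regenerating a well with the knob forced to 0 emulates acute
pharmacological disinhibition.

Reproducibility: a single seed feeds a splittable RNG
(`SeedSequence.spawn`); the window process and every channel own
independent child streams, so adding channels leaves existing spike
trains bit-identical. Specs whose mean inter-burst gap
(60/`nb_rate_per_min` − mean duration) falls below 200 ms are rejected:
their planted windows could be fused by the 65-ms merge rule and the
ground truth would stop being identifiable.

Ground-truth windows record the realized envelope over the recruited
channels' jittered intervals, so every in-burst spike lies inside its
recorded window by construction.

**What the generator does not emulate** — and hence what passing tests
do not show about real recordings: within-burst rate profiles are flat
(real bursts typically decay after an initial peak; the mean-shape
machinery does not assume either), there is no reverberation or
sub-network structure, no inter-channel correlation beyond shared
windows, no electrode noise heterogeneity, no development over DIVs, and
channel recruitment is independent rather than spatially structured.
Recovery results therefore certify the detectors' correctness under the
stated point-process model, not their behavior under every biological
waveform.

## Problem sizes and numerical choices

The validation suite uses 600-s, 12-channel wells for planted-parameter
recovery (5–10 seeds), 300-s wells over inhibitory fractions
{0, 0.05, 0.25, 0.35} (10 seeds) for the titration trends, 60–120 s of
10-kHz trace for spike detection, and 10,000 events per class for PSC
classification — sizes at which the planted quantities are estimated
well inside the asserted tolerances. Times are float64 seconds
throughout; durations are reported in ms in feature tables. Burst
boundary comparisons use plain floating-point inequalities (the
brute-force oracle applies the identical comparisons, so equivalence is
exact). Spike tables round-trip through CSV losslessly (17 significant
digits out, correctly rounded parsing in).
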