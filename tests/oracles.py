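"""Independent brute-force oracles used to validate the pipeline.

These deliberately re-derive each rule in the most literal way possible
(explicit loops, repeated passes to a fixed point, dense linear algebra)
and share no code with the implementation under test.
"""

from __future__ import annotations

import numpy as np


def brute_force_bursts(
    times_s,
    max_isi_ms: float = 30.0,
    merge_gap_ms: float = 65.0,
    min_duration_ms: float = 50.0,
    min_spikes: int = 4,
):
    """Literal detect -> merge -> filter burst rule on one spike train.

    Returns a list of (start_s, end_s, n_spikes) tuples.
    """
    t = list(times_s)
    max_isi = max_isi_ms / 1000.0
    gap = merge_gap_ms / 1000.0
    min_dur = min_duration_ms / 1000.0

    # stage 1: walk the train, extending a run while the next ISI <= max_isi
    runs = []
    i = 0
    while i < len(t):
        j = i
        while j + 1 < len(t) and t[j + 1] - t[j] <= max_isi:
            j += 1
        runs.append((t[i], t[j], j - i + 1))
        i = j + 1

    # stage 2: merge to a fixed point
    changed = True
    while changed:
        changed = False
        out = []
        for start, end, n in runs:
            if out and start - out[-1][1] < gap:
                prev = out[-1]
                out[-1] = (prev[0], end, prev[2] + n)
                changed = True
            else:
                out.append((start, end, n))
        runs = out

    # stage 3: remove short or sparse bursts
    return [
        (s, e, n) for s, e, n in runs if (e - s) >= min_dur and n >= min_spikes
    ]


def holm_sidak_bruteforce(p_values, alpha: float = 0.05):
    """Literal step-down Holm-Sidak procedure; returns boolean flags."""
    p = [1.0 if np.isnan(v) else float(v) for v in p_values]
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    flags = [False] * m
    for rank, idx in enumerate(order, start=1):
        remaining = m - rank + 1
        threshold = alpha if remaining == 1 else 1.0 - (1.0 - alpha) ** (1.0 / remaining)
        if p[idx] <= threshold:
            flags[idx] = True
        else:
            break  # step-down: once one fails, all later fail
    return np.array(flags)


def cda_oracle(X, labels):
    """Dense eigen-solve canonical discriminant oracle.

    Builds the within/between scatter matrices explicitly and solves the
    non-symmetric eigenproblem of W^{-1} B directly. Returns descending
    eigenvalues, canonical correlations, and the structure matrix with
    column signs fixed so the largest-magnitude entry is positive.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    groups = list(dict.fromkeys(y.tolist()))
    n, p = X.shape
    g = len(groups)
    grand = X.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for gr in groups:
        Xg = X[y == gr]
        mg = Xg.mean(axis=0)
        for row in Xg:
            d = (row - mg)[:, None]
            W += d @ d.T
        d = (mg - grand)[:, None]
        B += len(Xg) * (d @ d.T)
    evals, evecs = np.linalg.eig(np.linalg.solve(W, B))
    order = np.argsort(evals.real)[::-1]
    k = min(g - 1, p)
    evals = np.clip(evals.real[order][:k], 0.0, None)
    A = evecs.real[:, order][:, :k]
    S_w = W / (n - g)
    for j in range(k):
        A[:, j] /= np.sqrt(A[:, j] @ S_w @ A[:, j])
    structure = (S_w @ A) / np.sqrt(np.diag(S_w))[:, None]
    for j in range(k):
        i = int(np.argmax(np.abs(structure[:, j])))
        if structure[i, j] < 0:
            structure[:, j] *= -1
            A[:, j] *= -1
    corr = np.sqrt(evals / (1.0 + evals))
    return evals, corr, structure


def butterworth_gain(f_hz, order: int, cutoff_hz: float, kind: str) -> float:
    """Closed-form single-pass Butterworth magnitude response."""
    r = (f_hz / cutoff_hz) ** (2 * order)
    if kind == "lowpass":
        return 1.0 / np.sqrt(1.0 + r)
    if kind == "highpass":
        return np.sqrt(r / (1.0 + r))
    raise ValueError(kind)


def rice_rate(sos_list, fs_hz: float, threshold_sd: float, n_freq: int = 4096) -> float:
    """Rice level-crossing rate (events/s, both polarities) for Gaussian noise
    passed twice (zero-phase) through the given filter cascade.

    Spectral moments are computed from the cascade's power response; the
    forward-backward application squares the amplitude response, so the
    noise PSD is multiplied by |H|^4.
    """
    from scipy import signal as sps

    f = np.linspace(0.0, fs_hz / 2.0, n_freq)
    h_total = np.ones_like(f, dtype=complex)
    for sos in sos_list:
        _, h = sps.sosfreqz(sos, worN=f, fs=fs_hz)
        h_total *= h
    psd = np.abs(h_total) ** 4  # filtfilt: amplitude response |H|^2
    m0 = np.trapezoid(psd, f)
    m2 = np.trapezoid((2 * np.pi * f) ** 2 * psd, f)
    nu0 = np.sqrt(m2 / m0) / (2 * np.pi)  # zero-upcrossing rate
    # upcrossings of +u plus downcrossings of -u on |x|
    return 2.0 * nu0 * np.exp(-(threshold_sd**2) / 2.0)
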