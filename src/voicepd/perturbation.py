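"""Linear dysphonia measures: pitch statistics, jitter, shimmer, HNR/NHR.

Jitter and shimmer follow the standard perturbation-quotient conventions
(Praat/MDVP): mean absolute cycle-to-cycle difference normalized by the
mean, and K-point perturbation quotients against a centered moving mean.
All standard deviations are population (divisor N). HNR is derived from
the normalized autocorrelation value at the pitch lag,
HNR = 10 log10(r / (1 - r)), the classic periodicity-to-noise split.
"""

from __future__ import annotations

import numpy as np

from voicepd.pitch import PitchTrack

HNR_DB_MIN, HNR_DB_MAX = -20.0, 40.0
_R_CLIP = 1e-4


def f0_statistics(track: PitchTrack) -> tuple[float, float, float, float, float]:
    """(mean, max, min, median, population std) of voiced-frame F0."""
    f0 = track.voiced_f0
    if f0.size == 0:
        raise ValueError("pitch track has no voiced frames")
    return (
        float(np.mean(f0)),
        float(np.max(f0)),
        float(np.min(f0)),
        float(np.median(f0)),
        float(np.std(f0)),
    )


def _pq(values: np.ndarray, k: int) -> float:
    """K-point perturbation quotient (percent): mean absolute deviation of
    each value from its centered K-point mean, over the overall mean."""
    n = len(values)
    if n < k:
        raise ValueError(f"need >= {k} values for the {k}-point quotient, got {n}")
    half = k // 2
    windows = np.lib.stride_tricks.sliding_window_view(values, k)
    centered = values[half : n - half]
    dev = np.abs(centered - windows.mean(axis=1))
    return float(dev.mean() / values.mean() * 100.0)


def jitter_measures(periods) -> tuple[float, float, float, float, float]:
    """(jitter_pct, jitter_abs_seconds, ppq5, rap, ddp) from cycle periods."""
    T = np.asarray(periods, dtype=np.float64)
    if len(T) < 2:
        raise ValueError("jitter needs >= 2 periods")
    if np.any(T <= 0):
        raise ValueError("periods must be positive")
    mean_t = T.mean()
    abs_diff = np.abs(np.diff(T))
    jitter_abs = float(abs_diff.mean())
    jitter_pct = float(jitter_abs / mean_t * 100.0)
    if len(T) < 3:
        raise ValueError("rap/ddp need >= 3 periods")
    rap = _pq(T, 3)
    ddp = float(np.abs(np.diff(T, n=2)).mean() / mean_t * 100.0)
    if len(T) < 5:
        raise ValueError("ppq5 needs >= 5 periods")
    ppq5 = _pq(T, 5)
    return (jitter_pct, jitter_abs, ppq5, rap, ddp)


def shimmer_measures(amplitudes) -> tuple[float, float, float, float, float, float]:
    """(shimmer_pct, shimmer_db, apq3, apq5, apq11, dda) from cycle amplitudes."""
    A = np.asarray(amplitudes, dtype=np.float64)
    if np.any(A <= 0):
        raise ValueError("amplitudes must be positive")
    if len(A) < 2:
        raise ValueError("shimmer needs >= 2 amplitudes")
    shim_pct = float(np.abs(np.diff(A)).mean() / A.mean() * 100.0)
    shim_db = float(np.abs(20.0 * np.log10(A[1:] / A[:-1])).mean())
    if len(A) < 3:
        raise ValueError("apq3 needs >= 3 amplitudes")
    apq3 = _pq(A, 3)
    dda = 3.0 * apq3
    if len(A) < 5:
        raise ValueError("apq5 needs >= 5 amplitudes")
    apq5 = _pq(A, 5)
    if len(A) < 11:
        raise ValueError("apq11 needs >= 11 amplitudes")
    apq11 = _pq(A, 11)
    return (shim_pct, shim_db, apq3, apq5, apq11, dda)


def harmonicity(track: PitchTrack) -> tuple[float, float, float, float]:
    """(hnr_mean, hnr_std, nhr_mean, nhr_std) over voiced frames.

    Uses the normalized autocorrelation value at the pitch lag stored per
    voiced frame; the value is clipped away from 0 and 1 so that noiseless
    synthetic input yields the dB cap rather than an infinity.
    """
    r = track.peak[track.voiced]
    if r.size == 0:
        raise ValueError("pitch track has no voiced frames")
    r = np.clip(r, _R_CLIP, 1.0 - _R_CLIP)
    hnr = np.clip(10.0 * np.log10(r / (1.0 - r)), HNR_DB_MIN, HNR_DB_MAX)
    nhr = (1.0 - r) / r
    return (
        float(hnr.mean()),
        float(hnr.std()),
        float(nhr.mean()),
        float(nhr.std()),
    )
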