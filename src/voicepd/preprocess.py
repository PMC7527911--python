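"""Pre-emphasis, framing, short-time energy, and double-threshold endpoint detection.

The voiced part of a recording must contain a stretch of frames whose
short-time energy exceeds an upper threshold T_h; its endpoints are then
pushed outward to where the energy falls below a lower threshold T_l.
Both thresholds are defined relative to the maximum frame energy, which
makes the detector invariant to recording gain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from voicepd.audio_io import AudioSignal

_WINDOWS = ("hamming", "rectangular")


@dataclass
class FrameParams:
    frame_ms: float = 25.0
    shift_ms: float = 10.0
    window: str = "hamming"

    def __post_init__(self) -> None:
        if self.frame_ms <= 0:
            raise ValueError("frame_ms must be positive")
        if not 0 < self.shift_ms <= self.frame_ms:
            raise ValueError("shift_ms must satisfy 0 < shift_ms <= frame_ms")
        if self.window not in _WINDOWS:
            raise ValueError(f"window must be one of {_WINDOWS}")

    def frame_samples(self, rate: int) -> int:
        return int(round(self.frame_ms * rate / 1000.0))

    def shift_samples(self, rate: int) -> int:
        return int(round(self.shift_ms * rate / 1000.0))


@dataclass
class FrameSet:
    frames: np.ndarray  # (n_frames, frame_len), window already applied
    params: FrameParams
    rate: int
    start_indices: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class EnergyEnvelope:
    energies: np.ndarray
    params: FrameParams
    rate: int
    start_indices: np.ndarray
    frame_len: int


@dataclass
class VadParams:
    """Double-threshold parameters, as fractions of the maximum frame energy."""

    high_frac: float = 0.25
    low_frac: float = 0.05
    min_voiced_ms: float = 100.0

    def __post_init__(self) -> None:
        if not 0 < self.low_frac < self.high_frac < 1:
            raise ValueError("need 0 < low_frac < high_frac < 1")
        if self.min_voiced_ms < 0:
            raise ValueError("min_voiced_ms must be non-negative")


@dataclass
class VoicedInterval:
    start_frame: int
    end_frame: int  # inclusive
    start_sample: int
    end_sample: int  # inclusive

    def __post_init__(self) -> None:
        if self.start_frame > self.end_frame or self.start_sample > self.end_sample:
            raise ValueError("interval start must not exceed end")


def pre_emphasize(signal: AudioSignal, a: float = 0.9375) -> AudioSignal:
    """First-order high-pass y(n) = x(n) - a*x(n-1), y(0) = x(0)."""
    if not 0 < a < 1:
        raise ValueError(f"pre-emphasis coefficient must lie in (0, 1), got {a}")
    if len(signal) == 0:
        raise ValueError("cannot pre-emphasize an empty signal")
    x = signal.samples
    y = np.empty_like(x)
    y[0] = x[0]
    y[1:] = x[1:] - a * x[:-1]
    return AudioSignal(y, signal.rate, signal.source)


def window_function(name: str, length: int) -> np.ndarray:
    if name == "hamming":
        # symmetric form, denominator N-1
        return np.hamming(length)
    return np.ones(length)


def frame_signal(signal: AudioSignal, params: FrameParams | None = None) -> FrameSet:
    """Split into overlapping windowed frames; trailing partial frame dropped."""
    params = params or FrameParams()
    L = params.frame_samples(signal.rate)
    S = params.shift_samples(signal.rate)
    N = len(signal)
    if N < L:
        raise ValueError(f"signal ({N} samples) shorter than one frame ({L})")
    n_frames = (N - L) // S + 1
    starts = np.arange(n_frames) * S
    idx = starts[:, None] + np.arange(L)[None, :]
    frames = signal.samples[idx] * window_function(params.window, L)[None, :]
    return FrameSet(frames=frames, params=params, rate=signal.rate, start_indices=starts)


def short_time_energy(frames: FrameSet) -> EnergyEnvelope:
    """Per-frame energy: sum of squared windowed samples."""
    if frames.n_frames == 0:
        raise ValueError("empty frame set")
    energies = np.sum(frames.frames**2, axis=1)
    return EnergyEnvelope(
        energies=energies,
        params=frames.params,
        rate=frames.rate,
        start_indices=frames.start_indices,
        frame_len=frames.frames.shape[1],
    )


def detect_voiced(env: EnergyEnvelope, params: VadParams | None = None) -> list[VoicedInterval]:
    """Double-threshold voice endpoint detection on a short-time energy envelope.

    A voiced interval must contain at least one frame with energy above
    ``T_h = high_frac * max(E)``; it is then extended in both directions
    while energy stays at or above ``T_l = low_frac * max(E)``. Overlapping
    extended runs merge; intervals shorter than ``min_voiced_ms`` are
    discarded. Pure silence yields an empty list.
    """
    params = params or VadParams()
    E = np.asarray(env.energies, dtype=np.float64)
    if E.size == 0:
        raise ValueError("empty energy envelope")
    e_max = E.max()
    if e_max <= 0:
        return []
    t_h = params.high_frac * e_max
    t_l = params.low_frac * e_max

    above_h = E > t_h
    if not above_h.any():
        return []
    above_l = E >= t_l

    # cores: runs containing a frame above T_h, extended while E >= T_l
    raw: list[tuple[int, int]] = []
    n = len(E)
    i = 0
    while i < n:
        if above_h[i]:
            lo = i
            while lo > 0 and above_l[lo - 1]:
                lo -= 1
            hi = i
            while hi + 1 < n and above_l[hi + 1]:
                hi += 1
            raw.append((lo, hi))
            i = hi + 1
        else:
            i += 1

    # merge overlapping/adjacent extended runs
    merged: list[list[int]] = []
    for lo, hi in raw:
        if merged and lo <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])

    out: list[VoicedInterval] = []
    for lo, hi in merged:
        start_sample = int(env.start_indices[lo])
        end_sample = int(env.start_indices[hi]) + env.frame_len - 1
        dur_ms = (end_sample - start_sample + 1) / env.rate * 1000.0
        if dur_ms >= params.min_voiced_ms:
            out.append(
                VoicedInterval(
                    start_frame=lo,
                    end_frame=hi,
                    start_sample=start_sample,
                    end_sample=end_sample,
                )
            )
    return out
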