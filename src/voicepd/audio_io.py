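"""WAV reading/writing, channel selection, and rational resampling.

The pipeline analyses everything at 10 kHz mono; recordings arrive at
arbitrary rates (typically 44.1 kHz stereo from phone microphones), so the
entry point is: read, keep the left channel, normalize to [-1, 1], resample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

PIPELINE_RATE = 10_000

# full-scale divisors per integer PCM dtype
_PCM_SCALE = {
    np.dtype(np.int16): 32768.0,
    np.dtype(np.int32): 2147483648.0,
    np.dtype(np.uint8): 128.0,  # uint8 WAV is offset-binary around 128
}


@dataclass
class AudioSignal:
    """A sampled waveform with amplitudes normalized to [-1, 1]."""

    samples: np.ndarray
    rate: int
    source: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        if self.samples.ndim != 1:
            raise ValueError("AudioSignal holds a single channel (1-D array)")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate


def read_wav(path, channel_policy: str = "left") -> AudioSignal:
    """Read a RIFF/WAV file into a normalized mono :class:`AudioSignal`.

    Parameters
    ----------
    path:
        Path to a PCM (8/16/24/32-bit) or IEEE-float WAV file.
    channel_policy:
        ``"left"`` keeps channel 0 of a multi-channel file (the recording
        protocol reserves the left channel); ``"mono-mix"`` averages all
        channels. Mono files are returned unchanged under either policy.
    """
    if channel_policy not in ("left", "mono-mix"):
        raise ValueError(f"unknown channel policy {channel_policy!r}")
    import os

    if not os.path.exists(path):
        raise FileNotFoundError(f"WAV file not found: {path}")
    try:
        rate, data = wavfile.read(path)
    except ValueError as exc:
        # scipy raises ValueError both for bad RIFF headers and for
        # compressed codecs inside a valid container; distinguish them.
        msg = str(exc)
        if "understood" in msg or "format" in msg.lower():
            raise ValueError(f"unsupported WAV codec in {path}: {msg}") from exc
        raise ValueError(f"malformed RIFF/WAV header in {path}: {msg}") from exc

    data = np.atleast_1d(data)
    if data.ndim == 2:
        if channel_policy == "left":
            data = data[:, 0]
        else:
            data = data.astype(np.float64).mean(axis=1)

    if data.dtype in _PCM_SCALE:
        scale = _PCM_SCALE[data.dtype]
        if data.dtype == np.dtype(np.uint8):
            samples = (data.astype(np.float64) - 128.0) / scale
        else:
            samples = data.astype(np.float64) / scale
    else:
        samples = data.astype(np.float64)
    samples = np.clip(samples, -1.0, 1.0)
    return AudioSignal(samples, int(rate), source=str(path))


def write_wav(path, signal: AudioSignal) -> None:
    """Write an :class:`AudioSignal` as 16-bit PCM WAV."""
    # scale by full-scale 32768 (matching the read normalization) so that
    # int16 -> float -> int16 round-trips bit-exactly; +1.0 clips to 32767
    pcm = np.clip(np.round(signal.samples * 32768.0), -32768, 32767).astype(np.int16)
    wavfile.write(path, signal.rate, pcm)


def resample(signal: AudioSignal, target_rate: int = PIPELINE_RATE) -> AudioSignal:
    """Resample to ``target_rate`` with a polyphase Kaiser-windowed low-pass.

    Output length is ``round(N * target_rate / rate)``. The anti-alias filter
    cuts at the lower of the two Nyquist frequencies, so pure tones below
    half the target rate survive with their frequency intact.
    """
    if len(signal) == 0:
        raise ValueError("cannot resample an empty signal")
    if target_rate <= 0:
        raise ValueError("target rate must be positive")
    if target_rate == signal.rate:
        return AudioSignal(signal.samples.copy(), signal.rate, source=signal.source)

    frac = Fraction(int(target_rate), int(signal.rate))
    up, down = frac.numerator, frac.denominator
    out = resample_poly(signal.samples, up, down, window=("kaiser", 5.0))
    n_target = int(round(len(signal) * target_rate / signal.rate))
    if len(out) > n_target:
        out = out[:n_target]
    elif len(out) < n_target:
        out = np.pad(out, (0, n_target - len(out)))
    return AudioSignal(out, int(target_rate), source=signal.source)
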