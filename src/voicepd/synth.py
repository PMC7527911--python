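"""Seeded generators for synthetic sustained vowels and feature tables.

The vowel generator builds a harmonic source cycle by cycle: each glottal
cycle gets its own period (Gaussian relative perturbation = jitter) and
its own peak amplitude (shimmer), the phase advancing so every cycle
completes exactly one turn. Broadband Gaussian noise is added in the
voiced region at a requested harmonics-to-noise ratio, and the phonation
is flanked by silence so endpoint detection has something to find. Every
generator is a pure function of its spec and seed and returns ground
truth alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from voicepd.audio_io import AudioSignal
from voicepd.modeling import FeatureTable, UPDRS_MAX

# Feature-name vocabulary for synthetic tables (the standard sustained-vowel set)
FEATURE_VOCAB = [
    "F0_mean", "F0_max", "F0_min", "F0_median", "F0_std",
    "Jitter", "Jitter_abs", "Jitter_PPQ5", "Jitter_rap", "Jitter_ddp",
    "Shimmer", "Shimmer_dB", "Shimmer_APQ5", "Shimmer_APQ3", "Shimmer_dda",
    "Shimmer_APQ11", "HNR_mean", "HNR_std", "NHR_mean", "NHR_std",
    "DFA", "RPDE", "D2", "PPE",
]


@dataclass
class VowelSpec:
    f0: float = 150.0
    duration_s: float = 3.0
    jitter_rel_sd: float = 0.0
    shimmer_rel_sd: float = 0.0
    target_hnr_db: float | None = None
    n_harmonics: int = 5
    silence_pad_s: float = 0.5
    rate: int = 10_000
    amplitude: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 60 <= self.f0 <= 400:
            raise ValueError("f0 must lie in [60, 400] Hz")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        if self.jitter_rel_sd < 0 or self.shimmer_rel_sd < 0:
            raise ValueError("perturbation SDs must be non-negative")
        if self.n_harmonics < 1:
            raise ValueError("need at least one harmonic")


def _truncated_normal(rng: np.random.Generator, size: int) -> np.ndarray:
    """Standard normal truncated to +/-3 (keeps periods/amplitudes physical)."""
    u = rng.standard_normal(size)
    while True:
        bad = np.abs(u) > 3
        if not bad.any():
            return u
        u[bad] = rng.standard_normal(int(bad.sum()))


def synth_vowel(spec: VowelSpec) -> tuple[AudioSignal, dict]:
    """Generate a sustained vowel with controlled jitter, shimmer and HNR.

    Returns the padded signal and a ground-truth record with the realized
    cycle periods/amplitudes, voiced-region sample boundaries, the clean
    harmonic and noise components, and the realized HNR in dB.
    """
    rng = np.random.default_rng(spec.seed)
    rate = spec.rate
    t0 = 1.0 / spec.f0

    n_cycles = int(np.ceil(spec.duration_s / t0)) + 2
    periods = t0 * (1.0 + spec.jitter_rel_sd * _truncated_normal(rng, n_cycles))
    amplitudes = spec.amplitude * (
        1.0 + spec.shimmer_rel_sd * _truncated_normal(rng, n_cycles)
    )

    # one-cycle waveform shape, normalized to unit peak
    def cycle_shape(phase: np.ndarray) -> np.ndarray:
        w = np.zeros_like(phase)
        for h in range(1, spec.n_harmonics + 1):
            w += np.sin(2 * np.pi * h * phase) / h
        return w

    probe = cycle_shape(np.linspace(0, 1, 1000, endpoint=False))
    shape_peak = np.abs(probe).max()

    n_voiced = int(round(spec.duration_s * rate))
    harm = np.zeros(n_voiced)
    boundaries = np.concatenate([[0.0], np.cumsum(periods)])
    used_periods, used_amps = [], []
    for i in range(n_cycles):
        s = int(np.ceil(boundaries[i] * rate))
        e = min(int(np.ceil(boundaries[i + 1] * rate)), n_voiced)
        if s >= n_voiced:
            break
        n_samp = e - s
        if n_samp <= 0:
            continue
        t_local = (np.arange(s, e) / rate - boundaries[i]) / periods[i]
        harm[s:e] = (amplitudes[i] / shape_peak) * cycle_shape(t_local)
        if e < n_voiced:  # only complete cycles enter the ground truth
            used_periods.append(periods[i])
            used_amps.append(amplitudes[i])

    p_signal = float(np.mean(harm**2))
    if spec.target_hnr_db is not None:
        sigma = np.sqrt(p_signal / 10 ** (spec.target_hnr_db / 10.0))
        noise = sigma * rng.standard_normal(n_voiced)
    else:
        noise = np.zeros(n_voiced)
    p_noise = float(np.mean(noise**2))
    realized_hnr = 10 * np.log10(p_signal / p_noise) if p_noise > 0 else np.inf

    pad = np.zeros(int(round(spec.silence_pad_s * rate)))
    voiced = harm + noise
    peak = np.abs(voiced).max()
    if peak > 1.0:  # keep within normalized amplitude range
        voiced = voiced / peak
        harm = harm / peak
        noise = noise / peak
    samples = np.concatenate([pad, voiced, pad])

    truth = {
        "periods": np.array(used_periods),
        "amplitudes": np.array(used_amps),
        "voiced_start_sample": len(pad),
        "voiced_end_sample": len(pad) + n_voiced - 1,
        "harmonic": harm,
        "noise": noise,
        "realized_hnr_db": realized_hnr,
        "f0": spec.f0,
    }
    return AudioSignal(samples, rate, source=f"synth(f0={spec.f0})"), truth


def _feature_names(n_features: int) -> list[str]:
    names = list(FEATURE_VOCAB[:n_features])
    names += [f"feature_{i}" for i in range(len(names), n_features)]
    return names


def synth_classification_table(
    n_per_class: int = 100, n_features: int = 22, separation: float = 4.0, seed: int = 0
) -> tuple[FeatureTable, dict]:
    """Two spherical Gaussian classes separated by ``separation`` SDs along a
    random unit direction; stands in for a diagnosis feature table."""
    if n_per_class < 1 or n_features < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    direction = rng.standard_normal(n_features)
    direction /= np.linalg.norm(direction)
    X0 = rng.standard_normal((n_per_class, n_features))
    X1 = rng.standard_normal((n_per_class, n_features)) + separation * direction
    X = np.vstack([X0, X1])
    y = np.concatenate([np.zeros(n_per_class), np.ones(n_per_class)])
    perm = rng.permutation(len(y))
    table = FeatureTable(_feature_names(n_features), X[perm], y[perm])
    return table, {"direction": direction, "separation": separation}


def synth_regression_table(
    n: int = 500, n_features: int = 20, support: int = 5, noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[FeatureTable, dict]:
    """Sparse linear severity model: y = Xw + noise mapped affinely into the
    UPDRS range [0, 199]; ground truth records w and the mapping."""
    if support > n_features:
        raise ValueError("support cannot exceed n_features")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, n_features))
    w = np.zeros(n_features)
    idx = rng.choice(n_features, size=support, replace=False)
    w[idx] = rng.uniform(1.0, 3.0, size=support) * rng.choice([-1.0, 1.0], size=support)
    y_raw = X @ w + noise_sd * rng.standard_normal(n)

    lo, hi = y_raw.min(), y_raw.max()
    span = hi - lo if hi > lo else 1.0
    scale = UPDRS_MAX / span
    offset = -lo * scale
    y = y_raw * scale + offset
    table = FeatureTable(_feature_names(n_features), X, y)
    truth = {"w": w, "support": np.sort(idx), "scale": scale, "offset": offset}
    return table, truth
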