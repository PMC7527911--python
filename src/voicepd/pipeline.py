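"""End-to-end feature extraction, model persistence, diagnosis, and severity.

One recording flows: resample to 10 kHz -> pre-emphasis -> framing ->
energy-based endpoint detection -> autocorrelation pitch tracking on the
voiced regions -> wild-point removal -> glottal-cycle marking -> the 24
dysphonia features. Multiple vowels from one subject are averaged
element-wise into a single vector. Trained models persist together with
their feature-name manifest and standardization statistics and refuse to
predict on mismatched vectors.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import joblib
import numpy as np
import yaml

from voicepd.audio_io import AudioSignal, PIPELINE_RATE, read_wav, resample
from voicepd.modeling import (
    FeatureTable,
    UPDRS_MAX,
    make_classifier,
    make_regressor,
)
from voicepd.nonlinear import EmbeddingParams, correlation_dimension, dfa, ppe, rpde
from voicepd.perturbation import (
    f0_statistics,
    harmonicity,
    jitter_measures,
    shimmer_measures,
)
from voicepd.pitch import PitchParams, mark_cycles, remove_outliers, track_pitch
from voicepd.preprocess import (
    FrameParams,
    VadParams,
    detect_voiced,
    frame_signal,
    pre_emphasize,
    short_time_energy,
)
from sklearn.preprocessing import StandardScaler

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1

FEATURE_NAMES = [
    "F0_mean", "F0_max", "F0_min", "F0_median", "F0_std",
    "Jitter", "Jitter_abs", "Jitter_PPQ5", "Jitter_rap", "Jitter_ddp",
    "Shimmer", "Shimmer_dB", "Shimmer_APQ5", "Shimmer_APQ3", "Shimmer_dda",
    "Shimmer_APQ11", "HNR_mean", "HNR_std", "NHR_mean", "NHR_std",
    "DFA", "RPDE", "D2", "PPE",
]


@dataclass
class PipelineConfig:
    frame: FrameParams = field(default_factory=FrameParams)
    vad: VadParams = field(default_factory=VadParams)
    pitch: PitchParams = field(default_factory=PitchParams)
    embedding: EmbeddingParams = field(default_factory=EmbeddingParams)
    preemphasis: float = 0.9375
    channel_policy: str = "left"
    seed: int = 0

    def to_yaml(self, path) -> None:
        doc = {
            "frame": asdict(self.frame),
            "vad": asdict(self.vad),
            "pitch": asdict(self.pitch),
            "embedding": asdict(self.embedding),
            "preemphasis": self.preemphasis,
            "channel_policy": self.channel_policy,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(
            frame=FrameParams(**doc.get("frame", {})),
            vad=VadParams(**doc.get("vad", {})),
            pitch=PitchParams(**doc.get("pitch", {})),
            embedding=EmbeddingParams(**doc.get("embedding", {})),
            preemphasis=doc.get("preemphasis", 0.9375),
            channel_policy=doc.get("channel_policy", "left"),
            seed=doc.get("seed", 0),
        )


def extract_features_signal(
    signal: AudioSignal, config: PipelineConfig | None = None
) -> dict[str, float]:
    """Extract the 24 dysphonia features from one sustained-vowel signal."""
    config = config or PipelineConfig()
    if signal.rate != PIPELINE_RATE:
        signal = resample(signal, PIPELINE_RATE)

    emphasized = pre_emphasize(signal, config.preemphasis)
    frames = frame_signal(emphasized, config.frame)
    env = short_time_energy(frames)
    intervals = detect_voiced(env, config.vad)
    if not intervals:
        raise ValueError("no voiced segment detected")

    # pitch on the raw signal unless configured otherwise: pre-emphasis
    # attenuates the fundamental and degrades autocorrelation peaks
    pitch_source = emphasized if config.pitch.use_preemphasis else signal
    track = track_pitch(pitch_source, intervals, config.pitch, config.frame.shift_ms)
    track = remove_outliers(track)

    periods, amplitudes = [], []
    for iv in intervals:
        try:
            cycles = mark_cycles(signal, iv, track, config.pitch)
        except ValueError:
            continue
        periods.append(cycles.periods)
        amplitudes.append(cycles.amplitudes)
    if not periods:
        raise ValueError("too few cycles")
    periods = np.concatenate(periods)
    amplitudes = np.concatenate(amplitudes)

    f0_mean, f0_max, f0_min, f0_median, f0_std = f0_statistics(track)
    jit_pct, jit_abs, ppq5, rap, ddp = jitter_measures(periods)
    shim_pct, shim_db, apq3, apq5, apq11, dda = shimmer_measures(amplitudes)
    hnr_mean, hnr_std, nhr_mean, nhr_std = harmonicity(track)

    voiced_samples = np.concatenate(
        [signal.samples[iv.start_sample : iv.end_sample + 1] for iv in intervals]
    )
    feats = {
        "F0_mean": f0_mean, "F0_max": f0_max, "F0_min": f0_min,
        "F0_median": f0_median, "F0_std": f0_std,
        "Jitter": jit_pct, "Jitter_abs": jit_abs, "Jitter_PPQ5": ppq5,
        "Jitter_rap": rap, "Jitter_ddp": ddp,
        "Shimmer": shim_pct, "Shimmer_dB": shim_db, "Shimmer_APQ5": apq5,
        "Shimmer_APQ3": apq3, "Shimmer_dda": dda, "Shimmer_APQ11": apq11,
        "HNR_mean": hnr_mean, "HNR_std": hnr_std,
        "NHR_mean": nhr_mean, "NHR_std": nhr_std,
        "DFA": dfa(voiced_samples),
        "RPDE": rpde(voiced_samples, config.embedding),
        "D2": correlation_dimension(voiced_samples, config.embedding),
        "PPE": ppe(track),
    }
    bad = [k for k, v in feats.items() if not np.isfinite(v)]
    if bad:
        raise ValueError(f"non-finite feature values: {bad}")
    return feats


def extract_features(
    wav_paths, config: PipelineConfig | None = None
) -> dict[str, float]:
    """Extract one feature vector from 1-5 vowel recordings (element-wise mean)."""
    config = config or PipelineConfig()
    if isinstance(wav_paths, (str, bytes)) or hasattr(wav_paths, "__fspath__"):
        wav_paths = [wav_paths]
    if not 1 <= len(wav_paths) <= 5:
        raise ValueError("expected between 1 and 5 recordings")
    vectors = []
    for p in wav_paths:
        sig = read_wav(p, config.channel_policy)
        vectors.append(extract_features_signal(sig, config))
    return {
        name: float(np.mean([v[name] for v in vectors])) for name in FEATURE_NAMES
    }


# ---------------------------------------------------------------------------
# model training and persistence


def train_classifier(table: FeatureTable, algo: str = "svm", seed: int = 0) -> dict:
    """Fit a diagnosis model on the full table; returns a persistable bundle."""
    scaler = StandardScaler().fit(table.X)
    clf = make_classifier(algo, seed)
    clf.fit(scaler.transform(table.X), table.y)
    return {
        "version": MODEL_FORMAT_VERSION,
        "task": "classification",
        "algo": algo,
        "seed": seed,
        "feature_names": list(table.feature_names),
        "scaler": scaler,
        "model": clf,
    }


def train_regressor(table: FeatureTable, algo: str = "svr", seed: int = 0,
                    reg: float = 1.0) -> dict:
    """Fit a severity model on the full table; returns a persistable bundle."""
    scaler = StandardScaler().fit(table.X)
    model = make_regressor(algo, reg)
    y = table.y
    y_mu, y_sd = float(y.mean()), float(y.std()) or 1.0
    if algo == "svr":
        model.fit(scaler.transform(table.X), (y - y_mu) / y_sd)
    else:
        model.fit(scaler.transform(table.X), y)
        y_mu, y_sd = 0.0, 1.0
    return {
        "version": MODEL_FORMAT_VERSION,
        "task": "regression",
        "algo": algo,
        "seed": seed,
        "feature_names": list(table.feature_names),
        "scaler": scaler,
        "model": model,
        "y_mu": y_mu,
        "y_sd": y_sd,
    }


def save_model(bundle: dict, path) -> None:
    joblib.dump(bundle, path)


def load_model(path) -> dict:
    bundle = joblib.load(path)
    if bundle.get("version") != MODEL_FORMAT_VERSION:
        raise ValueError("unsupported model format version")
    return bundle


def _vector_from_features(features: dict[str, float], manifest: list[str]) -> np.ndarray:
    missing = [n for n in manifest if n not in features]
    if missing:
        raise ValueError(f"feature manifest mismatch: missing {missing}")
    return np.array([features[n] for n in manifest], dtype=np.float64)[None, :]


def diagnose(features: dict[str, float], bundle: dict) -> tuple[str, float]:
    """Classify a feature vector as PD / non-PD with a decision score."""
    if bundle.get("task") != "classification":
        raise ValueError("bundle is not a classification model")
    x = bundle["scaler"].transform(_vector_from_features(features, bundle["feature_names"]))
    model = bundle["model"]
    if hasattr(model, "decision_function"):
        score = float(model.decision_function(x)[0])
    else:
        score = float(model.predict_proba(x)[0, 1])
    label = "PD" if model.predict(x)[0] == 1 else "non-PD"
    return label, score


def assess_severity(features: dict[str, float], bundle: dict,
                    meta: dict | None = None) -> float:
    """Estimate the UPDRS severity score, clipped to [0, 199]."""
    if bundle.get("task") != "regression":
        raise ValueError("bundle is not a regression model")
    feats = dict(features)
    if meta:
        feats.update(meta)
    x = bundle["scaler"].transform(_vector_from_features(feats, bundle["feature_names"]))
    pred = float(bundle["model"].predict(x)[0]) * bundle["y_sd"] + bundle["y_mu"]
    return float(np.clip(pred, 0.0, UPDRS_MAX))
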