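"""Synthesize a perturbed vowel, write it to WAV, and extract all 24 features.

This is the minimal end-to-end loop: generator -> disk -> feature vector.
"""

import tempfile
from pathlib import Path

from voicepd import VowelSpec, synth_vowel
from voicepd.audio_io import read_wav, write_wav
from voicepd.pipeline import FEATURE_NAMES, extract_features_signal

spec = VowelSpec(f0=150.0, duration_s=3.0, jitter_rel_sd=0.01,
                 shimmer_rel_sd=0.02, target_hnr_db=20.0, seed=42)
signal, truth = synth_vowel(spec)
print(f"synthesized {signal.samples.size / signal.rate:.1f} s at {signal.rate} Hz, "
      f"{len(truth['periods'])} glottal cycles")

wav = Path(tempfile.mkdtemp()) / "vowel.wav"
write_wav(wav, signal)
feats = extract_features_signal(read_wav(wav))

for name in FEATURE_NAMES:
    print(f"  {name:14s} {feats[name]:12.5f}")
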