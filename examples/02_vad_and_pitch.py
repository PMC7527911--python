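"""Inspect the intermediate analyses: voiced-region detection and the pitch track.

A vowel with silence padding is synthesized; the endpoint detector should
recover the voiced span and the pitch tracker the programmed F0.
"""

import numpy as np

from voicepd import VowelSpec, synth_vowel
from voicepd.pitch import remove_outliers, track_pitch
from voicepd.preprocess import (FrameParams, VadParams, detect_voiced,
                                frame_signal, pre_emphasize, short_time_energy)

signal, truth = synth_vowel(VowelSpec(f0=180.0, duration_s=2.0,
                                      silence_pad_s=0.5, seed=1))

env = short_time_energy(frame_signal(pre_emphasize(signal, 0.9375), FrameParams()))
intervals = detect_voiced(env, VadParams())
print(f"true voiced span: {truth['voiced_start_sample'] / signal.rate:.3f}"
      f"-{truth['voiced_end_sample'] / signal.rate:.3f} s")
for iv in intervals:
    print(f"detected:         {iv.start_sample / signal.rate:.3f}"
          f"-{iv.end_sample / signal.rate:.3f} s")

track = remove_outliers(track_pitch(signal, intervals))
f0 = track.voiced_f0
print(f"pitch: {track.n_voiced} voiced frames, "
      f"F0 mean {f0.mean():.2f} Hz (programmed 180), "
      f"std {np.std(f0):.2f} Hz")
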