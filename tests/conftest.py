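import numpy as np
import pytest

from voicepd import VowelSpec, synth_vowel


@pytest.fixture(scope="session")
def clean_vowel_150():
    """A 3 s, 150 Hz sustained vowel with no injected perturbation."""
    return synth_vowel(VowelSpec(f0=150.0, duration_s=3.0, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def wav_path(tmp_path):
    """Factory writing an int16 stereo/mono array to a temp WAV file."""
    from scipy.io import wavfile

    def _write(data, rate=44100, name="test.wav"):
        p = tmp_path / name
        wavfile.write(p, rate, data)
        return p

    return _write
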