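import numpy as np
import pytest

from fricshape.corpus_io import FricativeGroup, PhoneToken, Utterance
from fricshape.frame_features import make_gammatone_bank
from fricshape.synthetic_fricatives import CorpusSpec, default_specs, generate_corpus

FS = 16000.0


@pytest.fixture(scope="session")
def bank():
    return make_gammatone_bank(fs=FS)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_corpus():
    """40 tokens/group/split, 8 talkers — shared across classifier tests."""
    return generate_corpus(
        default_specs(),
        CorpusSpec(n_tokens_per_group=40, n_talkers=8, seed=77),
    )


def make_tone_token(
    freq_hz: float,
    duration_ms: float = 64.0,
    fs: float = FS,
    group: FricativeGroup = FricativeGroup.ALV,
    amplitude: float = 0.1,
) -> PhoneToken:
    n = int(round(duration_ms * fs / 1000.0))
    t = np.arange(n) / fs
    return PhoneToken("tone", group, amplitude * np.cos(2 * np.pi * freq_hz * t), fs, "s")


@pytest.fixture()
def tone_utterance():
    n = int(FS)
    t = np.arange(n) / FS
    return Utterance("tone_utt", 0.1 * np.sin(2 * np.pi * 440.0 * t), FS)
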