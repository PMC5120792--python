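import numpy as np
import pytest
from scipy.signal import lfilter

import emasynth as es


@pytest.fixture(scope="session")
def harmonic_vowel():
    """Synthetic /a/-like vowel: 120 Hz pulse train through three resonances,
    with a -60 dB noise floor (bounded spectral dynamic range, as in real
    recordings)."""
    rate = 22050
    rng = np.random.default_rng(1)
    pulses = np.zeros(rate)
    pulses[np.arange(0, rate, rate / 120.0).astype(int)] = 1.0
    x = pulses
    for fc, bw in [(700, 110), (1200, 120), (2600, 160)]:
        r = np.exp(-np.pi * bw / rate)
        th = 2 * np.pi * fc / rate
        x = lfilter([1.0], [1, -2 * r * np.cos(th), r * r], x)
    x = x / np.std(x) + 1e-3 * rng.standard_normal(rate)
    return es.Waveform(x, rate=rate)


@pytest.fixture(scope="session")
def small_corpus():
    return es.generate_reference_corpus(es.SyntheticSpec(n_items=12, seed=5))


@pytest.fixture(scope="session")
def small_model(small_corpus):
    """A cheaply trained mapping for plumbing tests (not accuracy tests)."""
    pairs = es.training_pairs(small_corpus)
    cfg = es.TrainConfig(hidden=20, n_hidden_layers=3, max_epochs=3,
                         patience_epochs=3, blocks_per_epoch=10, seed=2)
    model, _ = es.train_layerwise(pairs, cfg)
    return model


@pytest.fixture(scope="session")
def impulse_template():
    period = 184
    tpl = np.zeros(period)
    tpl[0] = np.sqrt(period)
    return tpl
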