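import numpy as np
import pytest

from risesync import envelope as env
from risesync import synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def analyze(wave, ma_energy=6, ma_diff=10):
    """Waveform -> (smoothed energy, smoothed difference) with defaults."""
    raw = env.raw_energy(wave)
    zcr = env.zero_crossing_rate(wave)
    att = env.attenuate_fricatives(raw, zcr)
    smoothed = env.smooth_contour(att, ma_energy)
    return smoothed, env.energy_difference(smoothed, ma_diff)


def padded_tone(ramp_s, fall_s=0.05, dur_s=0.6, freq=500.0, amp=0.8,
                rate=44100, pad_s=0.3):
    """Tone embedded in silence so the rise foot has a baseline."""
    tone = synth.synth_tone(dur_s, freq, ramp_s, fall_s, amp, rate)
    pad = np.zeros(int(pad_s * rate))
    return env.Waveform(np.concatenate([pad, tone.samples, pad]), rate)


@pytest.fixture(scope="session")
def small_corpus():
    """Three synthetic sentences with ground truth, shared across tests."""
    generator = np.random.default_rng(7)
    sentences = []
    for s in range(3):
        specs = [
            synth.SyllableSpec(
                onset_ramp_s=float(generator.choice([0.02, 0.04, 0.06, 0.09, 0.12])),
                nucleus_dur_s=float(generator.uniform(0.10, 0.25)),
                peak_amp=float(generator.uniform(0.5, 0.95)),
                f0_hz=float(generator.choice([180.0, 220.0, 260.0])),
                onset_type=synth.ONSET_TYPES[int(generator.integers(4))],
            )
            for _ in range(6)
        ]
        wave, annotations, truth = synth.synth_sentence(
            specs, gap_s=0.15, seed=100 + s, sentence_id=f"S{s + 1:02d}"
        )
        sentences.append((wave, annotations, truth))
    return sentences
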