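"""Synthetic corpora with known ground truth.

Generates (i) sentence-like waveforms built from parametric syllables
with known linear onset ramps, (ii) looped tap trains with planted
anchors, Gaussian jitter, anticipation bias, and misses, and (iii)
feature tables drawn from a planted linear model — everything the
downstream stages need, without external recordings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.signal

from .envelope import Waveform
from .features import SyllableAnnotation
from .tapping import TapTrain

__all__ = [
    "SyllableSpec",
    "TapSimSpec",
    "synth_tone",
    "synth_sentence",
    "synth_taps",
    "synth_feature_table",
]

DEFAULT_RATE_HZ = 44100

ONSET_TYPES = ("none", "sonorant", "obstruent", "fricative")


@dataclass(frozen=True)
class SyllableSpec:
    """Parametric syllable: linear onset ramp, nucleus plateau, decay."""

    onset_ramp_s: float
    nucleus_dur_s: float
    peak_amp: float = 0.8
    decay_s: float = 0.06
    f0_hz: float = 220.0
    onset_type: str = "none"
    weight: str = "weak"
    onset_complexity: int = 0
    sonority: float = 9.0

    def __post_init__(self) -> None:
        if self.onset_ramp_s <= 0:
            raise ValueError("onset_ramp_s must be positive")
        if self.nucleus_dur_s <= 0:
            raise ValueError("nucleus_dur_s must be positive")
        if not (0 < self.peak_amp <= 1):
            raise ValueError("peak_amp must be in (0, 1]")
        if self.onset_type not in ONSET_TYPES:
            raise ValueError(f"onset_type must be one of {ONSET_TYPES}")

    @property
    def duration_s(self) -> float:
        return self.onset_ramp_s + self.nucleus_dur_s + self.decay_s


@dataclass(frozen=True)
class TapSimSpec:
    """Looped-tapping simulation: anchors per cycle plus timing noise."""

    anchor_times_s: tuple[float, ...]
    cycle_dur_s: float
    n_cycles: int = 15
    n_participants: int = 12
    jitter_sd_s: float = 0.02
    bias_s: float = 0.0
    miss_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "anchor_times_s", tuple(self.anchor_times_s))
        if self.n_cycles < 3:
            raise ValueError("n_cycles must be >= 3")
        if not all(0 <= a < self.cycle_dur_s for a in self.anchor_times_s):
            raise ValueError("anchors must lie within [0, cycle_dur_s)")
        if not (0 <= self.miss_prob <= 1):
            raise ValueError("miss_prob must be in [0, 1]")


def _linear_envelope(
    n: int, rate_hz: int, rise_s: float, fall_s: float, amp: float
) -> np.ndarray:
    t = np.arange(n) / rate_hz
    duration = n / rate_hz
    env = np.full(n, amp)
    if rise_s > 0:
        mask = t < rise_s
        env[mask] = amp * t[mask] / rise_s
    if fall_s > 0:
        mask = t >= duration - fall_s
        env[mask] = amp * (duration - t[mask]) / fall_s
    return env


def synth_tone(
    duration_s: float,
    freq_hz: float,
    rise_s: float,
    fall_s: float,
    amp: float,
    rate_hz: int = DEFAULT_RATE_HZ,
) -> Waveform:
    """Sine carrier under a linear rise / plateau / linear fall envelope."""
    if rise_s < 0 or fall_s < 0 or rise_s + fall_s > duration_s:
        raise ValueError("rise_s + fall_s must not exceed duration_s")
    if rate_hz < 8000:
        raise ValueError("rate_hz must be >= 8000")
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    carrier = np.sin(2 * np.pi * freq_hz * t)
    env = _linear_envelope(n, rate_hz, rise_s, fall_s, amp)
    return Waveform(carrier * env, rate_hz)


def _harmonic_carrier(n: int, rate_hz: int, f0_hz: float) -> np.ndarray:
    """f0 plus two partials, peak-normalized — speech-like low ZCR."""
    t = np.arange(n) / rate_hz
    x = (
        np.sin(2 * np.pi * f0_hz * t)
        + 0.5 * np.sin(2 * np.pi * 2 * f0_hz * t)
        + 0.25 * np.sin(2 * np.pi * 3 * f0_hz * t)
    )
    return x / np.max(np.abs(x))


def _fricative_noise(n: int, rate_hz: int, rng: np.random.Generator) -> np.ndarray:
    """High-passed white noise (>= 4 kHz) so the ZCR clears 7.5/ms."""
    noise = rng.standard_normal(n + 400)
    sos = scipy.signal.butter(6, 4000 / (rate_hz / 2), btype="high", output="sos")
    noise = scipy.signal.sosfilt(sos, noise)[400:]
    peak = np.max(np.abs(noise))
    return noise / peak if peak > 0 else noise


def _syllable_samples(
    spec: SyllableSpec, rate_hz: int, rng: np.random.Generator
) -> np.ndarray:
    n = int(round(spec.duration_s * rate_hz))
    n_ramp = int(round(spec.onset_ramp_s * rate_hz))
    carrier = _harmonic_carrier(n, rate_hz, spec.f0_hz)
    if spec.onset_type == "fricative":
        carrier[:n_ramp] = _fricative_noise(n_ramp, rate_hz, rng)
    elif spec.onset_type == "obstruent":
        carrier[:n_ramp] = rng.standard_normal(n_ramp) * 0.9
        carrier[:n_ramp] /= max(np.max(np.abs(carrier[:n_ramp])), 1e-9)
    env = _linear_envelope(n, rate_hz, spec.onset_ramp_s, spec.decay_s, spec.peak_amp)
    return carrier * env


def synth_sentence(
    specs: Sequence[SyllableSpec],
    gap_s: float = 0.05,
    rate_hz: int = DEFAULT_RATE_HZ,
    seed: int = 0,
    sentence_id: str = "S01",
) -> tuple[Waveform, list[SyllableAnnotation], list[dict]]:
    """Concatenate syllables separated by silences of ``gap_s``.

    Returns the waveform, syllable annotations (intervals extended half a
    gap on each side so the annotated span always contains the rise), and
    a ground-truth record per syllable with the exact ramp start/end.
    Deterministic for a fixed seed.
    """
    if not specs:
        raise ValueError("need at least one syllable spec")
    if gap_s < 0:
        raise ValueError("gap_s must be nonnegative")
    rng = np.random.default_rng(seed)
    gap = np.zeros(int(round(gap_s * rate_hz)))
    pieces = [gap]
    annotations: list[SyllableAnnotation] = []
    truth: list[dict] = []
    cursor = len(gap) / rate_hz
    for i, spec in enumerate(specs, start=1):
        samples = _syllable_samples(spec, rate_hz, rng)
        ramp_start = cursor
        ramp_end = cursor + spec.onset_ramp_s
        nucleus_end = ramp_end + spec.nucleus_dur_s
        syl_end = cursor + spec.duration_s
        half = gap_s / 2.0
        # stitch to the previous annotation so intervals tile exactly
        start_s = annotations[-1].end_s if annotations else ramp_start - half
        annotations.append(
            SyllableAnnotation(
                sentence_id=sentence_id,
                index=i,
                start_s=start_s,
                end_s=syl_end + half,
                nucleus_start_s=ramp_end,
                nucleus_end_s=nucleus_end,
                weight=spec.weight,
                onset_complexity=spec.onset_complexity,
                sonority=spec.sonority,
            )
        )
        truth.append(
            {
                "sentence_id": sentence_id,
                "syllable_idx": i,
                "ramp_start_s": ramp_start,
                "ramp_end_s": ramp_end,
                "ramp_dur_s": spec.onset_ramp_s,
                "nucleus_dur_s": spec.nucleus_dur_s,
                "peak_amp": spec.peak_amp,
                "onset_type": spec.onset_type,
            }
        )
        pieces.append(samples)
        pieces.append(gap.copy())
        cursor = syl_end + gap_s
    samples = np.concatenate(pieces)
    peak = np.max(np.abs(samples))
    if peak > 1.0:
        samples = samples / peak
    return Waveform(samples, rate_hz), annotations, truth


def synth_taps(spec: TapSimSpec, sentence_id: str = "S01") -> list[TapTrain]:
    """Simulated tap trains, one per participant.

    Every cycle emits each anchor with probability 1 - miss_prob at
    ``cycle_onset + anchor + bias + N(0, jitter_sd)``; reproducible for a
    fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    trains = []
    for p in range(spec.n_participants):
        times = []
        for k in range(spec.n_cycles):
            onset = k * spec.cycle_dur_s
            for anchor in spec.anchor_times_s:
                if rng.random() < spec.miss_prob:
                    continue
                t = onset + anchor + spec.bias_s
                if spec.jitter_sd_s > 0:
                    t += rng.normal(0.0, spec.jitter_sd_s)
                times.append(max(t, 0.0))
        times = np.unique(np.asarray(times, dtype=np.float64))
        trains.append(TapTrain(f"P{p + 1:02d}", sentence_id, times))
    return trains


#: predictor generators used by the planted-model feature table
_PREDICTOR_RANGES = {
    "serial_order": lambda rng, n: rng.integers(1, 14, size=n).astype(float),
    "weight": lambda rng, n: rng.integers(0, 2, size=n).astype(float),
    "onset_complexity": lambda rng, n: rng.integers(0, 3, size=n).astype(float),
    "sonority": lambda rng, n: rng.uniform(0, 9, size=n),
    "rise_slope": lambda rng, n: rng.lognormal(0.0, 0.5, size=n),
    "nucleus_dur_s": lambda rng, n: rng.uniform(0.05, 0.30, size=n),
    "rel_intensity": lambda rng, n: rng.normal(1.0, 0.15, size=n),
    "rise_time_ms": lambda rng, n: rng.uniform(20, 200, size=n),
}


def synth_feature_table(
    n: int,
    coefficients: Mapping[str, float],
    noise_sd: float,
    seed: int = 0,
    intercept: float = 0.0,
    response: str = "y",
):
    """Feature table with the response drawn from a planted linear model.

    ``coefficients`` maps predictor names (a subset of the built-in
    generators) to slopes; response = intercept + X b + N(0, noise_sd).
    A singular design triggers regeneration with a new seed and a warning.
    """
    import pandas as pd

    names = list(coefficients)
    unknown = [k for k in names if k not in _PREDICTOR_RANGES]
    if unknown:
        raise ValueError(f"no generator for predictor(s): {unknown}")
    if n < len(names) + 2:
        raise ValueError("n must be at least number of coefficients + 2")
    for attempt in range(20):
        rng = np.random.default_rng(seed + attempt)
        data = {k: _PREDICTOR_RANGES[k](rng, n) for k in names}
        X = np.column_stack([np.ones(n)] + [data[k] for k in names])
        if np.linalg.matrix_rank(X) == X.shape[1]:
            break
        warnings.warn(
            f"singular design for seed {seed + attempt}; regenerating",
            stacklevel=2,
        )
    else:
        raise RuntimeError("could not generate a full-rank design")
    y = intercept + sum(coefficients[k] * data[k] for k in names)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=n)
    table = pd.DataFrame(data)
    table[response] = y
    return table
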