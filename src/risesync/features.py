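"""Per-syllable predictor assembly: sonority, intensity, exclusions.

Builds the analysis table joining linguistic annotations with the
acoustic measurements (rise landmark, rise-time/slope, nucleus duration,
relative intensity) and applies the documented exclusion rules
(three-consonant onsets, intensity-measurement failures).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .envelope import HOP_S, Waveform, _window_bounds

__all__ = [
    "SONORITY_SCALE",
    "SyllableAnnotation",
    "sonority_default",
    "relative_intensity",
    "build_feature_table",
]

# 0-9 sonority scale: voiceless stops anchor 0, open vowels anchor 9;
# intermediate classes follow a conventional sonority hierarchy and are
# configurable by passing a custom table.
SONORITY_SCALE: dict[str, float] = {
    "voiceless_stop": 0.0,
    "voiced_stop": 1.0,
    "affricate": 1.5,
    "voiceless_fricative": 2.0,
    "voiced_fricative": 3.0,
    "nasal": 4.0,
    "lateral": 5.0,
    "rhotic": 6.0,
    "glide": 7.0,
    "close_vowel": 8.0,
    "open_vowel": 9.0,
}

#: reference power for dB intensity (square of 20 micro-pascal in full-scale
#: units); only the ratio of dB means is consumed downstream.
DB_POWER_REF = 4e-10

INTENSITY_WINDOW_S = 0.032


@dataclass(frozen=True)
class SyllableAnnotation:
    """Linguistic coding of one syllable within a sentence."""

    sentence_id: str
    index: int  # 1-based serial order within the sentence
    start_s: float
    end_s: float
    nucleus_start_s: float
    nucleus_end_s: float
    weight: str  # {"strong", "weak"}
    onset_complexity: int  # 0-3 as annotated
    sonority: float  # 0-9

    def __post_init__(self) -> None:
        if self.weight not in ("strong", "weak"):
            raise ValueError(f"weight must be strong|weak, got {self.weight!r}")
        if not (0 <= self.onset_complexity <= 3):
            raise ValueError("onset_complexity must be in 0..3")
        if not (self.start_s <= self.nucleus_start_s < self.nucleus_end_s <= self.end_s):
            raise ValueError(
                f"nucleus [{self.nucleus_start_s}, {self.nucleus_end_s}) must "
                f"lie within the syllable [{self.start_s}, {self.end_s})"
            )

    @property
    def syllable_id(self) -> str:
        return f"{self.sentence_id}:{self.index:02d}"

    @property
    def interval(self) -> tuple[float, float]:
        return (self.start_s, self.end_s)

    @property
    def nucleus_interval(self) -> tuple[float, float]:
        return (self.nucleus_start_s, self.nucleus_end_s)

    @property
    def nucleus_dur_s(self) -> float:
        return self.nucleus_end_s - self.nucleus_start_s


def sonority_default(
    onset_segments: Sequence[str],
    nucleus: Optional[str] = None,
    scale: Mapping[str, float] = SONORITY_SCALE,
) -> float:
    """Average sonority of the onset consonants on the 0-9 scale.

    Onset-free syllables take the sonority of the nucleus instead.
    Unknown segment classes raise ``ValueError`` naming the offenders.
    """
    segments = list(onset_segments)
    if not segments:
        if nucleus is None:
            raise ValueError("onset-free syllable requires a nucleus class")
        segments = [nucleus]
    unknown = sorted(set(s for s in segments if s not in scale))
    if unknown:
        raise ValueError(
            f"unknown segment class(es): {', '.join(unknown)}; "
            f"known: {', '.join(sorted(scale))}"
        )
    return float(np.mean([scale[s] for s in segments]))


def _intensity_db_frames(
    w: Waveform, window_s: float = INTENSITY_WINDOW_S, power_ref: float = DB_POWER_REF
) -> np.ndarray:
    """Per-frame intensity in dB on the 1-ms grid (windowed mean power)."""
    starts, ends = _window_bounds(len(w.samples), w.rate_hz, window_s)
    csum = np.concatenate(([0.0], np.cumsum(w.samples**2)))
    power = (csum[ends] - csum[starts]) / np.maximum(ends - starts, 1)
    with np.errstate(divide="ignore"):
        return 10.0 * np.log10(power / power_ref)


def relative_intensity(
    w: Waveform,
    nucleus: tuple[float, float],
    sentence: Optional[tuple[float, float]] = None,
    silence_floor_db: float = -60.0,
    power_ref: float = DB_POWER_REF,
) -> tuple[float, bool]:
    """Mean nucleus intensity (dB) over mean sentence intensity (dB).

    Sentence frames more than ``silence_floor_db`` below the loudest frame
    are treated as silence and excluded from the sentence mean. Returns
    ``(ratio, ok)``; an all-silent nucleus yields ``(nan, False)`` — the
    measurement-failure flag that drives the exclusion rule downstream.
    """
    db = _intensity_db_frames(w, power_ref=power_ref)
    times = np.arange(len(db)) * HOP_S
    if sentence is None:
        sent_mask = np.ones(len(db), dtype=bool)
    else:
        sent_mask = (times >= sentence[0]) & (times < sentence[1])
    nuc_mask = (times >= nucleus[0]) & (times < nucleus[1])
    if not nuc_mask.any() or not sent_mask.any():
        return float("nan"), False
    peak_db = np.max(db[sent_mask])
    voiced = sent_mask & (db > peak_db + silence_floor_db) & np.isfinite(db)
    nuc = nuc_mask & np.isfinite(db) & (db > peak_db + silence_floor_db)
    if not nuc.any() or not voiced.any():
        return float("nan"), False
    sent_mean = float(np.mean(db[voiced]))
    if sent_mean == 0.0:
        return float("nan"), False
    return float(np.mean(db[nuc]) / sent_mean), True


def build_feature_table(
    annotations: Iterable[SyllableAnnotation],
    rises: pd.DataFrame,
    landmarks: pd.DataFrame,
    waveforms: Mapping[str, Waveform],
) -> tuple[pd.DataFrame, list[dict]]:
    """Join annotations with acoustic measurements; apply exclusions.

    ``rises`` and ``landmarks`` must carry one row per syllable keyed by
    ``syllable_id``. Rows with a three-consonant onset or a failed
    intensity measurement are dropped; every exclusion is logged in the
    returned list. ``onset_complexity`` is recoded as a categorical with
    levels {0, 1, 2}.
    """
    annotations = list(annotations)
    ann_df = pd.DataFrame(
        {
            "syllable_id": [a.syllable_id for a in annotations],
            "sentence_id": [a.sentence_id for a in annotations],
            "serial_order": [a.index for a in annotations],
            "weight": [a.weight for a in annotations],
            "onset_complexity": [a.onset_complexity for a in annotations],
            "sonority": [a.sonority for a in annotations],
            "nucleus_dur_s": [a.nucleus_dur_s for a in annotations],
        }
    )
    for name, df in (("rises", rises), ("landmarks", landmarks)):
        if df["syllable_id"].duplicated().any():
            dupes = df.loc[df["syllable_id"].duplicated(), "syllable_id"]
            raise ValueError(f"duplicate keys in {name}: {sorted(set(dupes))}")
        orphans = set(ann_df["syllable_id"]) ^ set(df["syllable_id"])
        if orphans:
            raise ValueError(
                f"join mismatch between annotations and {name}: "
                f"orphan syllable_id(s) {sorted(orphans)}"
            )
    table = ann_df.merge(
        rises[["syllable_id", "rise_time_s", "rise_slope", "corrected", "flagged"]],
        on="syllable_id",
    ).merge(landmarks[["syllable_id", "maxD_s", "maxD_value"]], on="syllable_id")

    rel_int, ok = [], []
    for a in annotations:
        value, good = relative_intensity(
            waveforms[a.sentence_id], a.nucleus_interval
        )
        rel_int.append(value)
        ok.append(good)
    table["rel_intensity"] = rel_int
    table["intensity_ok"] = ok

    exclusions: list[dict] = []
    drop_complex = table["onset_complexity"] == 3
    for sid in table.loc[drop_complex, "syllable_id"]:
        exclusions.append({"syllable_id": sid, "reason": "onset_complexity_3"})
    drop_intensity = ~table["intensity_ok"]
    for sid in table.loc[drop_intensity & ~drop_complex, "syllable_id"]:
        exclusions.append({"syllable_id": sid, "reason": "intensity_failure"})
    table = table.loc[~(drop_complex | drop_intensity)].copy()
    table["onset_complexity"] = pd.Categorical(
        table["onset_complexity"], categories=[0, 1, 2]
    )
    table = table.drop(columns=["intensity_ok"]).reset_index(drop=True)
    if table.isna().any().any():
        bad = table.columns[table.isna().any()].tolist()
        raise ValueError(f"missing values after exclusion filters in {bad}")
    return table, exclusions
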