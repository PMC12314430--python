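"""Anchoring tapping peaks to rise landmarks and computing asynchronies.

A tapping peak within +/-120 ms of a landmark is anchored to its nearest
landmark (ties break toward the earlier landmark); signed asynchrony is
peak time minus landmark time, negative for anticipatory taps. Item-level
aggregation takes the median over participants of the signed and the
absolute asynchronies separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .envelope import Landmark
from .tapping import DensityPeak

__all__ = ["Asynchrony", "anchor", "aggregate_by_item"]


@dataclass(frozen=True)
class Asynchrony:
    participant_id: str
    sentence_id: str
    syllable_id: str
    signed_ms: float

    def __post_init__(self) -> None:
        if abs(self.signed_ms) > 120.0 + 1e-9:
            raise ValueError("asynchrony outside the +/-120 ms anchoring window")

    @property
    def abs_ms(self) -> float:
        return abs(self.signed_ms)


def anchor(
    peaks: Sequence[DensityPeak],
    landmarks: Sequence[Landmark],
    window_ms: float = 120.0,
) -> list[Asynchrony]:
    """Assign each peak to its nearest landmark within the window.

    The window is inclusive at +/-``window_ms``. A peak equidistant from
    two landmarks goes to the earlier one. When several peaks anchor to
    the same landmark only the nearest (earlier on ties) is kept;
    unmatched landmarks yield no record.
    """
    if not peaks or not landmarks:
        return []
    window_s = window_ms / 1000.0
    marks = sorted(landmarks, key=lambda m: m.time_s)
    best_for_mark: dict[int, tuple[float, DensityPeak]] = {}
    for peak in peaks:
        dists = [abs(peak.time_s - m.time_s) for m in marks]
        j = int(np.argmin(dists))  # argmin → earliest landmark on ties
        if dists[j] > window_s + 1e-12:
            continue
        prev = best_for_mark.get(j)
        if prev is None or dists[j] < prev[0] - 1e-12:
            best_for_mark[j] = (dists[j], peak)
    records = []
    for j, (_, peak) in sorted(best_for_mark.items()):
        signed_ms = (peak.time_s - marks[j].time_s) * 1000.0
        signed_ms = float(np.clip(signed_ms, -window_ms, window_ms))
        records.append(
            Asynchrony(
                peak.participant_id,
                peak.sentence_id,
                marks[j].syllable_id,
                signed_ms,
            )
        )
    return records


def aggregate_by_item(asynchronies: Iterable[Asynchrony]) -> pd.DataFrame:
    """Per-syllable medians over participants.

    Signed and absolute asynchronies are aggregated independently (even
    counts use the midpoint), so median absolute need not equal the
    absolute value of the median signed asynchrony.
    """
    rows = [
        {
            "syllable_id": a.syllable_id,
            "sentence_id": a.sentence_id,
            "participant_id": a.participant_id,
            "signed_ms": a.signed_ms,
            "abs_ms": a.abs_ms,
        }
        for a in asynchronies
    ]
    if not rows:
        return pd.DataFrame(
            columns=[
                "syllable_id",
                "sentence_id",
                "median_signed_ms",
                "median_abs_ms",
                "n_participants",
            ]
        )
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["syllable_id", "sentence_id"], sort=True)
        .agg(
            median_signed_ms=("signed_ms", "median"),
            median_abs_ms=("abs_ms", "median"),
            n_participants=("participant_id", "nunique"),
        )
        .reset_index()
    )
    return out
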