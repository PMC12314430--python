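"""Per-syllable rise-time and rise-slope extraction.

Rise-time is the interval between a local minimum and the following local
maximum of the smoothed energy contour, spanning the syllable's rise
landmark. The preceding minimum is located by walking backward from the
maximum in 5-ms steps until the local slope collapses (drops by more than
70% relative to the step nearer the maximum).

An alternative backend measures the same quantities on a low-passed
Hilbert envelope for cross-method comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.signal

from .envelope import HOP_S, EnergyContour, Landmark, Waveform

__all__ = [
    "RiseMeasurement",
    "local_energy_maximum",
    "find_preceding_minimum",
    "rise_measurement",
    "hilbert_rise",
    "hilbert_envelope_contour",
]


@dataclass(frozen=True)
class RiseMeasurement:
    syllable_id: str
    t_min_s: float
    e_min: float
    t_max_s: float
    e_max: float
    rise_time_s: float
    rise_slope: float  # energy units per second
    corrected: bool = False  # manual override applied
    flagged: bool = False  # fallback path or landmark outside the rise

    def __post_init__(self) -> None:
        if self.t_min_s >= self.t_max_s:
            raise ValueError(
                f"degenerate rise: t_min {self.t_min_s} >= t_max {self.t_max_s}"
            )


def local_energy_maximum(
    e: EnergyContour,
    syllable: tuple[float, float],
    rel_tol: float = 1e-3,
) -> tuple[float, float]:
    """Time and value of the highest smoothed-energy frame in the syllable.

    Ties resolve to the earliest frame. Frames within ``rel_tol`` of the
    maximum count as tied, so numerically rippled plateaus (e.g. steady
    vowels) yield the plateau onset rather than a ripple crest deep
    inside it. Empty overlap raises ValueError.
    """
    if e.kind != "smoothed":
        raise ValueError("expects the smoothed energy contour")
    start_s, end_s = syllable
    mask = e.slice_mask(start_s, end_s)
    if not mask.any():
        raise ValueError(
            f"syllable [{start_s}, {end_s}) does not overlap the contour"
        )
    idx = np.flatnonzero(mask)
    seg = e.values[idx]
    vmax = float(np.max(seg))
    best = idx[np.flatnonzero(seg >= vmax - rel_tol * abs(vmax))[0]]
    return e.t0_s + best * e.hop_s, float(e.values[best])


def find_preceding_minimum(
    e: EnergyContour,
    t_max_s: float,
    step_s: float = 0.005,
    drop_frac: float = 0.70,
    lower_bound_s: Optional[float] = None,
) -> tuple[float, float, bool]:
    """Foot of the energy rise preceding ``t_max_s``.

    Walks backward from the maximum in ``step_s`` steps comparing
    consecutive step slopes: the minimum is the boundary point where the
    farther slope falls below ``(1 - drop_frac)`` of the slope nearer the
    maximum (or stops being positive while the nearer one rises). If no
    step qualifies before ``lower_bound_s`` (previous syllable's maximum,
    default contour start), falls back to the lowest-energy frame in the
    search range and flags the measurement for review.

    Returns ``(time_s, value, flagged)``.
    """
    v = e.values
    i_max = e.frame_index(t_max_s)
    step = max(1, int(round(step_s / e.hop_s)))
    i_lo = 0 if lower_bound_s is None else e.frame_index(lower_bound_s)

    nearer_slope = None
    j = 1
    while i_max - j * step >= i_lo:
        i_far = i_max - j * step
        i_near = i_far + step
        slope = (v[i_near] - v[i_far]) / (step * e.hop_s)
        if nearer_slope is not None and nearer_slope > 0:
            if slope <= 0 or slope < (1.0 - drop_frac) * nearer_slope:
                t = e.t0_s + i_near * e.hop_s
                return t, float(v[i_near]), False
        nearer_slope = slope
        j += 1

    # fallback: flat or short contour — lowest energy before the maximum
    lo = min(i_lo, i_max)
    if lo == i_max:
        lo = max(0, i_max - 1)
    seg = v[lo:i_max]
    if len(seg) == 0:
        seg = v[max(0, i_max - 1) : i_max + 1]
        lo = max(0, i_max - 1)
    k = lo + int(np.argmin(seg))
    return e.t0_s + k * e.hop_s, float(v[k]), True


def rise_measurement(
    e: EnergyContour,
    syllable: tuple[float, float],
    maxd: Optional[Landmark] = None,
    override_min_s: Optional[float] = None,
    prev_max_s: Optional[float] = None,
    step_s: float = 0.005,
    drop_frac: float = 0.70,
    syllable_id: str = "",
    rel_tol: float = 1e-3,
) -> RiseMeasurement:
    """Full rise measurement for one syllable.

    ``override_min_s`` replaces the automatic minimum (manual-correction
    hook) and sets ``corrected``. The measurement is flagged when the
    fallback search fired or when the rise interval does not span the
    ``maxd`` landmark.
    """
    t_max, e_max = local_energy_maximum(e, syllable, rel_tol=rel_tol)
    if override_min_s is not None:
        i = e.frame_index(override_min_s)
        t_min, e_min, flagged = e.t0_s + i * e.hop_s, float(e.values[i]), False
        corrected = True
    else:
        t_min, e_min, flagged = find_preceding_minimum(
            e, t_max, step_s=step_s, drop_frac=drop_frac, lower_bound_s=prev_max_s
        )
        corrected = False
    if maxd is not None and not (t_min <= maxd.time_s <= t_max):
        flagged = True
    if t_min >= t_max:
        # fully flat contour: degrade to a one-frame rise, for review
        flagged = True
        i_max = e.frame_index(t_max)
        if i_max > 0:
            t_min, e_min = t_max - e.hop_s, float(e.values[i_max - 1])
        else:
            t_max, e_max = t_min + e.hop_s, float(e.values[i_max + 1])
    rise_time = t_max - t_min
    slope = max(e_max - e_min, 0.0) / rise_time
    sid = syllable_id or (maxd.syllable_id if maxd is not None else "")
    return RiseMeasurement(
        sid, t_min, e_min, t_max, e_max, rise_time, slope, corrected, flagged
    )


def hilbert_envelope_contour(
    w: Waveform, cutoff_hz: float = 10.0
) -> EnergyContour:
    """Low-passed analytic-signal magnitude resampled to the 1-ms grid."""
    env = np.abs(scipy.signal.hilbert(w.samples))
    nyq = w.rate_hz / 2.0
    b, a = scipy.signal.butter(4, cutoff_hz / nyq, btype="low")
    env = scipy.signal.filtfilt(b, a, env)
    env = np.maximum(env, 0.0)
    n_frames = int(np.floor((len(w.samples) - 1) / w.rate_hz / HOP_S)) + 1
    idx = np.round(np.arange(n_frames) * HOP_S * w.rate_hz).astype(np.int64)
    idx = np.clip(idx, 0, len(env) - 1)
    return EnergyContour(env[idx], kind="smoothed")


def hilbert_rise(
    w: Waveform,
    syllable: tuple[float, float],
    prev_max_s: Optional[float] = None,
    cutoff_hz: float = 40.0,
    syllable_id: str = "",
) -> RiseMeasurement:
    """Rise measurement on the Hilbert amplitude envelope (alt. backend).

    The low-pass cutoff defaults to 40 Hz: wide enough to preserve the
    20-120 ms onset ramps this backend is compared on, while still
    removing the carrier ripple. The zero-phase filter rings
    symmetrically at amplitude steps, so near-maximal humps within 0.5%
    count as tied and the earliest wins (the onset-side overshoot rather
    than the decay-side one).
    """
    contour = hilbert_envelope_contour(w, cutoff_hz=cutoff_hz)
    return rise_measurement(
        contour, syllable, prev_max_s=prev_max_s, syllable_id=syllable_id,
        rel_tol=5e-3,
    )
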