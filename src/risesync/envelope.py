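"""Energy contours and rise landmarks of speech-like signals.

The chain implemented here turns a waveform into a 1-ms-hop energy
contour, attenuates high-zero-crossing (fricative-like) frames, smooths,
differentiates, and locates the point of maximal energy increase (the
rise landmark) inside each annotated syllable interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "Waveform",
    "EnergyContour",
    "Landmark",
    "HOP_S",
    "raw_energy",
    "zero_crossing_rate",
    "attenuate_fricatives",
    "smooth_contour",
    "energy_difference",
    "find_maxD",
]

#: frame hop of every contour, seconds
HOP_S = 0.001

#: analysis window for energy and ZCR, seconds
ENERGY_WINDOW_S = 0.040


@dataclass(frozen=True)
class Waveform:
    """Mono audio: float samples in [-1, 1] plus a sample rate."""

    samples: np.ndarray
    rate_hz: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if self.rate_hz <= 0:
            raise ValueError(f"rate_hz must be positive, got {self.rate_hz}")
        if samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")
        object.__setattr__(self, "samples", samples)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate_hz

    def scaled(self, gain: float) -> "Waveform":
        return Waveform(self.samples * gain, self.rate_hz)


@dataclass(frozen=True)
class EnergyContour:
    """Frame series on a fixed 1-ms grid.

    ``kind`` distinguishes raw energy, smoothed energy, and the (signed)
    smoothed energy-difference contour. Frame ``k`` sits at time
    ``t0_s + k * hop_s``.
    """

    values: np.ndarray
    kind: str  # {"raw", "smoothed", "difference"}
    t0_s: float = 0.0
    hop_s: float = HOP_S

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if self.kind not in ("raw", "smoothed", "difference"):
            raise ValueError(f"unknown contour kind {self.kind!r}")
        if abs(self.hop_s - HOP_S) > 1e-12:
            raise ValueError("contour hop must be exactly 1 ms")
        if self.kind in ("raw", "smoothed") and np.any(values < -1e-12):
            raise ValueError(f"{self.kind} energy contour must be nonnegative")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(len(self.values)) * self.hop_s

    def frame_index(self, time_s: float) -> int:
        """Nearest frame to ``time_s``, clipped to the contour domain."""
        k = int(round((time_s - self.t0_s) / self.hop_s))
        return min(max(k, 0), len(self.values) - 1)

    def slice_mask(self, start_s: float, end_s: float) -> np.ndarray:
        """Boolean mask of frames whose centers lie in [start_s, end_s)."""
        t = self.times_s
        eps = 1e-9
        return (t >= start_s - eps) & (t < end_s - eps)


@dataclass(frozen=True)
class Landmark:
    """A timed per-syllable event (e.g. the maximal-rise point)."""

    syllable_id: str
    time_s: float
    value: float


def _window_bounds(n_samples: int, rate_hz: int, window_s: float):
    """Per-frame [start, end) sample indices for centered windows.

    Frames are centered every 1 ms; edge windows are truncated to the
    available samples.
    """
    n_frames = int(np.floor((n_samples - 1) / rate_hz / HOP_S)) + 1
    centers = np.round(np.arange(n_frames) * HOP_S * rate_hz).astype(np.int64)
    half = int(round(window_s * rate_hz / 2))
    starts = np.clip(centers - half, 0, n_samples)
    ends = np.clip(centers + half, 0, n_samples)
    return starts, ends


def raw_energy(w: Waveform, window_s: float = ENERGY_WINDOW_S) -> EnergyContour:
    """Raw energy contour: mean squared amplitude in a 40-ms window, 1-ms hop.

    Raises ``ValueError`` for inputs shorter than one analysis window.
    """
    if w.duration_s < window_s:
        raise ValueError(
            f"waveform of {w.duration_s * 1000:.1f} ms is shorter than the "
            f"{window_s * 1000:.0f}-ms analysis window"
        )
    starts, ends = _window_bounds(len(w.samples), w.rate_hz, window_s)
    csum = np.concatenate(([0.0], np.cumsum(w.samples**2)))
    energy = (csum[ends] - csum[starts]) / (ends - starts)
    return EnergyContour(energy, kind="raw")


def zero_crossing_rate(w: Waveform, window_s: float = ENERGY_WINDOW_S) -> np.ndarray:
    """Zero crossings per millisecond on the same 1-ms frame grid.

    A crossing is a sign change between consecutive samples (zeros count
    as positive, so silence and DC give rate 0). The count within each
    40-ms window is divided by the window duration in ms.
    """
    if w.duration_s < window_s:
        raise ValueError("waveform shorter than the analysis window")
    starts, ends = _window_bounds(len(w.samples), w.rate_hz, window_s)
    nonneg = w.samples >= 0
    crossing = (nonneg[1:] != nonneg[:-1]).astype(np.float64)
    csum = np.concatenate(([0.0], np.cumsum(crossing)))
    # crossing i sits between samples i and i+1: window [s, e) holds
    # crossings s .. e-2
    counts = csum[np.maximum(ends - 1, starts)] - csum[starts]
    dur_ms = (ends - starts) / w.rate_hz * 1000.0
    return counts / dur_ms


def attenuate_fricatives(
    e: EnergyContour,
    zcr: np.ndarray,
    threshold: float = 7.5,
    factor: float = 0.25,
) -> EnergyContour:
    """Scale frames with ZCR strictly above ``threshold`` by ``factor``.

    ``e`` must be a raw energy contour on the same frame grid as ``zcr``.
    """
    if e.kind != "raw":
        raise ValueError("fricative attenuation applies to the raw contour")
    zcr = np.asarray(zcr, dtype=np.float64)
    if zcr.shape != e.values.shape:
        raise ValueError(
            f"frame grid mismatch: contour has {len(e)} frames, "
            f"ZCR has {len(zcr)}"
        )
    out = e.values.copy()
    out[zcr > threshold] *= factor
    return replace(e, values=out)


def smooth_contour(e: EnergyContour, order: int) -> EnergyContour:
    """Zero-phase moving average of window length ``order`` frames.

    Average of a causal forward pass and an anticausal backward pass, so
    landmark times are not delayed; output length equals input length.
    """
    if order < 1:
        raise ValueError(f"order must be >= 1, got {order}")
    x = e.values
    kernel = np.ones(order) / order
    # edge-replicated so constant and interior-affine contours are exact
    fwd_pad = np.concatenate([np.full(order - 1, x[0]), x])
    bwd_pad = np.concatenate([x, np.full(order - 1, x[-1])])
    forward = np.convolve(fwd_pad, kernel, mode="valid")
    backward = np.convolve(bwd_pad, kernel, mode="valid")
    smoothed = (forward + backward) / 2.0
    kind = "smoothed" if e.kind in ("raw", "smoothed") else "difference"
    if kind == "smoothed":
        smoothed = np.maximum(smoothed, 0.0)  # guard float dust
    return replace(e, values=smoothed, kind=kind)


def energy_difference(e: EnergyContour, smooth_order: int = 10) -> EnergyContour:
    """First difference of the smoothed energy, re-smoothed (order 10)."""
    if e.kind != "smoothed":
        raise ValueError("energy_difference expects a smoothed contour")
    d = np.empty_like(e.values)
    d[0] = 0.0
    d[1:] = e.values[1:] - e.values[:-1]
    diff = replace(e, values=d, kind="difference")
    return smooth_contour(diff, smooth_order)


def find_maxD(
    d: EnergyContour,
    syllable: tuple[float, float],
    syllable_id: str = "",
) -> Landmark:
    """Highest value of the difference contour within [start, end).

    Ties resolve to the earliest frame. Raises ``ValueError`` when the
    syllable interval contains no frame centers.
    """
    if d.kind != "difference":
        raise ValueError("find_maxD expects the smoothed difference contour")
    start_s, end_s = syllable
    mask = d.slice_mask(start_s, end_s)
    if not mask.any():
        raise ValueError(
            f"syllable [{start_s}, {end_s}) does not overlap the contour"
        )
    idx = np.flatnonzero(mask)
    best = idx[np.argmax(d.values[idx])]  # argmax returns first max
    return Landmark(syllable_id, d.t0_s + best * d.hop_s, float(d.values[best]))
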