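"""Tap-train pre-processing: latency correction, cycle folding, kernel
density estimation, and density-peak picking.

Peaks of the per-participant tapping density over the (cycle-relative)
sentence time line represent consistently anchored taps: local density
maxima at least 40% of the tallest mode, thinned so that no two retained
peaks fall within 100 ms of each other (the higher one wins).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "TapTrain",
    "TapDensity",
    "DensityPeak",
    "correct_latency",
    "fold_cycles",
    "nrd_bandwidth",
    "tap_density",
    "find_tap_peaks",
]


@dataclass(frozen=True)
class TapTrain:
    """Absolute tap times of one participant on one looped sentence."""

    participant_id: str
    sentence_id: str
    tap_times_s: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.tap_times_s, dtype=np.float64)
        if len(times) and times.min() < 0:
            raise ValueError("tap times must be nonnegative")
        if len(times) > 1 and np.any(np.diff(times) <= 0):
            raise ValueError("tap times must be strictly increasing")
        object.__setattr__(self, "tap_times_s", times)

    def __len__(self) -> int:
        return len(self.tap_times_s)


@dataclass(frozen=True)
class TapDensity:
    """Gaussian KDE of cycle-relative tap times on a uniform 1-ms grid."""

    times_s: np.ndarray
    values: np.ndarray
    bandwidth_s: float
    n_taps: int

    @property
    def grid_step_s(self) -> float:
        return float(self.times_s[1] - self.times_s[0])


@dataclass(frozen=True)
class DensityPeak:
    participant_id: str
    sentence_id: str
    time_s: float  # cycle-relative
    density_value: float


def correct_latency(train: TapTrain, latency_s: float = 0.005) -> TapTrain:
    """Subtract the recording latency from every tap time.

    Taps that would become negative are clipped to 0 with a warning;
    duplicates produced by clipping are merged.
    """
    times = train.tap_times_s - latency_s
    if len(times) and times.min() < 0:
        warnings.warn(
            f"{np.sum(times < 0)} tap(s) clipped to 0 after latency correction",
            stacklevel=2,
        )
        times = np.maximum(times, 0.0)
        times = np.unique(times)
    return replace(train, tap_times_s=times)


def fold_cycles(
    train: TapTrain,
    cycle_dur_s: float,
    n_reps: int,
    skip_reps: int = 2,
    lead_s: float = 0.300,
) -> np.ndarray:
    """Cycle-relative tap times, skipping the first ``skip_reps`` cycles.

    Each tap maps to the cycle whose onset lies within ``lead_s`` after
    (or anywhere before) it: relative time r = t - k*cycle_dur with
    r in [-lead_s, cycle_dur - lead_s). Taps in the skipped leading
    cycles or beyond cycle ``n_reps`` are discarded.
    """
    if cycle_dur_s <= lead_s:
        raise ValueError("cycle duration must exceed the lead window")
    t = train.tap_times_s
    k = np.floor((t + lead_s) / cycle_dur_s).astype(np.int64)
    r = t - k * cycle_dur_s
    keep = (k >= skip_reps) & (k < n_reps)
    return np.sort(r[keep])


def nrd_bandwidth(x: np.ndarray) -> float:
    """Normal-reference KDE bandwidth 1.06 * min(sd, IQR/1.34) * n^(-1/5).

    ``sd`` is the n-1 sample standard deviation; the IQR uses
    linear-interpolation quantiles between order statistics.
    """
    x = np.asarray(x, dtype=np.float64)
    n = len(x)
    if n < 2:
        raise ValueError("bandwidth needs at least 2 observations")
    sd = float(np.std(x, ddof=1))
    q25, q75 = np.quantile(x, [0.25, 0.75])  # linear interpolation
    iqr = float(q75 - q25)
    return 1.06 * min(sd, iqr / 1.34) * n ** (-1.0 / 5.0)


def tap_density(
    rel_times: np.ndarray,
    grid_step_s: float = 0.001,
    bw_divisor: float = 8.0,
    pad_bandwidths: float = 4.0,
) -> TapDensity:
    """Gaussian KDE of folded tap times with 1/8 of the default bandwidth.

    The evaluation grid extends ``pad_bandwidths`` bandwidths beyond the
    extreme taps so that the density integrates to 1 over the grid
    (within 1%). Raises on fewer than 2 distinct times or a degenerate
    (zero) bandwidth.
    """
    rel_times = np.asarray(rel_times, dtype=np.float64)
    if len(np.unique(rel_times)) < 2:
        raise ValueError("degenerate distribution: need >= 2 distinct tap times")
    h = nrd_bandwidth(rel_times) / bw_divisor
    if h <= 0:
        raise ValueError("degenerate distribution: zero bandwidth")
    # grid must resolve the kernel, else the density cannot normalize
    grid_step_s = min(grid_step_s, h / 4.0)
    lo = rel_times.min() - pad_bandwidths * h
    hi = rel_times.max() + pad_bandwidths * h
    k_lo = int(np.floor(lo / grid_step_s))
    k_hi = int(np.ceil(hi / grid_step_s))
    grid = np.arange(k_lo, k_hi + 1) * grid_step_s
    z = (grid[:, None] - rel_times[None, :]) / h
    values = np.exp(-0.5 * z**2).sum(axis=1) / (len(rel_times) * h * np.sqrt(2 * np.pi))
    return TapDensity(grid, values, h, len(rel_times))


def find_tap_peaks(
    density: TapDensity,
    rel_threshold: float = 0.40,
    min_sep_s: float = 0.100,
    participant_id: str = "",
    sentence_id: str = "",
) -> list[DensityPeak]:
    """Retained density peaks: local maxima above the relative threshold,
    thinned greedily from the highest so retained peaks are >= min_sep
    apart.

    Local maxima are strictly greater than both neighbours; plateaus
    contribute their center frame. When two candidates fall within
    ``min_sep_s``, the higher one wins (ties: the earlier).
    """
    v = density.values
    t = density.times_s
    candidates: list[tuple[float, float]] = []  # (time, value)
    i = 1
    n = len(v)
    while i < n - 1:
        if v[i] > v[i - 1]:
            j = i
            while j + 1 < n and v[j + 1] == v[i]:
                j += 1
            if j < n - 1 and v[j + 1] < v[i]:
                mid = (i + j) // 2
                candidates.append((float(t[mid]), float(v[mid])))
            i = j + 1
        else:
            i += 1
    if not candidates:
        return []
    vmax = max(val for _, val in candidates)
    candidates = [c for c in candidates if c[1] >= rel_threshold * vmax]
    # greedy from the highest peak down; earlier peak wins ties
    candidates.sort(key=lambda c: (-c[1], c[0]))
    kept: list[tuple[float, float]] = []
    eps = 1e-12
    for time, val in candidates:
        if all(abs(time - kt) >= min_sep_s - eps for kt, _ in kept):
            kept.append((time, val))
    kept.sort()
    return [
        DensityPeak(participant_id, sentence_id, time, val) for time, val in kept
    ]
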