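"""Mono PCM WAV read/write backed by scipy.io.wavfile."""

from __future__ import annotations

import numpy as np
import scipy.io.wavfile

from ..envelope import Waveform

__all__ = ["read_wav", "write_wav"]


def write_wav(path, w: Waveform) -> None:
    """Write 16-bit PCM mono."""
    clipped = np.clip(w.samples, -1.0, 1.0)
    data = np.round(clipped * 32767.0).astype(np.int16)
    scipy.io.wavfile.write(str(path), w.rate_hz, data)


def read_wav(path) -> Waveform:
    """Read mono audio as float64 in [-1, 1]."""
    rate, data = scipy.io.wavfile.read(str(path))
    if data.ndim == 2:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max)
        data = data.astype(np.float64) / scale
    else:
        data = data.astype(np.float64)
    return Waveform(data, int(rate))
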