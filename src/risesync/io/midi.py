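"""Minimal Standard MIDI File support for tap recordings.

Writes/reads single-track (format 0) files containing note-on events
whose onset times encode the taps. Tempo is fixed at 120 bpm with 480
ticks per quarter note, giving ~1 ms resolution; that is ample for tap
times that are later folded on a 1-ms grid.
"""

from __future__ import annotations

import struct
from typing import Sequence

import numpy as np

__all__ = ["write_tap_midi", "read_tap_midi"]

TICKS_PER_BEAT = 480
TEMPO_US = 500000  # 120 bpm -> 0.5 s per beat


def _varlen(value: int) -> bytes:
    out = [value & 0x7F]
    value >>= 7
    while value:
        out.append(0x80 | (value & 0x7F))
        value >>= 7
    return bytes(reversed(out))


def _read_varlen(data: bytes, pos: int) -> tuple[int, int]:
    value = 0
    while True:
        b = data[pos]
        pos += 1
        value = (value << 7) | (b & 0x7F)
        if not b & 0x80:
            return value, pos


def _seconds_to_ticks(t: float) -> int:
    return int(round(t * 1e6 / TEMPO_US * TICKS_PER_BEAT))


def write_tap_midi(path, times_s: Sequence[float], note: int = 60) -> None:
    """Write tap onsets as note-on/note-off pairs in a format-0 SMF."""
    events: list[tuple[int, bytes]] = [(0, bytes([0xFF, 0x51, 0x03]) + TEMPO_US.to_bytes(3, "big"))]
    for t in sorted(times_s):
        tick = _seconds_to_ticks(float(t))
        events.append((tick, bytes([0x90, note, 100])))
        events.append((tick + 24, bytes([0x80, note, 0])))
    events.sort(key=lambda e: e[0])
    track = b""
    prev = 0
    for tick, msg in events:
        track += _varlen(tick - prev) + msg
        prev = tick
    track += _varlen(0) + bytes([0xFF, 0x2F, 0x00])  # end of track
    with open(path, "wb") as fh:
        fh.write(b"MThd" + struct.pack(">IHHH", 6, 0, 1, TICKS_PER_BEAT))
        fh.write(b"MTrk" + struct.pack(">I", len(track)) + track)


def read_tap_midi(path) -> np.ndarray:
    """Note-on onset times (seconds) from a format-0/1 SMF."""
    with open(path, "rb") as fh:
        data = fh.read()
    if data[:4] != b"MThd":
        raise ValueError("not a Standard MIDI File")
    header_len = struct.unpack(">I", data[4:8])[0]
    _, n_tracks, division = struct.unpack(">HHH", data[8:14])
    if division & 0x8000:
        raise ValueError("SMPTE time division not supported")
    pos = 8 + header_len
    tempo = TEMPO_US
    times: list[float] = []
    for _ in range(n_tracks):
        if data[pos : pos + 4] != b"MTrk":
            raise ValueError("malformed track chunk")
        length = struct.unpack(">I", data[pos + 4 : pos + 8])[0]
        track = data[pos + 8 : pos + 8 + length]
        pos += 8 + length
        tick = 0
        i = 0
        status = 0
        while i < len(track):
            delta, i = _read_varlen(track, i)
            tick += delta
            b = track[i]
            if b & 0x80:
                status = b
                i += 1
            if status == 0xFF:  # meta
                meta_type = track[i]
                i += 1
                mlen, i = _read_varlen(track, i)
                if meta_type == 0x51:
                    tempo = int.from_bytes(track[i : i + 3], "big")
                i += mlen
            elif status in (0xF0, 0xF7):  # sysex
                mlen, i = _read_varlen(track, i)
                i += mlen
            else:
                kind = status & 0xF0
                n_data = 1 if kind in (0xC0, 0xD0) else 2
                if kind == 0x90 and track[i + 1] > 0:
                    times.append(tick * tempo / 1e6 / division)
                i += n_data
    return np.asarray(sorted(times))
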