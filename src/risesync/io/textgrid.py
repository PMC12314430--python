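"""Minimal Praat TextGrid (long text format) reader/writer.

Supports interval tiers only, which is all the annotation pipeline
needs (tiers "syllable" and "nucleus").
"""

from __future__ import annotations

import re
from typing import Mapping, Sequence

__all__ = ["read_textgrid", "write_textgrid"]

Interval = tuple[float, float, str]


def write_textgrid(
    path, tiers: Mapping[str, Sequence[Interval]], xmin: float = 0.0, xmax: float = None
) -> None:
    """Write interval tiers in Praat's long TextGrid format."""
    if xmax is None:
        xmax = max(
            (iv[1] for ivs in tiers.values() for iv in ivs), default=xmin + 1.0
        )
    lines = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        f"xmin = {xmin:.6f}",
        f"xmax = {xmax:.6f}",
        "tiers? <exists>",
        f"size = {len(tiers)}",
        "item []:",
    ]
    for t, (name, intervals) in enumerate(tiers.items(), start=1):
        lines += [
            f"    item [{t}]:",
            '        class = "IntervalTier"',
            f'        name = "{name}"',
            f"        xmin = {xmin:.6f}",
            f"        xmax = {xmax:.6f}",
            f"        intervals: size = {len(intervals)}",
        ]
        for i, (a, b, label) in enumerate(intervals, start=1):
            esc = label.replace('"', '""')
            lines += [
                f"        intervals [{i}]:",
                f"            xmin = {a:.6f}",
                f"            xmax = {b:.6f}",
                f'            text = "{esc}"',
            ]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def read_textgrid(path) -> dict[str, list[Interval]]:
    """Parse interval tiers from a long-format TextGrid.

    Returns ``{tier_name: [(xmin, xmax, text), ...]}``; point tiers are
    skipped.
    """
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    tiers: dict[str, list[Interval]] = {}
    tier_chunks = re.split(r"item \[\d+\]:", text)[1:]
    for chunk in tier_chunks:
        cls = re.search(r'class\s*=\s*"([^"]*)"', chunk)
        name = re.search(r'name\s*=\s*"([^"]*)"', chunk)
        if not cls or cls.group(1) != "IntervalTier" or not name:
            continue
        intervals: list[Interval] = []
        for m in re.finditer(
            r"intervals \[\d+\]:\s*"
            r"xmin\s*=\s*([\d.eE+-]+)\s*"
            r"xmax\s*=\s*([\d.eE+-]+)\s*"
            r'text\s*=\s*"((?:[^"]|"")*)"',
            chunk,
        ):
            label = m.group(3).replace('""', '"')
            intervals.append((float(m.group(1)), float(m.group(2)), label))
        tiers[name.group(1)] = intervals
    return tiers
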