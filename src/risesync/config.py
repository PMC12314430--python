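"""Run configuration: paths, analysis constants, simulation settings.

Every analysis constant has a single documented home here so the whole
chain (energy windowing, smoothing orders, fricative reduction, slope
rule, latency, cycle folding, KDE bandwidth divisor, peak rules,
anchoring window, model alphas) is traceable and overridable from one
YAML file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["AnalysisParams", "SimulateParams", "RunConfig"]


@dataclass
class AnalysisParams:
    energy_window_ms: float = 40.0
    ma_order_energy: int = 6
    ma_order_diff: int = 10
    zcr_threshold: float = 7.5  # crossings per ms
    fricative_factor: float = 0.25
    slope_step_ms: float = 5.0
    slope_drop: float = 0.70
    latency_ms: float = 5.0
    lead_ms: float = 300.0
    skip_reps: int = 2
    bw_divisor: float = 8.0
    peak_rel_threshold: float = 0.40
    peak_min_sep_ms: float = 100.0
    anchor_window_ms: float = 120.0
    alpha: float = 0.05
    corr_alpha: float = 0.001

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if f.name != "skip_reps" and value <= 0:
                raise ValueError(f"parameter {f.name} must be positive")
        if self.skip_reps < 0:
            raise ValueError("skip_reps must be >= 0")


@dataclass
class SimulateParams:
    n_sentences: int = 10
    syllables_per_sentence: int = 8
    n_participants: int = 12
    n_reps: int = 15
    gap_s: float = 0.15
    rate_hz: int = 44100
    jitter_sd_ms: float = 20.0
    bias_ms: float = 0.0
    miss_prob: float = 0.05


@dataclass
class RunConfig:
    output_dir: Path = Path("runs/default")
    audio_dir: Path | None = None  # default: <output_dir>/audio
    textgrid_dir: Path | None = None
    features_csv: Path | None = None
    taps_dir: Path | None = None
    loops_csv: Path | None = None
    corrections_csv: Path | None = None
    seed: int = 0
    params: AnalysisParams = field(default_factory=AnalysisParams)
    simulate: SimulateParams = field(default_factory=SimulateParams)

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        if self.audio_dir is None:
            self.audio_dir = self.output_dir / "audio"
        if self.textgrid_dir is None:
            self.textgrid_dir = self.output_dir / "textgrids"
        if self.features_csv is None:
            self.features_csv = self.output_dir / "syllable_features.csv"
        if self.taps_dir is None:
            self.taps_dir = self.output_dir / "taps"
        if self.loops_csv is None:
            self.loops_csv = self.output_dir / "loops.csv"
        for name in ("audio_dir", "textgrid_dir", "features_csv", "taps_dir", "loops_csv"):
            setattr(self, name, Path(getattr(self, name)))
        if self.corrections_csv is not None:
            self.corrections_csv = Path(self.corrections_csv)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        params = AnalysisParams(**raw.pop("params", {}))
        simulate = SimulateParams(**raw.pop("simulate", {}))
        return cls(params=params, simulate=simulate, **raw)

    def to_yaml(self, path) -> None:
        raw = dataclasses.asdict(self)
        for key, value in list(raw.items()):
            if isinstance(value, Path):
                raw[key] = str(value)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)
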