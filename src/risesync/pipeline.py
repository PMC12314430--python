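"""End-to-end orchestration: simulate a corpus, run the acoustic chain,
the tapping/asynchrony chain, and the model workflow, all from one
``RunConfig``. Every stage writes plain CSV so reruns with the same seed
are bit-identical.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import asynchrony as asyn
from . import envelope as env
from . import features as feat
from . import regression as reg
from . import risetime as rt
from . import synth
from . import tapping as tap
from .config import RunConfig
from .io import read_textgrid, read_wav, write_tap_midi, write_textgrid, write_wav

logger = logging.getLogger("risesync")

FLOAT_FMT = "%.10g"

RISE_PREDICTORS = [
    "rise_slope",
    "nucleus_dur_s",
    "weight",
    "onset_complexity",
    "sonority",
    "rel_intensity",
    "serial_order",
]
ASYNC_PREDICTORS = ["log_rise_time_ms"] + RISE_PREDICTORS
NUMERIC_PREDICTORS = [
    "log_rise_time_ms",
    "rise_slope",
    "nucleus_dur_s",
    "sonority",
    "rel_intensity",
    "serial_order",
]


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# corpus simulation
# ---------------------------------------------------------------------------

ONSET_CYCLE = ("none", "sonorant", "obstruent", "fricative")


def _sentence_specs(rng: np.random.Generator, n_syllables: int) -> list[synth.SyllableSpec]:
    specs = []
    ramps = (0.02, 0.035, 0.05, 0.075, 0.10, 0.12)
    for i in range(n_syllables):
        specs.append(
            synth.SyllableSpec(
                onset_ramp_s=float(rng.choice(ramps)),
                nucleus_dur_s=float(rng.uniform(0.10, 0.25)),
                peak_amp=float(rng.uniform(0.5, 0.95)),
                decay_s=float(rng.uniform(0.04, 0.08)),
                f0_hz=float(rng.choice([180.0, 220.0, 260.0])),
                onset_type=ONSET_CYCLE[int(rng.integers(len(ONSET_CYCLE)))],
                weight="strong" if rng.random() < 0.5 else "weak",
                onset_complexity=int(rng.integers(0, 3)),
                sonority=float(np.round(rng.uniform(0, 9), 1)),
            )
        )
    return specs


def simulate_corpus(config: RunConfig) -> dict:
    """Generate the synthetic corpus on disk: audio, TextGrids, feature
    sidecar, loop metadata, tap recordings (CSV + SMF), ground truth.

    Tap anchors are planted at the rise landmarks measured on the
    generated audio, so zero-jitter/zero-bias runs synchronize exactly.
    """
    sim = config.simulate
    p = config.params
    rng = np.random.default_rng(config.seed)
    config.audio_dir.mkdir(parents=True, exist_ok=True)
    config.textgrid_dir.mkdir(parents=True, exist_ok=True)
    config.taps_dir.mkdir(parents=True, exist_ok=True)
    config.output_dir.mkdir(parents=True, exist_ok=True)

    feature_rows, truth_rows, loop_rows = [], [], []
    complexity3_planted = False
    for s in range(sim.n_sentences):
        sid = f"S{s + 1:02d}"
        specs = _sentence_specs(rng, sim.syllables_per_sentence)
        if not complexity3_planted and s == 0:
            # exactly one three-consonant onset in the corpus, to exercise
            # the exclusion rule
            mid = len(specs) // 2
            specs[mid] = synth.SyllableSpec(
                **{**specs[mid].__dict__, "onset_complexity": 3}
            )
            complexity3_planted = True
        wave, annotations, truth = synth.synth_sentence(
            specs,
            gap_s=sim.gap_s,
            rate_hz=sim.rate_hz,
            seed=int(rng.integers(2**31)),
            sentence_id=sid,
        )
        write_wav(config.audio_dir / f"{sid}.wav", wave)
        syl_tier = [(a.start_s, a.end_s, f"syl{a.index:02d}") for a in annotations]
        nuc_tier = [
            (a.nucleus_start_s, a.nucleus_end_s, f"nuc{a.index:02d}")
            for a in annotations
        ]
        write_textgrid(
            config.textgrid_dir / f"{sid}.TextGrid",
            {"syllable": syl_tier, "nucleus": nuc_tier},
            xmax=wave.duration_s,
        )
        for a in annotations:
            feature_rows.append(
                {
                    "sentence_id": sid,
                    "syllable_idx": a.index,
                    "weight": a.weight,
                    "onset_complexity": a.onset_complexity,
                    "sonority": a.sonority,
                }
            )
        truth_rows.extend(truth)

        # plant tap anchors at the measured rise landmarks
        landmarks = _sentence_landmarks(wave, [a.interval for a in annotations], p)
        anchors = tuple(lm.time_s for lm in landmarks)
        cycle_dur = wave.duration_s
        loop_rows.append(
            {"sentence_id": sid, "cycle_dur_s": cycle_dur, "n_reps": sim.n_reps}
        )
        spec = synth.TapSimSpec(
            anchor_times_s=anchors,
            cycle_dur_s=cycle_dur,
            n_cycles=sim.n_reps,
            n_participants=sim.n_participants,
            jitter_sd_s=sim.jitter_sd_ms / 1000.0,
            bias_s=sim.bias_ms / 1000.0,
            miss_prob=sim.miss_prob,
            seed=int(rng.integers(2**31)),
        )
        for train in synth.synth_taps(spec, sentence_id=sid):
            # taps as recorded: the equipment latency is added here and
            # subtracted again by the pre-processing stage
            recorded = train.tap_times_s + p.latency_ms / 1000.0
            stem = f"{sid}__{train.participant_id}"
            _write_csv(
                pd.DataFrame({"time_s": recorded}), config.taps_dir / f"{stem}.csv"
            )
            write_tap_midi(config.taps_dir / f"{stem}.mid", recorded)

    _write_csv(pd.DataFrame(feature_rows), config.features_csv)
    _write_csv(pd.DataFrame(truth_rows), config.output_dir / "ground_truth.csv")
    _write_csv(pd.DataFrame(loop_rows), config.loops_csv)
    return {
        "n_sentences": sim.n_sentences,
        "n_syllables": len(feature_rows),
        "n_participants": sim.n_participants,
    }


# ---------------------------------------------------------------------------
# acoustics
# ---------------------------------------------------------------------------


def analyze_waveform(wave: env.Waveform, params) -> tuple[env.EnergyContour, env.EnergyContour]:
    """Waveform -> (smoothed energy contour, smoothed difference contour)."""
    raw = env.raw_energy(wave, window_s=params.energy_window_ms / 1000.0)
    zcr = env.zero_crossing_rate(wave, window_s=params.energy_window_ms / 1000.0)
    attenuated = env.attenuate_fricatives(
        raw, zcr, threshold=params.zcr_threshold, factor=params.fricative_factor
    )
    smoothed = env.smooth_contour(attenuated, params.ma_order_energy)
    diff = env.energy_difference(smoothed, smooth_order=params.ma_order_diff)
    return smoothed, diff


def _sentence_landmarks(wave, intervals, params, ids=None) -> list[env.Landmark]:
    _, diff = analyze_waveform(wave, params)
    ids = ids or [f"{i + 1:02d}" for i in range(len(intervals))]
    return [
        env.find_maxD(diff, interval, syllable_id=sid)
        for interval, sid in zip(intervals, ids)
    ]


def _load_annotations(config: RunConfig) -> tuple[list[feat.SyllableAnnotation], dict]:
    sidecar = pd.read_csv(config.features_csv)
    waveforms: dict[str, env.Waveform] = {}
    annotations: list[feat.SyllableAnnotation] = []
    grids = sorted(config.textgrid_dir.glob("*.TextGrid"))
    if not grids:
        raise FileNotFoundError(f"no TextGrids under {config.textgrid_dir}")
    for grid_path in grids:
        sid = grid_path.stem
        tiers = read_textgrid(grid_path)
        if "syllable" not in tiers:
            raise ValueError(f"{grid_path}: missing tier 'syllable'")
        wav_path = config.audio_dir / f"{sid}.wav"
        try:
            waveforms[sid] = read_wav(wav_path)
        except Exception as exc:  # corrupt or missing audio
            raise RuntimeError(f"could not read audio {wav_path}: {exc}") from exc
        syllables = [iv for iv in tiers["syllable"] if iv[2].strip()]
        nuclei = [iv for iv in tiers.get("nucleus", []) if iv[2].strip()]
        if len(nuclei) != len(syllables):
            raise ValueError(f"{grid_path}: syllable/nucleus tier size mismatch")
        meta = sidecar[sidecar["sentence_id"] == sid].set_index("syllable_idx")
        for i, ((a, b, _), (na, nb, _)) in enumerate(zip(syllables, nuclei), start=1):
            if i not in meta.index:
                raise ValueError(f"{sid}: no sidecar features for syllable {i}")
            row = meta.loc[i]
            annotations.append(
                feat.SyllableAnnotation(
                    sentence_id=sid,
                    index=i,
                    start_s=a,
                    end_s=b,
                    nucleus_start_s=na,
                    nucleus_end_s=nb,
                    weight=str(row["weight"]),
                    onset_complexity=int(row["onset_complexity"]),
                    sonority=float(row["sonority"]),
                )
            )
    return annotations, waveforms


def run_acoustics(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Acoustic chain: landmarks, rise measurements, feature table."""
    p = config.params
    annotations, waveforms = _load_annotations(config)
    corrections: dict[tuple[str, int], float] = {}
    if config.corrections_csv is not None and Path(config.corrections_csv).exists():
        cdf = pd.read_csv(config.corrections_csv)
        corrections = {
            (r.sentence_id, int(r.syllable_idx)): float(r.override_min_s)
            for r in cdf.itertuples()
        }

    landmark_rows, rise_rows = [], []
    for sid in sorted(waveforms):
        smoothed, diff = analyze_waveform(waveforms[sid], p)
        sent_annotations = [a for a in annotations if a.sentence_id == sid]
        prev_max = None
        for a in sent_annotations:
            maxd = env.find_maxD(diff, a.interval, syllable_id=a.syllable_id)
            landmark_rows.append(
                {
                    "sentence_id": sid,
                    "syllable_idx": a.index,
                    "syllable_id": a.syllable_id,
                    "maxD_s": maxd.time_s,
                    "maxD_value": maxd.value,
                }
            )
            measure = rt.rise_measurement(
                smoothed,
                a.interval,
                maxd=maxd,
                override_min_s=corrections.get((sid, a.index)),
                prev_max_s=prev_max,
                step_s=p.slope_step_ms / 1000.0,
                drop_frac=p.slope_drop,
                syllable_id=a.syllable_id,
            )
            prev_max = measure.t_max_s
            if measure.flagged:
                logger.info("flagged rise measurement for %s", a.syllable_id)
            rise_rows.append(
                {
                    "sentence_id": sid,
                    "syllable_idx": a.index,
                    "syllable_id": a.syllable_id,
                    "t_min_s": measure.t_min_s,
                    "e_min": measure.e_min,
                    "t_max_s": measure.t_max_s,
                    "e_max": measure.e_max,
                    "rise_time_s": measure.rise_time_s,
                    "rise_slope": measure.rise_slope,
                    "corrected": measure.corrected,
                    "flagged": measure.flagged,
                }
            )
    landmarks = pd.DataFrame(landmark_rows)
    rises = pd.DataFrame(rise_rows)
    table, exclusions = feat.build_feature_table(
        annotations, rises, landmarks, waveforms
    )
    for entry in exclusions:
        logger.info("excluded %(syllable_id)s: %(reason)s", entry)
    out = config.output_dir
    _write_csv(landmarks, out / "landmarks.csv")
    _write_csv(rises, out / "rises.csv")
    _write_csv(table, out / "features.csv")
    _write_csv(pd.DataFrame(exclusions, columns=["syllable_id", "reason"]),
               out / "exclusions.csv")
    return {"landmarks": landmarks, "rises": rises, "features": table}


# ---------------------------------------------------------------------------
# tapping & asynchrony
# ---------------------------------------------------------------------------


def run_sms(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Tap pre-processing and asynchrony computation.

    Requires ``landmarks.csv`` from :func:`run_acoustics` plus the tap
    recordings and loop metadata.
    """
    p = config.params
    out = config.output_dir
    landmarks = pd.read_csv(out / "landmarks.csv")
    loops = pd.read_csv(config.loops_csv).set_index("sentence_id")

    peak_rows = []
    records: list[asyn.Asynchrony] = []
    tap_files = sorted(config.taps_dir.glob("*.csv"))
    if not tap_files:
        warnings.warn("no tap recordings found; asynchrony tables will be empty")
    for path in tap_files:
        sid, pid = path.stem.split("__")
        times = pd.read_csv(path)["time_s"].to_numpy()
        train = tap.TapTrain(pid, sid, times)
        train = tap.correct_latency(train, latency_s=p.latency_ms / 1000.0)
        loop = loops.loc[sid]
        rel = tap.fold_cycles(
            train,
            cycle_dur_s=float(loop["cycle_dur_s"]),
            n_reps=int(loop["n_reps"]),
            skip_reps=p.skip_reps,
            lead_s=p.lead_ms / 1000.0,
        )
        if len(np.unique(rel)) < 2:
            warnings.warn(f"{path.stem}: too few taps for a density estimate")
            continue
        density = tap.tap_density(rel, bw_divisor=p.bw_divisor)
        peaks = tap.find_tap_peaks(
            density,
            rel_threshold=p.peak_rel_threshold,
            min_sep_s=p.peak_min_sep_ms / 1000.0,
            participant_id=pid,
            sentence_id=sid,
        )
        for pk in peaks:
            peak_rows.append(
                {
                    "participant_id": pid,
                    "sentence_id": sid,
                    "time_s": pk.time_s,
                    "density_value": pk.density_value,
                }
            )
        marks = [
            env.Landmark(r.syllable_id, r.maxD_s, r.maxD_value)
            for r in landmarks[landmarks["sentence_id"] == sid].itertuples()
        ]
        records.extend(asyn.anchor(peaks, marks, window_ms=p.anchor_window_ms))

    peaks_df = pd.DataFrame(
        peak_rows, columns=["participant_id", "sentence_id", "time_s", "density_value"]
    )
    async_df = pd.DataFrame(
        [
            {
                "participant_id": a.participant_id,
                "sentence_id": a.sentence_id,
                "syllable_id": a.syllable_id,
                "signed_ms": a.signed_ms,
                "abs_ms": a.abs_ms,
            }
            for a in records
        ],
        columns=["participant_id", "sentence_id", "syllable_id", "signed_ms", "abs_ms"],
    )
    item_df = asyn.aggregate_by_item(records)
    _write_csv(peaks_df, out / "peaks.csv")
    _write_csv(async_df, out / "asynchrony.csv")
    _write_csv(item_df, out / "item_asynchrony.csv")
    return {"peaks": peaks_df, "asynchrony": async_df, "item": item_df}


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------


def build_item_table(config: RunConfig) -> pd.DataFrame:
    """Join the feature table with the item-level asynchronies."""
    out = config.output_dir
    features = pd.read_csv(out / "features.csv")
    items = pd.read_csv(out / "item_asynchrony.csv")
    table = features.merge(
        items[["syllable_id", "median_signed_ms", "median_abs_ms", "n_participants"]],
        on="syllable_id",
        how="inner",
    )
    table["rise_time_ms"] = table["rise_time_s"] * 1000.0
    table["weight"] = pd.Categorical(table["weight"], categories=["weak", "strong"])
    table["onset_complexity"] = pd.Categorical(
        table["onset_complexity"], categories=[0, 1, 2]
    )
    return table


def run_models(config: RunConfig) -> dict:
    """Regression workflow on the joined item table; writes reports."""
    p = config.params
    out = config.output_dir
    table = build_item_table(config)
    if table["median_abs_ms"].min() <= 0:
        # syllables tapped exactly on the landmark: nudge for the log by
        # half the 1-ms peak grid
        table.loc[table["median_abs_ms"] <= 0, "median_abs_ms"] = 0.5
    table, checks = reg.prepare_responses(table)

    analyses = {
        "log_rise_time_ms": RISE_PREDICTORS,
        "log_median_abs_ms": ASYNC_PREDICTORS,
        "median_signed_ms": ASYNC_PREDICTORS,
    }
    results = {"normality": checks, "models": {}}
    for response, terms in analyses.items():
        full, final, comparison = reg.backward_eliminate(
            table, response, terms, alpha=p.alpha
        )
        vifs = reg.vif(table, terms)
        _write_csv(full.coef_table(), out / f"model_{response}_full.csv")
        _write_csv(final.coef_table(), out / f"model_{response}_final.csv")
        vifs.rename_axis("column").reset_index().to_csv(
            out / f"vif_{response}.csv", index=False, float_format=FLOAT_FMT
        )
        with open(out / f"model_{response}_comparison.json", "w") as fh:
            json.dump(
                {
                    "F": comparison.f,
                    "df1": comparison.df1,
                    "df2": comparison.df2,
                    "p": comparison.p,
                    "lr_chi2": comparison.lr_chi2,
                    "lr_p": comparison.lr_p,
                    "final_terms": list(final.terms),
                },
                fh,
                indent=2,
            )
        results["models"][response] = (full, final, comparison, vifs)
    r, pvals, flags = reg.predictor_correlations(
        table, NUMERIC_PREDICTORS, alpha=p.corr_alpha
    )
    r.rename_axis("predictor").reset_index().to_csv(
        out / "predictor_correlations.csv", index=False, float_format=FLOAT_FMT
    )
    results["correlations"] = (r, pvals, flags)
    return results


def run_all(config: RunConfig) -> dict:
    """simulate -> acoustics -> sms -> models."""
    info = simulate_corpus(config)
    acoustics = run_acoustics(config)
    sms = run_sms(config)
    models = run_models(config)
    return {"simulate": info, "acoustics": acoustics, "sms": sms, "models": models}
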