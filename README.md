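# risesync

Analysis pipeline for amplitude-envelope rhythm research: from raw speech
audio and finger-tap recordings to rise-time statistics and
sensorimotor-synchronization (SMS) asynchrony models — exercised end to end
on synthetic corpora with known ground truth.

The chain:

1. **envelope** — raw energy contour (squared amplitudes, 40-ms window,
   1-ms hop), zero-crossing rate, fricative attenuation (ZCR > 7.5/ms →
   ×0.25), zero-phase moving-average smoothing (order 6), energy-difference
   contour (first difference, re-smoothed order 10), and the per-syllable
   maximal-rise landmark (maxD).
2. **risetime** — local energy maximum per syllable, backward slope-drop
   search (5-ms steps, 70% drop) for the preceding minimum, rise-time and
   rise-slope; Hilbert-envelope alternative backend with review flags and a
   manual-correction override hook.
3. **features** — per-syllable predictor table: metrical weight, onset
   complexity (categorical 0–2; 3-consonant onsets excluded), sonority
   (0–9 scale), nucleus duration, relative intensity (ratio of dB means,
   failures excluded), serial order.
4. **tapping** — tap-train latency correction (5 ms), cycle folding
   (300-ms lead window, first 2 repetitions skipped), Gaussian KDE with
   1/8 of the normal-reference bandwidth, density-peak picking (40% of the
   tallest mode, 100-ms separation, higher peak wins).
5. **asynchrony** — peaks anchored to the nearest landmark within ±120 ms;
   signed (negative = anticipation) and absolute asynchronies, aggregated
   per item as medians over participants.
6. **regression** — log transforms with Shapiro–Wilk diagnostics, OLS with
   reference-coded categorical terms, backward elimination (categorical
   factors as blocks), nested-model F test plus LR chi-square, VIFs, and a
   significance-flagged predictor correlation matrix (α = 0.001).
7. **synth** — synthetic corpora: parametric syllables (linear onset
   ramps, harmonic nuclei, high-ZCR fricative onsets), looped tap trains
   with planted anchors/jitter/bias/misses, and feature tables drawn from
   planted linear models.

## CLI

```sh
risesync all --output-dir runs/demo --seed 1          # full pipeline
risesync simulate --output-dir runs/demo --seed 1     # corpus only
risesync acoustics --output-dir runs/demo             # landmarks/rises/features
risesync sms --output-dir runs/demo                   # peaks + asynchronies
risesync model --output-dir runs/demo                 # regression reports
```

All analysis constants (window lengths, smoothing orders, thresholds,
windows, alphas) live in one `RunConfig`; dump/restore with
`RunConfig.to_yaml` / `--config config.yaml`. Outputs are plain CSV/JSON
and bit-identical across reruns with the same seed.

To analyse your own recordings, point the config at directories of
per-sentence WAVs, TextGrids (tiers `syllable` and `nucleus`), a sidecar
feature CSV (`sentence_id, syllable_idx, weight, onset_complexity,
sonority`), tap files named `<sentence>__<participant>.csv`, and a
`loops.csv` (`sentence_id, cycle_dur_s, n_reps`); then run the
`acoustics`, `sms`, and `model` stages. Manual rise-foot corrections go in
an optional CSV (`sentence_id, syllable_idx, override_min_s`).

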