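# exerstep

Movement analysis for a lateral-stepping balance-training exergame, driven by
a synthetic gameplay simulator with exact ground truth.

The package covers the full measurement chain used to study how game settings
(game speed, obstacle presence) shape the movements of older adults playing a
step-based exergame:

- **`exerstep.mocap_io`** — read/write 22-marker trajectory recordings
  (tab-separated dialect; C3D read support via the optional `ezc3d` extra),
  gap filling, validation, unit handling (mm/m).
- **`exerstep.simulator`** — a synthetic exergame: object schedules (falling
  grapes, falling branches, stationary chickens with 7 s catch windows), a
  configurable player-behavior policy, game-clock pauses with error messages
  when the player leaves the 2 × 2 m active area, and minimum-jerk marker
  rendering at 120 Hz with analytic ground-truth event annotations.
- **`exerstep.detection`** — step detection (≥ 0.03 m toe-marker displacement
  lasting ≥ 0.05 s, delimited by a 0 ± 0.1 m/s velocity band), arm-lift
  detection (wrist above mean head-marker height, with hysteresis), and
  single-leg-support derivation.
- **`exerstep.metrics`** — per-trial movement characteristics: mean step
  size, cadence, single-support duration and ratio per foot, arm-lift
  frequency, sternum occupancy heatmaps (30 × 30), anterior drift.
- **`exerstep.gamelog`** — structured JSON-lines game event logs: scoring
  (+1 grape / +3 chicken / −2 branch), error-message tallies by condition,
  and the 2 × 2 Pearson chi-squared test (no continuity correction).
- **`exerstep.lmm`** — the long-format study table and REML linear
  mixed-effects fits (fixed: speed, obstacles, repetition, gender, side;
  random: per-participant intercept + side slope), plus simulation-based
  calibration and parameter-recovery experiments.
- **`exerstep.pipeline`** — reproducible end-to-end runs
  (simulate → detect → metrics → game stats → models) with a JSON run report.

## CLI

```sh
exerstep simulate --n 15 --seed 7 --out run/     # synthetic study, full chain
exerstep load trial.tsv --format auto            # validate a recording
exerstep detect trial.tsv --out events.tsv       # event detection
exerstep metrics trial.tsv --out metrics.tsv     # movement characteristics
exerstep gamestats run/ --out tables/            # scores + error messages
exerstep fit metrics.tsv -r cadence --out lmm/   # mixed-effects models
exerstep run trial1.tsv trial2.tsv --out run/    # analysis of recordings
```

## Notes

- Trial time used for rates/ratios is the full capture duration: the game
  clock pauses during error messages but the capture does not.
- All randomness flows from a single seed; identical seeds give
  byte-identical event tables and metrics.
- Detector thresholds, the differentiation scheme and the heatmap extent are
  configurable (`DetectionConfig`, CLI `--config`).
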