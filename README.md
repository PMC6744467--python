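# trailtrack

Assignment-based multi-object tracking and trajectory analysis for ant
trail videos, plus a synthetic trail-scene simulator that provides ground
truth for testing every stage without video data.

The toolkit links per-frame ant detections into trajectories by solving a
minimum-cost assignment (a transportation problem: detections in frame K
are suppliers, detections in frame K+1 receivers, unmatched detections pay
a birth/death penalty), calibrates them into physical units, applies
completeness filtering and U-turn splitting, computes movement metrics
(speed, straightness index ST = d/L, visiting maps, exploration indices),
and runs the statistical stages: beta-mixture grouping of straightness with
BIC model selection, linear mixed models with crossed random intercepts,
and 30-minute-interval comparisons with Tukey contrasts.

## Layout

| module | contents |
| --- | --- |
| `trailtrack.core_io` | domain types (`Detection`, `FrameSet`, `Trajectory`, `MetricRecord`, `TrailConfig`), CSV readers/writers, config loading |
| `trailtrack.tracker` | gated pairwise costs, per-frame-pair optimal assignment with birth/death, tracklet building with gap bridging and false-positive pruning, error-cue extraction, training-frame selection |
| `trailtrack.preprocess` | pixel→cm / frame→clock calibration, edge-start filtering, U-turn splitting, direction assignment |
| `trailtrack.metrics` | path length/displacement, straightness, average speed, visiting maps (supercover rasterization; `entries` and `trajectories` modes), exploration index (EI/AEI), heatmap export |
| `trailtrack.stats` | beta-mixture EM with BIC selection and group classification; mixed models (statsmodels REML) and Tukey-adjusted interval comparisons |
| `trailtrack.simulate` | seeded correlated-random-walk scene generator, detector-noise corruption, tracking evaluation against ground truth |
| `trailtrack.cli` / `trailtrack.pipeline` | `trailtrack` command-line entry points and the end-to-end pipeline with a reproducibility manifest |

## CLI

```bash
# generate a synthetic scene bundle (ground truth + corrupted detections)
trailtrack simulate --n-ants 200 --seed 7 --jitter-px 1 --miss-rate 0.02 --out scene/

# track detections into trajectories
trailtrack track --detections scene/detections.csv --config trail.yaml --out tracked/

# score the tracking against the simulator's ground truth
trailtrack evaluate --truth scene/ground_truth.csv --recovered tracked/

# the full pipeline: track -> calibrate -> filter -> split U-turns -> metrics -> stats
trailtrack pipeline --detections scene/detections.csv --config trail.yaml --out run/ --seed 7
```

A trail config (YAML or JSON) needs at least `cm_per_px` and `fps`;
`view_width_px`/`view_height_px` are required by the pipeline. Optional
keys: `start_clock` ("19:30:00"), `nest_side` (low|high), `trail_axis`
(x|y), `edge_margin_frac` (default 0.05), `cell_size_cm` (default 1.0).

Detection CSVs have columns `frame,x,y[,confidence][,a0..aK]` — one row per
detection, no ID column. Appearance columns, when present, enter the
assignment cost as range-normalized Euclidean distances.

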