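# droneval

Detection-reliability evaluation for multi-camera drone surveys of marine
fauna. The package matches model-generated bounding boxes against manually
annotated ground-truth tracks frame by frame, using IoU-threshold matching
(default 50%), and reports per-flight, per-sensor-treatment true/false
positives, false negatives, precision, recall and F1. Because the original
survey footage is not publicly available, a synthetic scene simulator
generates flights with the same statistical structure — dolphins that
repeatedly surface and dive, depth-dependent detectability that differs
between an unfiltered RGB sensor, a green-bandpass-filtered sensor and a
green-plus-polariser sensor, Gaussian box-localisation jitter, and clutter
false positives — so every pipeline stage runs and is tested at desk scale.

## Modules

| Module | Role |
|---|---|
| `droneval.detection_io` | Box/detection/track data model; MOT-style CSV readers and writers; temporal clipping; central-region filter; keyframe interpolation |
| `droneval.stream_sync` | Per-camera frame-offset estimation from short-lived event anchors; sync verification; offset correction |
| `droneval.matcher` | IoU; one-to-one greedy/optimal box assignment; TP/FP/FN tallies (with a literal and a strict false-positive convention) |
| `droneval.metrics_report` | Precision/recall/F1 from counts; treatment-level means; IoU histograms with peak detection; CSV/Markdown report emission |
| `droneval.synthetic_scene` | Dive-cycle trajectory simulation, logistic depth-detectability, jittered detections, clutter, planted camera offsets, event anchors |
| `droneval.pipeline` / `droneval.cli` | Run orchestration (simulate or from files), manifest with checksums, published-counts cross-check, `droneval` command |

## CLI

```sh
# write a synthetic three-camera flight (ground truth, detections, anchors)
droneval simulate --out flight_dir            # packaged preset
droneval simulate --config my_preset.yaml --seed 7 --out flight_dir

# full evaluation run on the packaged preset (or your own files)
droneval evaluate --out run_dir
droneval evaluate --gt gt.csv --detections RGB rgb.csv --detections GREEN green.csv \
    --anchors anchors.csv --out run_dir

# recompute precision/recall/F1 from published per-flight counts
droneval check-counts

# re-render a report from an existing metrics table
droneval report --metrics run_dir/report/metrics.csv --out new_report
```

`evaluate` writes a fixed output layout: `gt/`, `detections/<treatment>/`,
`matches/`, `report/` (with `metrics.csv` and `summary.md`),
`sync_report.json` and a `manifest.json` whose checksums are reproducible
for a fixed seed and config. Exit codes: 0 success, 1 validation failure,
2 I/O failure.

## File formats

* Detection streams: CSV `frame,id,x,y,w,h,conf,class` with `x,y` the
  top-left corner; ground-truth rows carry `conf = -1` and the animal id.
* Track keyframes: CSV `animal_id,frame,x_min,y_min,x_max,y_max`.
* Event anchors: CSV `event_id,camera,frame`.
* Simulation presets: YAML (see `src/droneval/data/default_preset.yaml`).
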