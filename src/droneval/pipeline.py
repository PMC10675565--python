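"""End-to-end run orchestration: simulate (or load) → sync → clip/filter →
match → metrics → report, with a manifest recording config, row counts and
checksums of every emitted artefact."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

from droneval import __version__
from droneval.detection_io import (
    Treatment,
    central_region_filter,
    clip_to_frame_range,
    read_detections,
    write_detections,
)
from droneval.errors import ValidationError
from droneval.matcher import MatchConfig, match_sequence, write_frame_results
from droneval.metrics_report import (
    IoUHistogram,
    MetricRow,
    compute_metrics,
    iou_histogram,
    metrics_from_counts,
    render_report,
    summarize_treatments,
)
from droneval.stream_sync import (
    apply_offset,
    estimate_offsets,
    read_event_anchors,
    write_event_anchors,
)
from droneval.synthetic_scene import SimulationConfig, simulate_flight

logger = logging.getLogger(__name__)

_SENSOR_LABELS = {t.display: t for t in Treatment}


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one evaluation run (exactly one input mode)."""

    output_dir: Path
    simulation: SimulationConfig | None = None
    input_paths: Mapping[str, object] | None = None
    match: MatchConfig = field(default_factory=MatchConfig)
    central_fraction: float = 0.8
    sync_tolerance: int = 1
    correct_offsets: bool = True
    strict_sync: bool = True
    reference_camera: Treatment = Treatment.RGB
    seed: int | None = None

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.input_paths is None):
            raise ValidationError("exactly one of simulation / input_paths must be set")

    @property
    def mode(self) -> str:
        return "simulate" if self.simulation is not None else "from_files"


@dataclass(frozen=True)
class RunManifest:
    mode: str
    seed: int | None
    version: str
    row_counts: Mapping[str, int]
    checksums: Mapping[str, str]
    timings: Mapping[str, float]
    metric_rows: tuple[MetricRow, ...]

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "seed": self.seed,
            "version": self.version,
            "row_counts": dict(self.row_counts),
            "checksums": dict(self.checksums),
            "timings": {k: round(v, 3) for k, v in self.timings.items()},
        }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_inputs(config: RunConfig):
    """Return (ground_truth, model_sets, anchors) for either input mode."""
    if config.simulation is not None:
        sim_config = config.simulation
        if config.seed is not None:
            sim_config = replace(sim_config, seed=config.seed)
        sim = simulate_flight(sim_config)
        return sim.ground_truth, dict(sim.model_sets), list(sim.anchors)
    paths = dict(config.input_paths)
    width = int(paths.get("frame_width", 3840))
    height = int(paths.get("frame_height", 2160))
    flight_id = str(paths.get("flight_id", "flight"))
    gt = read_detections(paths["ground_truth"], flight_id=flight_id,
                         frame_width=width, frame_height=height)
    model_sets = {}
    for key, path in dict(paths["detections"]).items():
        treatment = Treatment(key) if not isinstance(key, Treatment) else key
        model_sets[treatment] = read_detections(
            path, flight_id=flight_id, treatment=treatment,
            frame_width=width, frame_height=height,
        )
    anchors = read_event_anchors(paths["anchors"]) if paths.get("anchors") else []
    return gt, model_sets, anchors


def run(config: RunConfig) -> RunManifest:
    """Execute every stage in order, writing all intermediate artefacts under
    the output directory (``gt/``, ``detections/<treatment>/``, ``matches/``,
    ``report/``)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    row_counts: dict[str, int] = {}
    written: list[Path] = []

    t0 = time.perf_counter()
    ground_truth, model_sets, anchors = _load_inputs(config)
    timings["inputs"] = time.perf_counter() - t0
    row_counts["ground_truth"] = len(ground_truth)

    gt_dir = outdir / "gt"
    gt_dir.mkdir(exist_ok=True)
    gt_path = gt_dir / "ground_truth.csv"
    write_detections(ground_truth, gt_path)
    written.append(gt_path)
    if anchors:
        anchor_path = gt_dir / "event_anchors.csv"
        write_event_anchors(anchors, anchor_path)
        written.append(anchor_path)
    for treatment, dset in model_sets.items():
        det_dir = outdir / "detections" / treatment.value
        det_dir.mkdir(parents=True, exist_ok=True)
        det_path = det_dir / "detections.csv"
        write_detections(dset, det_path)
        written.append(det_path)
        row_counts[f"detections_{treatment.value}"] = len(dset)

    # synchronisation
    t0 = time.perf_counter()
    offsets: dict[Treatment, int] = {t: 0 for t in model_sets}
    if anchors:
        report = estimate_offsets(
            anchors, config.reference_camera.value, tolerance=config.sync_tolerance
        )
        sync_path = outdir / "sync_report.json"
        report.write_json(sync_path)
        written.append(sync_path)
        if config.strict_sync and not report.passed:
            raise ValidationError(
                f"synchronisation verification failed: max offset "
                f"{report.max_abs_offset} frames exceeds tolerance "
                f"{config.sync_tolerance} or anchors disagree"
            )
        if config.correct_offsets:
            for treatment in model_sets:
                offsets[treatment] = int(report.offset_by_camera.get(treatment.value, 0))
    timings["sync"] = time.perf_counter() - t0

    # clip / filter / match / metrics per treatment
    t0 = time.perf_counter()
    matches_dir = outdir / "matches"
    matches_dir.mkdir(exist_ok=True)
    rows: list[MetricRow] = []
    histograms: dict[tuple[str, Treatment], IoUHistogram] = {}
    for treatment in sorted(model_sets, key=lambda t: t.value):
        model = apply_offset(model_sets[treatment], offsets[treatment])
        common = ground_truth.frame_range.intersection(model.frame_range)
        if common is None:
            raise ValidationError(
                f"no common frame range between ground truth and {treatment.value} stream"
            )
        gt_clipped = central_region_filter(
            clip_to_frame_range(ground_truth, common), config.central_fraction
        )
        model_clipped = central_region_filter(
            clip_to_frame_range(model, common), config.central_fraction
        )
        counts, frame_results = match_sequence(gt_clipped, model_clipped, config.match)
        write_frame_results(frame_results, matches_dir / f"{treatment.value}.csv")
        written.append(matches_dir / f"{treatment.value}.csv")
        row = compute_metrics(counts, gt_clipped.flight_id or "flight", treatment)
        rows.append(row)
        histograms[(row.flight_id, treatment)] = iou_histogram(counts.overlap_ious)
        row_counts[f"matched_{treatment.value}"] = counts.tp
    timings["match"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    summaries = summarize_treatments(rows)
    written += render_report(rows, summaries, histograms, outdir / "report")
    timings["report"] = time.perf_counter() - t0

    seed = config.seed
    if seed is None and config.simulation is not None:
        seed = config.simulation.seed
    checksums = {str(p.relative_to(outdir)): _sha256(p) for p in sorted(written)}
    manifest = RunManifest(
        mode=config.mode,
        seed=seed,
        version=__version__,
        row_counts=row_counts,
        checksums=checksums,
        timings=timings,
        metric_rows=tuple(rows),
    )
    (outdir / "manifest.json").write_text(json.dumps(manifest.to_dict(), indent=2, sort_keys=True) + "\n")
    for name, duration in timings.items():
        logger.info("stage %s: %.3f s", name, duration)
    return manifest


# ---------------------------------------------------------------------------
# Published-counts cross-check


@dataclass(frozen=True)
class CountsCheckResult:
    """Recomputed metrics next to the published ones, with agreement flags."""

    table: pd.DataFrame
    mean_f1: Mapping[Treatment, float]
    mean_precision: Mapping[Treatment, float]
    mean_recall: Mapping[Treatment, float]


def packaged_counts_path() -> Path:
    """The packaged per-flight TP/FP/FN fixture transcribed from the study report."""
    return Path(resources.files("droneval") / "data" / "flight_counts.csv")


def check_published_counts(counts_csv: str | Path | None = None) -> CountsCheckResult:
    """Recompute precision/recall/F1 from published per-flight counts and flag
    each row's agreement (±0.05, i.e. one-decimal rounding) with the published
    metric values when those are present in the file."""
    path = Path(counts_csv) if counts_csv is not None else packaged_counts_path()
    df = pd.read_csv(path)
    required = {"flight", "sensor", "tp", "fp", "fn"}
    if not required.issubset(df.columns):
        raise ValidationError(f"counts file must have columns {sorted(required)}")
    recomputed = df.apply(
        lambda r: metrics_from_counts(int(r.tp), int(r.fp), int(r.fn)),
        axis=1, result_type="expand",
    )
    recomputed.columns = ["precision_rc", "recall_rc", "f1_rc"]
    out = pd.concat([df, recomputed], axis=1)
    for col in ("precision", "recall", "f1"):
        if col in df.columns:
            out[f"{col}_agrees"] = (out[f"{col}_rc"] - out[col]).abs() <= 0.05
    mean_f1: dict[Treatment, float] = {}
    mean_precision: dict[Treatment, float] = {}
    mean_recall: dict[Treatment, float] = {}
    for label, group in out.groupby("sensor", sort=False):
        treatment = _SENSOR_LABELS.get(str(label))
        if treatment is None:
            raise ValidationError(f"unknown sensor label {label!r}")
        mean_f1[treatment] = float(group["f1_rc"].mean())
        mean_precision[treatment] = float(group["precision_rc"].mean())
        mean_recall[treatment] = float(group["recall_rc"].mean())
    return CountsCheckResult(
        table=out,
        mean_f1=mean_f1,
        mean_precision=mean_precision,
        mean_recall=mean_recall,
    )


def published_metric_rows(counts_csv: str | Path | None = None) -> list[MetricRow]:
    """The packaged published counts as MetricRow records (metrics recomputed
    from the counts), in file order."""
    path = Path(counts_csv) if counts_csv is not None else packaged_counts_path()
    df = pd.read_csv(path)
    rows = []
    for _, r in df.iterrows():
        treatment = _SENSOR_LABELS[str(r.sensor)]
        precision, recall, f1 = metrics_from_counts(int(r.tp), int(r.fp), int(r.fn))
        rows.append(MetricRow(
            flight_id=str(r.flight), treatment=treatment,
            tp=int(r.tp), fp=int(r.fp), fn=int(r.fn),
            precision=precision, recall=recall, f1=f1,
        ))
    return rows
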