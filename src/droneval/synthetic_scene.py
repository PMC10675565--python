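"""Synthetic flight generator.

Produces ground-truth dolphin tracks plus per-treatment model-detection
streams with the statistical structure the evaluation pipeline assumes:
animals surface and dive on a cycle, detectability falls off with depth
following a logistic curve scaled by the light reaching each sensor,
detected boxes get Gaussian corner jitter, and clutter false positives
arrive as a Poisson stream.

Everything is deterministic given the master seed: per-animal and
per-treatment random streams are derived from it by fixed offsets, so the
three simulated cameras are conditionally independent given the shared
ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.optimize import minimize

from droneval.detection_io import (
    Box,
    Detection,
    DetectionSet,
    FrameRange,
    GroundTruthTrack,
    Source,
    Treatment,
    interpolate_track,
    tracks_to_detection_set,
)
from droneval.errors import ValidationError
from droneval.stream_sync import EventAnchor

# fixed seed offsets deriving per-treatment noise streams from the master seed
_TREATMENT_SEED_OFFSET = {Treatment.RGB: 1001, Treatment.GREEN: 2002, Treatment.GREEN_POL: 3003}

DEFAULT_PRESET = Path(__file__).parent / "data" / "default_preset.yaml"


@dataclass(frozen=True)
class AnimalModel:
    """Kinematic and dive-cycle parameters for one simulated animal."""

    animal_id: str
    start_x: float
    start_y: float
    speed: float = 2.0            # pixels/frame
    heading: float = 0.0          # radians, 0 = +x
    surface_duration: int = 60    # frames at depth 0
    dive_duration: int = 240      # frames below the surface
    max_depth: float = 6.0        # metres at the bottom of the dive
    body_width: float = 60.0      # pixels at the surface
    body_height: float = 25.0
    cycle_phase: int = 0          # frames into the cycle at frame 0

    def __post_init__(self) -> None:
        if self.surface_duration <= 0 or self.dive_duration <= 0:
            raise ValidationError("dive-cycle durations must be positive")
        if self.max_depth <= 0 or self.speed < 0:
            raise ValidationError("max_depth must be positive and speed non-negative")
        if self.body_width <= 0 or self.body_height <= 0:
            raise ValidationError("body box size must be positive")


@dataclass(frozen=True)
class TreatmentDetectability:
    """Depth-dependent detection model for one sensor treatment.

    Detection probability at depth d is ``light_fraction**gamma /
    (1 + exp((d - d50)/slope))`` — a logistic availability curve with 50%
    point ``d50`` scaled by the light penalty of the sensor's filters.
    """

    treatment: Treatment
    d50: float                    # metres
    slope: float = 0.5            # metres
    jitter_sd: float = 3.5        # pixels, per corner coordinate
    fp_rate: float = 0.0          # expected clutter boxes per frame
    light_fraction: float = 1.0   # relative light reaching the sensor

    def __post_init__(self) -> None:
        if self.d50 <= 0 or self.slope <= 0:
            raise ValidationError("d50 and slope must be positive")
        if self.jitter_sd < 0 or self.fp_rate < 0:
            raise ValidationError("jitter_sd and fp_rate must be non-negative")
        if not (0.0 < self.light_fraction <= 1.0):
            raise ValidationError("light_fraction must be in (0, 1]")

    def detection_probability(self, depth: float | np.ndarray, gamma: float = 0.5) -> np.ndarray:
        penalty = self.light_fraction ** gamma
        z = np.clip((np.asarray(depth, dtype=float) - self.d50) / self.slope, -700.0, 700.0)
        return penalty / (1.0 + np.exp(z))


@dataclass(frozen=True)
class SimulationConfig:
    n_frames: int
    animals: tuple[AnimalModel, ...]
    detectability: Mapping[Treatment, TreatmentDetectability]
    camera_offsets: Mapping[Treatment, int] = field(
        default_factory=lambda: {t: 0 for t in Treatment}
    )
    seed: int = 0
    frame_width: int = 3840
    frame_height: int = 2160
    fps: int = 30
    light_gamma: float = 0.5
    annotation_margin: float = 1.0   # metres beyond the deepest d50 still annotated
    max_extension: int = 60          # frames the last box is held after disappearance
    heading_noise_sd: float = 0.03   # radians/frame
    flight_id: str = "sim"
    class_label: str = "dolphin"

    def __post_init__(self) -> None:
        if self.n_frames <= 0:
            raise ValidationError("n_frames must be positive")
        if not self.animals:
            raise ValidationError("at least one animal is required")
        if not self.detectability:
            raise ValidationError("at least one treatment detectability is required")

    @property
    def annotation_cutoff(self) -> float:
        """Depth (m) down to which the annotator still boxes the animal:
        the deepest treatment d50 plus a sightability margin."""
        return max(d.d50 for d in self.detectability.values()) + self.annotation_margin

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_frames": self.n_frames,
            "seed": self.seed,
            "frame_width": self.frame_width,
            "frame_height": self.frame_height,
            "fps": self.fps,
            "light_gamma": self.light_gamma,
            "annotation_margin": self.annotation_margin,
            "max_extension": self.max_extension,
            "heading_noise_sd": self.heading_noise_sd,
            "flight_id": self.flight_id,
            "class_label": self.class_label,
            "camera_offsets": {t.value: int(o) for t, o in self.camera_offsets.items()},
            "animals": [
                {
                    "animal_id": a.animal_id,
                    "start_x": a.start_x,
                    "start_y": a.start_y,
                    "speed": a.speed,
                    "heading": a.heading,
                    "surface_duration": a.surface_duration,
                    "dive_duration": a.dive_duration,
                    "max_depth": a.max_depth,
                    "body_width": a.body_width,
                    "body_height": a.body_height,
                    "cycle_phase": a.cycle_phase,
                }
                for a in self.animals
            ],
            "detectability": {
                t.value: {
                    "d50": d.d50,
                    "slope": d.slope,
                    "jitter_sd": d.jitter_sd,
                    "fp_rate": d.fp_rate,
                    "light_fraction": d.light_fraction,
                }
                for t, d in self.detectability.items()
            },
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        animals = tuple(AnimalModel(**a) for a in data["animals"])
        detectability = {
            Treatment(t): TreatmentDetectability(treatment=Treatment(t), **d)
            for t, d in data["detectability"].items()
        }
        offsets = {Treatment(t): int(o) for t, o in data.get("camera_offsets", {}).items()}
        kwargs = {
            k: data[k]
            for k in (
                "n_frames", "seed", "frame_width", "frame_height", "fps", "light_gamma",
                "annotation_margin", "max_extension", "heading_noise_sd", "flight_id",
                "class_label",
            )
            if k in data
        }
        return cls(animals=animals, detectability=detectability,
                   camera_offsets=offsets or {t: 0 for t in Treatment}, **kwargs)


def load_config(path: str | Path) -> SimulationConfig:
    with Path(path).open() as fh:
        return SimulationConfig.from_dict(yaml.safe_load(fh))


def save_config(config: SimulationConfig, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def default_config(**overrides) -> SimulationConfig:
    """The packaged default preset, optionally overridden field-by-field."""
    config = load_config(DEFAULT_PRESET)
    return replace(config, **overrides) if overrides else config


# ---------------------------------------------------------------------------
# Ground truth


def depth_series(animal: AnimalModel, n_frames: int) -> np.ndarray:
    """Per-frame depth in metres: 0 while surfaced, a half-sine down to
    ``max_depth`` while diving; continuous and 0 at each surfacing."""
    cycle = animal.surface_duration + animal.dive_duration
    t = (np.arange(n_frames) + animal.cycle_phase) % cycle
    depth = np.zeros(n_frames)
    diving = t >= animal.surface_duration
    phase = (t[diving] - animal.surface_duration) / animal.dive_duration
    depth[diving] = animal.max_depth * np.sin(np.pi * phase)
    return depth


def simulate_tracks(
    config: SimulationConfig,
) -> tuple[list[GroundTruthTrack], dict[str, np.ndarray]]:
    """Simulate trajectories and produce annotated ground-truth tracks.

    Keyframes exist on every frame where the animal is shallower than the
    annotation cutoff; gaps and trailing frames are filled by
    :func:`interpolate_track`, mimicking manual annotation carried past the
    sightability limit.  Deterministic given the config seed.
    """
    cutoff = config.annotation_cutoff
    tracks: list[GroundTruthTrack] = []
    depths: dict[str, np.ndarray] = {}
    for index, animal in enumerate(config.animals):
        rng = np.random.default_rng([config.seed, 7 + index])
        depth = depth_series(animal, config.n_frames)
        half_w, half_h = animal.body_width / 2, animal.body_height / 2
        lo_x, hi_x = half_w, config.frame_width - half_w
        lo_y, hi_y = half_h, config.frame_height - half_h
        x = float(np.clip(animal.start_x, lo_x, hi_x))
        y = float(np.clip(animal.start_y, lo_y, hi_y))
        heading = animal.heading
        keyframes: list[tuple[int, Box]] = []
        for frame in range(config.n_frames):
            if depth[frame] < cutoff:
                keyframes.append((frame, Box(x - half_w, y - half_h, x + half_w, y + half_h)))
            heading += rng.normal(0.0, config.heading_noise_sd)
            x += animal.speed * math.cos(heading)
            y += animal.speed * math.sin(heading)
            # reflect off frame borders, flipping the heading component
            if x < lo_x or x > hi_x:
                x = min(max(2 * lo_x - x if x < lo_x else 2 * hi_x - x, lo_x), hi_x)
                heading = math.pi - heading
            if y < lo_y or y > hi_y:
                y = min(max(2 * lo_y - y if y < lo_y else 2 * hi_y - y, lo_y), hi_y)
                heading = -heading
        if not keyframes:
            raise ValidationError(
                f"animal {animal.animal_id} never rises above the annotation cutoff"
            )
        track = interpolate_track(
            GroundTruthTrack(animal.animal_id, tuple(keyframes)),
            max_extension=config.max_extension,
        )
        # the simulated timeline ends at n_frames - 1
        trimmed = {f: b for f, b in track.interpolated.items() if f < config.n_frames}
        tracks.append(GroundTruthTrack(track.animal_id, track.keyframes, trimmed))
        depths[animal.animal_id] = depth
    return tracks, depths


# ---------------------------------------------------------------------------
# Model detections


def _sanitize_box(coords: np.ndarray, width: int, height: int, min_size: float = 1.0) -> Box:
    x0, x1 = sorted((float(coords[0]), float(coords[2])))
    y0, y1 = sorted((float(coords[1]), float(coords[3])))
    x0, x1 = max(0.0, x0), min(float(width), x1)
    y0, y1 = max(0.0, y0), min(float(height), y1)
    if x1 - x0 < min_size:
        mid = min(max((x0 + x1) / 2, min_size / 2), width - min_size / 2)
        x0, x1 = mid - min_size / 2, mid + min_size / 2
    if y1 - y0 < min_size:
        mid = min(max((y0 + y1) / 2, min_size / 2), height - min_size / 2)
        y0, y1 = mid - min_size / 2, mid + min_size / 2
    return Box(x0, y0, x1, y1)


def simulate_detection_outcomes(
    tracks: Sequence[GroundTruthTrack],
    depths: Mapping[str, np.ndarray],
    detectability: TreatmentDetectability,
    seed: int,
    gamma: float = 0.5,
) -> list[tuple[str, int, float, bool]]:
    """Per (animal, frame) Bernoulli detection trials.

    Returns (animal_id, frame, depth, detected) tuples in deterministic
    order.  Uniform draws are consumed for every trial regardless of outcome,
    so the detected set grows monotonically with d50 under a shared seed.
    """
    rng = np.random.default_rng([seed, 1])
    outcomes = []
    items = []
    for track in sorted(tracks, key=lambda t: t.animal_id):
        for frame in track.boxes_by_frame():
            items.append((track.animal_id, frame))
    items.sort(key=lambda it: (it[1], it[0]))  # frame-major, animal-minor
    for animal_id, frame in items:
        d = float(depths[animal_id][frame])
        p = float(detectability.detection_probability(d, gamma))
        outcomes.append((animal_id, frame, d, bool(rng.random() < p)))
    return outcomes


def simulate_detections(
    tracks: Sequence[GroundTruthTrack],
    depths: Mapping[str, np.ndarray],
    detectability: TreatmentDetectability,
    seed: int,
    *,
    frame_width: int = 3840,
    frame_height: int = 2160,
    n_frames: int | None = None,
    gamma: float = 0.5,
    flight_id: str = "sim",
    class_label: str = "dolphin",
) -> DetectionSet:
    """Simulate one treatment's model-detection stream on the truth timeline.

    Each ground-truth box is detected independently with the depth-dependent
    probability; detected boxes receive Gaussian corner jitter and a uniform
    [0.5, 1] confidence.  Clutter boxes arrive Poisson(``fp_rate``) per frame
    at uniform positions with sizes drawn near the animal body sizes.
    """
    outcomes = simulate_detection_outcomes(tracks, depths, detectability, seed, gamma)
    rng_jitter = np.random.default_rng([seed, 2])
    rng_conf = np.random.default_rng([seed, 3])
    rng_clutter = np.random.default_rng([seed, 4])
    boxes_by_track = {t.animal_id: t.boxes_by_frame() for t in tracks}
    detections: list[Detection] = []
    for animal_id, frame, _depth, detected in outcomes:
        jitter = rng_jitter.normal(0.0, detectability.jitter_sd, 4) if detectability.jitter_sd > 0 else np.zeros(4)
        conf = float(rng_conf.uniform(0.5, 1.0))
        if not detected:
            continue
        gt_box = boxes_by_track[animal_id][frame]
        coords = np.array([gt_box.x_min, gt_box.y_min, gt_box.x_max, gt_box.y_max]) + jitter
        detections.append(Detection(
            frame_index=frame,
            box=_sanitize_box(coords, frame_width, frame_height),
            source=Source.MODEL,
            confidence=conf,
            class_label=class_label,
        ))
    last_frame = max((f for bx in boxes_by_track.values() for f in bx), default=0)
    if n_frames is None:
        n_frames = last_frame + 1
    n_frames = max(n_frames, last_frame + 1)
    if detectability.fp_rate > 0:
        mean_w = float(np.mean([t_boxes[next(iter(t_boxes))].width
                                for t_boxes in boxes_by_track.values() if t_boxes]))
        mean_h = float(np.mean([t_boxes[next(iter(t_boxes))].height
                                for t_boxes in boxes_by_track.values() if t_boxes]))
        for frame in range(n_frames):
            for _ in range(int(rng_clutter.poisson(detectability.fp_rate))):
                w = max(2.0, float(rng_clutter.normal(mean_w, 0.2 * mean_w)))
                h = max(2.0, float(rng_clutter.normal(mean_h, 0.2 * mean_h)))
                cx = float(rng_clutter.uniform(0, frame_width))
                cy = float(rng_clutter.uniform(0, frame_height))
                conf = float(rng_clutter.uniform(0.5, 1.0))
                box = _sanitize_box(
                    np.array([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2]),
                    frame_width, frame_height,
                )
                detections.append(Detection(
                    frame_index=frame, box=box, source=Source.MODEL,
                    confidence=conf, class_label=class_label,
                ))
    detections.sort(key=lambda d: d.frame_index)
    return DetectionSet(
        flight_id=flight_id,
        treatment=detectability.treatment,
        frame_range=FrameRange(0, n_frames - 1),
        detections=tuple(detections),
        frame_width=frame_width,
        frame_height=frame_height,
    )


# ---------------------------------------------------------------------------
# Whole flights


@dataclass(frozen=True)
class FlightSimulation:
    """One simulated flight: shared truth plus three offset camera streams."""

    config: SimulationConfig
    tracks: tuple[GroundTruthTrack, ...]
    depths: Mapping[str, np.ndarray]
    ground_truth: DetectionSet
    model_sets: Mapping[Treatment, DetectionSet]
    anchors: tuple[EventAnchor, ...]


def surfacing_events(
    tracks: Sequence[GroundTruthTrack],
    depths: Mapping[str, np.ndarray],
    camera_offsets: Mapping[Treatment, int],
) -> list[EventAnchor]:
    """Event anchors at each moment an animal breaks the surface, expressed
    on every camera's (offset) timeline."""
    anchors = []
    if len(camera_offsets) < 2:
        return anchors  # an anchor needs at least two cameras
    for animal_id in sorted(depths):
        depth = depths[animal_id]
        for frame in range(len(depth)):
            if depth[frame] == 0.0 and (frame == 0 or depth[frame - 1] > 0.0):
                frames = {t.value: frame + off for t, off in camera_offsets.items()}
                if any(f < 0 for f in frames.values()):
                    continue
                anchors.append(EventAnchor(f"surface_{animal_id}_{frame}", frames))
    return anchors


def _shift_stream(dset: DetectionSet, offset: int) -> DetectionSet:
    if offset == 0:
        return dset
    from dataclasses import replace as _replace
    shifted = tuple(
        _replace(d, frame_index=d.frame_index + offset)
        for d in dset.detections
        if d.frame_index + offset >= 0
    )
    new_range = FrameRange(max(0, dset.frame_range.start + offset), dset.frame_range.end + offset)
    return _replace(dset, detections=shifted, frame_range=new_range)


def simulate_flight(config: SimulationConfig) -> FlightSimulation:
    """Simulate the full three-camera flight.

    A single shared ground truth is generated on the truth timeline; each
    treatment's model stream uses its own detectability and a noise stream
    derived from the master seed by a fixed offset, then has its planted
    integer camera offset applied.  Surfacing moments are exported as event
    anchors for the synchronisation stage.
    """
    tracks, depths = simulate_tracks(config)
    ground_truth = tracks_to_detection_set(
        tracks,
        flight_id=config.flight_id,
        treatment=Treatment.RGB,
        frame_width=config.frame_width,
        frame_height=config.frame_height,
        class_label=config.class_label,
    )
    model_sets: dict[Treatment, DetectionSet] = {}
    for treatment, det in config.detectability.items():
        sub_seed = config.seed + _TREATMENT_SEED_OFFSET[treatment]
        stream = simulate_detections(
            tracks, depths, det, sub_seed,
            frame_width=config.frame_width,
            frame_height=config.frame_height,
            n_frames=config.n_frames,
            gamma=config.light_gamma,
            flight_id=config.flight_id,
            class_label=config.class_label,
        )
        model_sets[treatment] = _shift_stream(stream, int(config.camera_offsets.get(treatment, 0)))
    anchors = surfacing_events(tracks, depths, {
        t: int(config.camera_offsets.get(t, 0)) for t in config.detectability
    })
    return FlightSimulation(
        config=config,
        tracks=tuple(tracks),
        depths=depths,
        ground_truth=ground_truth,
        model_sets=model_sets,
        anchors=tuple(anchors),
    )


# ---------------------------------------------------------------------------
# Parameter recovery


def fit_detection_curve(
    depths: np.ndarray,
    detected: np.ndarray,
    light_penalty: float = 1.0,
) -> tuple[float, float]:
    """Maximum-likelihood fit of the logistic depth-detectability curve.

    Fits p(d) = light_penalty / (1 + exp((d - d50)/slope)) to Bernoulli
    (depth, detected) pairs; returns (d50, slope).
    """
    depths = np.asarray(depths, dtype=float)
    detected = np.asarray(detected, dtype=bool)
    if depths.shape != detected.shape or depths.size == 0:
        raise ValidationError("depths and detected must be equal-length, non-empty arrays")

    def nll(params: np.ndarray) -> float:
        d50, log_slope = params
        slope = math.exp(log_slope)
        p = light_penalty / (1.0 + np.exp((depths - d50) / slope))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return -float(np.sum(np.where(detected, np.log(p), np.log1p(-p))))

    init = np.array([float(np.median(depths)), 0.0])
    res = minimize(nll, init, method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000})
    d50, log_slope = res.x
    return float(d50), float(math.exp(log_slope))
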