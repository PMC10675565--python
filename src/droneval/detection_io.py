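"""Bounding-box data model and CSV readers/writers.

Boxes use continuous pixel coordinates with origin at the top-left corner,
x increasing rightward and y downward.  Detection streams are exchanged in a
MOT-challenge-like CSV dialect (``frame,id,x,y,w,h,conf,class`` with ``x,y``
the top-left corner); ground-truth rows carry ``conf = -1``.

Frame indices are 0-based and frame ranges are inclusive at both ends.
All operations are value-semantic: inputs are never mutated.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from droneval.errors import ParseError, ValidationError

MOT_HEADER = ["frame", "id", "x", "y", "w", "h", "conf", "class"]
TRACK_HEADER = ["animal_id", "frame", "x_min", "y_min", "x_max", "y_max"]


class Treatment(str, enum.Enum):
    """Camera/sensor treatment labels."""

    RGB = "RGB"
    GREEN = "GREEN"
    GREEN_POL = "GREEN_POL"

    @property
    def display(self) -> str:
        return {"RGB": "RGB", "GREEN": "Green", "GREEN_POL": "Green/Pol"}[self.value]


class Source(str, enum.Enum):
    GROUND_TRUTH = "ground_truth"
    MODEL = "model"


@dataclass(frozen=True)
class Box:
    """Axis-aligned rectangle with strictly positive area."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValidationError(
                f"degenerate box ({self.x_min}, {self.y_min}, {self.x_max}, {self.y_max})"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))


@dataclass(frozen=True)
class FrameRange:
    """Inclusive range of 0-based frame indices."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValidationError(f"invalid frame range [{self.start}, {self.end}]")

    def __contains__(self, frame: int) -> bool:
        return self.start <= frame <= self.end

    def __len__(self) -> int:
        return self.end - self.start + 1

    def intersection(self, other: "FrameRange") -> "FrameRange | None":
        lo, hi = max(self.start, other.start), min(self.end, other.end)
        return FrameRange(lo, hi) if lo <= hi else None

    def shifted(self, delta: int) -> "FrameRange":
        return FrameRange(self.start + delta, self.end + delta)


@dataclass(frozen=True)
class Detection:
    """One box on one frame, from either the annotator or the model."""

    frame_index: int
    box: Box
    source: Source
    animal_id: str | None = None
    confidence: float | None = None
    class_label: str = "dolphin"

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValidationError(f"negative frame index {self.frame_index}")
        if self.source is Source.GROUND_TRUTH and self.animal_id is None:
            raise ValidationError("ground-truth detection requires animal_id")
        if self.source is Source.MODEL:
            if self.confidence is None or not (0.0 <= self.confidence <= 1.0):
                raise ValidationError(
                    f"model detection requires confidence in [0, 1], got {self.confidence}"
                )


@dataclass(frozen=True)
class DetectionSet:
    """An ordered detection stream for one flight and one treatment."""

    flight_id: str
    treatment: Treatment
    frame_range: FrameRange
    detections: tuple[Detection, ...]
    frame_width: int
    frame_height: int

    def __post_init__(self) -> None:
        if self.frame_width <= 0 or self.frame_height <= 0:
            raise ValidationError("frame dimensions must be positive")
        for det in self.detections:
            if det.frame_index not in self.frame_range:
                raise ValidationError(
                    f"detection at frame {det.frame_index} outside range "
                    f"[{self.frame_range.start}, {self.frame_range.end}]"
                )
            b = det.box
            if b.x_min < 0 or b.y_min < 0 or b.x_max > self.frame_width or b.y_max > self.frame_height:
                raise ValidationError(
                    f"box {b} outside frame {self.frame_width}x{self.frame_height}"
                )

    def __len__(self) -> int:
        return len(self.detections)

    def by_frame(self) -> dict[int, list[Detection]]:
        """Detections grouped by frame, preserving within-frame row order."""
        out: dict[int, list[Detection]] = {}
        for det in self.detections:
            out.setdefault(det.frame_index, []).append(det)
        return out


@dataclass(frozen=True)
class GroundTruthTrack:
    """Keyframed box sequence for one animal.

    ``keyframes`` are the annotated (frame, box) pairs in strictly increasing
    frame order; ``interpolated`` holds boxes produced by
    :func:`interpolate_track` rather than annotation.
    """

    animal_id: str
    keyframes: tuple[tuple[int, Box], ...]
    interpolated: Mapping[int, Box] = field(default_factory=dict)

    def __post_init__(self) -> None:
        frames = [f for f, _ in self.keyframes]
        if any(b >= a for a, b in zip(frames[1:], frames)):
            raise ValidationError(f"keyframes of {self.animal_id} not strictly increasing")
        if set(frames) & set(self.interpolated):
            raise ValidationError("interpolated frames overlap keyframe indices")

    @property
    def interpolated_frames(self) -> frozenset[int]:
        return frozenset(self.interpolated)

    def boxes_by_frame(self) -> dict[int, Box]:
        """All covered frames (keyframed plus interpolated), in frame order."""
        merged = dict(self.keyframes)
        merged.update(self.interpolated)
        return dict(sorted(merged.items()))


# ---------------------------------------------------------------------------
# CSV I/O


def _fmt(value: float) -> str:
    # str() of a float is the shortest round-tripping repr
    return str(int(value)) if float(value).is_integer() else str(float(value))


def read_detections(
    path: str | Path,
    dialect: str = "mot_csv",
    *,
    flight_id: str = "",
    treatment: Treatment = Treatment.RGB,
    frame_width: int = 3840,
    frame_height: int = 2160,
    frame_range: FrameRange | None = None,
    class_label_default: str = "dolphin",
) -> DetectionSet:
    """Read a detection stream from a mot_csv file.

    Rows with ``conf < 0`` are ground truth (the ``id`` column is the animal
    identity); other rows are model detections.  ``frame_range`` defaults to
    the span of the frames present (``[0, 0]`` for an empty file).
    """
    if dialect != "mot_csv":
        raise ValidationError(f"unknown dialect {dialect!r}")
    path = Path(path)
    detections: list[Detection] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != MOT_HEADER:
            raise ParseError(f"expected header {','.join(MOT_HEADER)!r}", line=1)
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 8:
                raise ParseError(f"expected 8 fields, got {len(row)}", line=lineno)
            try:
                frame = int(row[0])
                ident = row[1].strip()
                x, y, w, h = (float(v) for v in row[2:6])
                conf = float(row[6])
            except ValueError as exc:
                raise ParseError(str(exc), line=lineno) from None
            if w <= 0 or h <= 0:
                raise ValidationError(f"line {lineno}: non-positive box size w={w} h={h}")
            box = Box(x, y, x + w, y + h)
            if conf < 0:
                det = Detection(frame, box, Source.GROUND_TRUTH, animal_id=ident,
                                class_label=row[7].strip() or class_label_default)
            else:
                det = Detection(frame, box, Source.MODEL, confidence=conf,
                                class_label=row[7].strip() or class_label_default)
            detections.append(det)
    if frame_range is None:
        frames = [d.frame_index for d in detections]
        frame_range = FrameRange(min(frames), max(frames)) if frames else FrameRange(0, 0)
    return DetectionSet(
        flight_id=flight_id,
        treatment=treatment,
        frame_range=frame_range,
        detections=tuple(detections),
        frame_width=frame_width,
        frame_height=frame_height,
    )


def write_detections(dset: DetectionSet, path: str | Path) -> None:
    """Write a detection stream in the mot_csv dialect (conf −1 marks ground truth)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MOT_HEADER)
        for det in dset.detections:
            b = det.box
            if det.source is Source.GROUND_TRUTH:
                ident, conf = det.animal_id, -1.0
            else:
                ident, conf = "-1", det.confidence
            writer.writerow([
                det.frame_index,
                ident,
                _fmt(b.x_min),
                _fmt(b.y_min),
                _fmt(b.width),
                _fmt(b.height),
                _fmt(conf),
                det.class_label,
            ])


def read_track_keyframes(path: str | Path) -> list[GroundTruthTrack]:
    """Read annotated keyframes from a CSV with columns
    ``animal_id,frame,x_min,y_min,x_max,y_max`` (corner coordinates)."""
    path = Path(path)
    per_animal: dict[str, list[tuple[int, Box]]] = {}
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != TRACK_HEADER:
            raise ParseError(f"expected header {','.join(TRACK_HEADER)!r}", line=1)
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 6:
                raise ParseError(f"expected 6 fields, got {len(row)}", line=lineno)
            try:
                ident = row[0].strip()
                frame = int(row[1])
                box = Box(*(float(v) for v in row[2:6]))
            except (ValueError, ValidationError) as exc:
                raise ParseError(str(exc), line=lineno) from None
            per_animal.setdefault(ident, []).append((frame, box))
    tracks = []
    for ident, keyframes in per_animal.items():
        keyframes.sort(key=lambda kv: kv[0])
        tracks.append(GroundTruthTrack(animal_id=ident, keyframes=tuple(keyframes)))
    return tracks


def write_track_keyframes(tracks: Iterable[GroundTruthTrack], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(TRACK_HEADER)
        for track in tracks:
            for frame, box in track.keyframes:
                writer.writerow([track.animal_id, frame, _fmt(box.x_min), _fmt(box.y_min),
                                 _fmt(box.x_max), _fmt(box.y_max)])


# ---------------------------------------------------------------------------
# Stream transforms


def clip_to_frame_range(dset: DetectionSet, frame_range: FrameRange) -> DetectionSet:
    """Keep only detections whose frame lies within ``frame_range`` (inclusive).

    The result's range is the intersection of the input range with the
    requested one; a disjoint request yields an empty set.
    """
    inter = dset.frame_range.intersection(frame_range)
    if inter is None:
        return replace(dset, detections=(), frame_range=frame_range)
    kept = tuple(d for d in dset.detections if d.frame_index in inter)
    return replace(dset, detections=kept, frame_range=inter)


def central_region_filter(dset: DetectionSet, central_fraction: float = 0.8) -> DetectionSet:
    """Drop detections whose box centre falls outside the centred rectangle
    covering ``central_fraction`` of the frame in each dimension.

    Mirrors the restriction of the analysis to the middle of the frame where
    vignetting and filter phase shift are negligible.
    """
    if not (0.0 < central_fraction <= 1.0):
        raise ValidationError(f"central_fraction must be in (0, 1], got {central_fraction}")
    half_w = 0.5 * central_fraction * dset.frame_width
    half_h = 0.5 * central_fraction * dset.frame_height
    cx, cy = 0.5 * dset.frame_width, 0.5 * dset.frame_height
    kept = []
    for det in dset.detections:
        bx, by = det.box.center
        if abs(bx - cx) <= half_w and abs(by - cy) <= half_h:
            kept.append(det)
    return replace(dset, detections=tuple(kept))


def interpolate_track(track: GroundTruthTrack, max_extension: int = 60) -> GroundTruthTrack:
    """Fill keyframe gaps by per-coordinate linear interpolation and hold the
    last annotated box for up to ``max_extension`` frames past the final
    keyframe (continuing the track while the animal fades from sightability).
    """
    if not track.keyframes:
        raise ValidationError(f"track {track.animal_id} has no keyframes")
    if max_extension < 0:
        raise ValidationError("max_extension must be non-negative")
    interpolated: dict[int, Box] = {}
    for (f0, b0), (f1, b1) in zip(track.keyframes, track.keyframes[1:]):
        span = f1 - f0
        for f in range(f0 + 1, f1):
            t = (f - f0) / span
            interpolated[f] = Box(
                (1 - t) * b0.x_min + t * b1.x_min,
                (1 - t) * b0.y_min + t * b1.y_min,
                (1 - t) * b0.x_max + t * b1.x_max,
                (1 - t) * b0.y_max + t * b1.y_max,
            )
    last_frame, last_box = track.keyframes[-1]
    for f in range(last_frame + 1, last_frame + 1 + max_extension):
        interpolated[f] = last_box
    return GroundTruthTrack(track.animal_id, track.keyframes, interpolated)


def tracks_to_detection_set(
    tracks: Sequence[GroundTruthTrack],
    *,
    flight_id: str,
    treatment: Treatment,
    frame_width: int,
    frame_height: int,
    frame_range: FrameRange | None = None,
    class_label: str = "dolphin",
) -> DetectionSet:
    """Flatten interpolated tracks to one ground-truth detection per
    (animal, frame) pair, ordered by frame then animal."""
    rows: list[tuple[int, str, Box]] = []
    seen: set[tuple[str, int]] = set()
    for track in tracks:
        for frame, box in track.boxes_by_frame().items():
            key = (track.animal_id, frame)
            if key in seen:
                raise ValidationError(f"duplicate box for animal {track.animal_id} at frame {frame}")
            seen.add(key)
            rows.append((frame, track.animal_id, box))
    rows.sort(key=lambda r: (r[0], r[1]))
    detections = tuple(
        Detection(frame, box, Source.GROUND_TRUTH, animal_id=ident, class_label=class_label)
        for frame, ident, box in rows
    )
    if frame_range is None:
        frames = [r[0] for r in rows]
        frame_range = FrameRange(min(frames), max(frames)) if frames else FrameRange(0, 0)
    return DetectionSet(
        flight_id=flight_id,
        treatment=treatment,
        frame_range=frame_range,
        detections=detections,
        frame_width=frame_width,
        frame_height=frame_height,
    )
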