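"""Cross-camera frame synchronisation from short-lived event anchors.

Each anchor is an event (e.g. a surfacing animal) whose frame index was noted
independently on each camera.  Per-camera integer offsets relative to a
reference camera are estimated as the median of per-event frame differences;
residuals flag anchors that disagree with the consensus offset.
"""

from __future__ import annotations

import csv
import json
import logging
import math
import statistics
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from droneval.detection_io import DetectionSet
from droneval.errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

ANCHOR_HEADER = ["event_id", "camera", "frame"]


@dataclass(frozen=True)
class EventAnchor:
    """A short-lived event seen on two or more cameras."""

    event_id: str
    frame_by_camera: Mapping[str, int]

    def __post_init__(self) -> None:
        if len(self.frame_by_camera) < 2:
            raise ValidationError(f"anchor {self.event_id} seen by fewer than 2 cameras")


@dataclass(frozen=True)
class SyncReport:
    """Estimated per-camera offsets plus per-event residual diagnostics."""

    reference_camera: str
    offset_by_camera: Mapping[str, int]
    max_abs_offset: int
    per_event_residuals: Mapping[str, Mapping[str, int]]
    tolerance: int
    passed: bool

    def to_dict(self) -> dict:
        return {
            "reference_camera": self.reference_camera,
            "offset_by_camera": dict(self.offset_by_camera),
            "max_abs_offset": self.max_abs_offset,
            "per_event_residuals": {e: dict(r) for e, r in self.per_event_residuals.items()},
            "tolerance": self.tolerance,
            "passed": self.passed,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")


def _round_half_away(x: float) -> int:
    return math.floor(x + 0.5) if x >= 0 else math.ceil(x - 0.5)


def estimate_offsets(
    anchors: Sequence[EventAnchor], reference: str, tolerance: int = 1
) -> SyncReport:
    """Estimate integer frame offsets of every camera relative to ``reference``.

    The offset of camera c is the median over anchors of
    ``frame_c - frame_reference``, rounded half away from zero; the median is
    robust to a single misidentified event.  Anchors missing a camera are
    skipped for that camera with a warning.
    """
    if not anchors:
        raise ValidationError("no event anchors supplied")
    for anchor in anchors:
        if reference not in anchor.frame_by_camera:
            raise ValidationError(
                f"anchor {anchor.event_id} does not include reference camera {reference!r}"
            )
    cameras = sorted({cam for a in anchors for cam in a.frame_by_camera})
    offsets: dict[str, int] = {reference: 0}
    for cam in cameras:
        if cam == reference:
            continue
        diffs = []
        for anchor in anchors:
            if cam in anchor.frame_by_camera:
                diffs.append(anchor.frame_by_camera[cam] - anchor.frame_by_camera[reference])
            else:
                logger.warning("anchor %s missing camera %s; skipped", anchor.event_id, cam)
        if not diffs:
            logger.warning("camera %s absent from every anchor; omitted from report", cam)
            continue
        offsets[cam] = _round_half_away(statistics.median(diffs))
    residuals: dict[str, dict[str, int]] = {}
    for anchor in anchors:
        ref_frame = anchor.frame_by_camera[reference]
        row = {}
        for cam, frame in anchor.frame_by_camera.items():
            if cam in offsets:
                row[cam] = (frame - ref_frame) - offsets[cam]
        residuals[anchor.event_id] = row
    max_abs = max(abs(v) for v in offsets.values())
    all_zero = all(r == 0 for row in residuals.values() for r in row.values())
    return SyncReport(
        reference_camera=reference,
        offset_by_camera=offsets,
        max_abs_offset=max_abs,
        per_event_residuals=residuals,
        tolerance=tolerance,
        passed=max_abs <= tolerance and all_zero,
    )


def verify_sync(report: SyncReport, tolerance: int = 1) -> bool:
    """True iff all offsets are within ``tolerance`` frames and every anchor
    agrees exactly with its camera's consensus offset."""
    all_zero = all(r == 0 for row in report.per_event_residuals.values() for r in row.values())
    return report.max_abs_offset <= tolerance and all_zero


def apply_offset(dset: DetectionSet, offset: int) -> DetectionSet:
    """Shift a stream by ``-offset`` frames so that streams with estimated
    offsets land on the reference camera's timeline."""
    if offset == 0:
        return dset
    new_range = dset.frame_range.shifted(-offset)
    if new_range.start < 0:
        raise ValidationError(
            f"offset {offset} would shift frame range to negative indices"
        )
    shifted = tuple(replace(d, frame_index=d.frame_index - offset) for d in dset.detections)
    return replace(dset, detections=shifted, frame_range=new_range)


# ---------------------------------------------------------------------------
# Anchor CSV I/O


def read_event_anchors(path: str | Path) -> list[EventAnchor]:
    """Read anchors from a CSV with columns ``event_id,camera,frame``."""
    path = Path(path)
    by_event: dict[str, dict[str, int]] = {}
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != ANCHOR_HEADER:
            raise ParseError(f"expected header {','.join(ANCHOR_HEADER)!r}", line=1)
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 3:
                raise ParseError(f"expected 3 fields, got {len(row)}", line=lineno)
            try:
                frame = int(row[2])
            except ValueError as exc:
                raise ParseError(str(exc), line=lineno) from None
            by_event.setdefault(row[0].strip(), {})[row[1].strip()] = frame
    return [EventAnchor(event_id=e, frame_by_camera=frames) for e, frames in by_event.items()]


def write_event_anchors(anchors: Iterable[EventAnchor], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(ANCHOR_HEADER)
        for anchor in anchors:
            for cam, frame in sorted(anchor.frame_by_camera.items()):
                writer.writerow([anchor.event_id, cam, frame])
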