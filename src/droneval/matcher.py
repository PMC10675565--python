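"""IoU computation and per-frame one-to-one box matching.

A model box counts as a true positive when it can be assigned one-to-one to a
ground-truth box with IoU at or above the threshold (default 0.5).  Unmatched
ground-truth boxes are false negatives.  For unmatched model boxes two
false-positive conventions are provided:

* ``paper_literal`` — a model box is a false positive only when it has zero
  overlap with every ground-truth box on its frame; sub-threshold overlaps
  are discarded (neither TP nor FP).
* ``strict`` — every unmatched model box is a false positive (COCO-style).

Matching is frame-wise only; class labels are ignored by default.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from droneval.detection_io import Box, DetectionSet
from droneval.errors import ValidationError


def iou(a: Box, b: Box) -> float:
    """Intersection over union of two boxes; 0 for disjoint, 1 for identical."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


@dataclass(frozen=True)
class MatchConfig:
    iou_threshold: float = 0.5
    assignment_mode: Literal["greedy", "optimal"] = "greedy"
    fp_mode: Literal["paper_literal", "strict"] = "paper_literal"
    require_class_match: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.iou_threshold <= 1.0):
            raise ValidationError(f"iou_threshold must be in (0, 1], got {self.iou_threshold}")
        if self.assignment_mode not in ("greedy", "optimal"):
            raise ValidationError(f"unknown assignment_mode {self.assignment_mode!r}")
        if self.fp_mode not in ("paper_literal", "strict"):
            raise ValidationError(f"unknown fp_mode {self.fp_mode!r}")


@dataclass(frozen=True)
class FrameMatchResult:
    """Assignment outcome for a single frame.

    Indices refer to positions in the gt/model sequences passed to
    :func:`match_frame`.  ``overlap_ious`` collects the IoU of every
    positively-overlapping (gt, model) pair regardless of threshold or
    assignment — the raw distribution used for threshold diagnostics.
    """

    frame_index: int
    matched_pairs: tuple[tuple[int, int, float], ...]
    unmatched_gt: tuple[int, ...]
    unmatched_model: tuple[int, ...]
    discarded_model: tuple[int, ...]
    overlap_ious: tuple[float, ...] = ()

    @property
    def tp(self) -> int:
        return len(self.matched_pairs)

    @property
    def fn(self) -> int:
        return len(self.unmatched_gt)

    @property
    def fp(self) -> int:
        return len(self.unmatched_model)


@dataclass(frozen=True)
class MatchCounts:
    tp: int
    fp: int
    fn: int
    matched_ious: tuple[float, ...] = ()
    overlap_ious: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValidationError("counts must be non-negative")
        if len(self.matched_ious) not in (0, self.tp):
            raise ValidationError("matched_ious length must equal tp")


def _greedy_assign(
    scores: np.ndarray, threshold: float
) -> list[tuple[int, int, float]]:
    candidates = [
        (scores[g, m], g, m)
        for g in range(scores.shape[0])
        for m in range(scores.shape[1])
        if scores[g, m] >= threshold
    ]
    # descending IoU; ties by smaller gt index then smaller model index
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    used_g: set[int] = set()
    used_m: set[int] = set()
    pairs = []
    for s, g, m in candidates:
        if g not in used_g and m not in used_m:
            pairs.append((g, m, float(s)))
            used_g.add(g)
            used_m.add(m)
    return pairs


def _optimal_assign(
    scores: np.ndarray, threshold: float
) -> list[tuple[int, int, float]]:
    # maximise cardinality first, then total IoU: an eligible pair is worth
    # BIG + iou with BIG exceeding any achievable IoU sum, so dropping a pair
    # can never be compensated by better IoUs elsewhere
    n_g, n_m = scores.shape
    if n_g == 0 or n_m == 0:
        return []
    big = float(max(n_g, n_m) + 1)
    eligible = scores >= threshold
    value = np.where(eligible, big + scores, 0.0)
    rows, cols = linear_sum_assignment(value, maximize=True)
    pairs = [
        (int(g), int(m), float(scores[g, m]))
        for g, m in zip(rows, cols)
        if eligible[g, m]
    ]
    pairs.sort(key=lambda p: (p[0], p[1]))
    return pairs


def match_frame(
    gt: Sequence[Box],
    model: Sequence[Box],
    config: MatchConfig = MatchConfig(),
    frame_index: int = 0,
) -> FrameMatchResult:
    """One-to-one assignment of model boxes to ground-truth boxes on a frame."""
    scores = np.zeros((len(gt), len(model)))
    for g, gbox in enumerate(gt):
        for m, mbox in enumerate(model):
            scores[g, m] = iou(gbox, mbox)
    if config.assignment_mode == "greedy":
        pairs = _greedy_assign(scores, config.iou_threshold)
    else:
        pairs = _optimal_assign(scores, config.iou_threshold)
    matched_g = {g for g, _, _ in pairs}
    matched_m = {m for _, m, _ in pairs}
    unmatched_gt = tuple(g for g in range(len(gt)) if g not in matched_g)
    fp: list[int] = []
    discarded: list[int] = []
    for m in range(len(model)):
        if m in matched_m:
            continue
        if config.fp_mode == "strict":
            fp.append(m)
        else:
            best = scores[:, m].max() if len(gt) else 0.0
            (discarded if best > 0.0 else fp).append(m)
    overlap = tuple(
        float(scores[g, m])
        for g in range(len(gt))
        for m in range(len(model))
        if scores[g, m] > 0.0
    )
    return FrameMatchResult(
        frame_index=frame_index,
        matched_pairs=tuple(pairs),
        unmatched_gt=unmatched_gt,
        unmatched_model=tuple(fp),
        discarded_model=tuple(discarded),
        overlap_ious=overlap,
    )


def match_sequence(
    gt_set: DetectionSet,
    model_set: DetectionSet,
    config: MatchConfig = MatchConfig(),
) -> tuple[MatchCounts, list[FrameMatchResult]]:
    """Sum per-frame matching over a common frame range.

    Both sets must already share a timeline and frame range; clip first with
    :func:`droneval.detection_io.clip_to_frame_range` otherwise.
    """
    if gt_set.frame_range != model_set.frame_range:
        raise ValidationError(
            "gt and model frame ranges differ "
            f"([{gt_set.frame_range.start}, {gt_set.frame_range.end}] vs "
            f"[{model_set.frame_range.start}, {model_set.frame_range.end}]); "
            "clip both to a common range first"
        )
    gt_frames = gt_set.by_frame()
    model_frames = model_set.by_frame()
    results: list[FrameMatchResult] = []
    tp = fp = fn = 0
    matched_ious: list[float] = []
    overlap_ious: list[float] = []
    for frame in sorted(set(gt_frames) | set(model_frames)):
        gt_dets = gt_frames.get(frame, [])
        model_dets = model_frames.get(frame, [])
        if config.require_class_match:
            # restricted multi-class mode: match within class label groups
            labels = sorted({d.class_label for d in gt_dets + model_dets})
            for label in labels:
                res = match_frame(
                    [d.box for d in gt_dets if d.class_label == label],
                    [d.box for d in model_dets if d.class_label == label],
                    config,
                    frame_index=frame,
                )
                results.append(res)
        else:
            results.append(match_frame(
                [d.box for d in gt_dets],
                [d.box for d in model_dets],
                config,
                frame_index=frame,
            ))
    for res in results:
        tp += res.tp
        fp += res.fp
        fn += res.fn
        matched_ious.extend(s for _, _, s in res.matched_pairs)
        overlap_ious.extend(res.overlap_ious)
    counts = MatchCounts(tp=tp, fp=fp, fn=fn,
                         matched_ious=tuple(matched_ious),
                         overlap_ious=tuple(overlap_ious))
    return counts, results


def write_frame_results(results: Sequence[FrameMatchResult], path: str | Path) -> None:
    """Dump per-frame match outcomes as CSV ``frame,kind,gt_id,model_row,iou``."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame", "kind", "gt_id", "model_row", "iou"])
        for res in results:
            for g, m, s in res.matched_pairs:
                writer.writerow([res.frame_index, "TP", g, m, f"{s:.6f}"])
            for g in res.unmatched_gt:
                writer.writerow([res.frame_index, "FN", g, "", ""])
            for m in res.unmatched_model:
                writer.writerow([res.frame_index, "FP", "", m, ""])
            for m in res.discarded_model:
                writer.writerow([res.frame_index, "DISCARDED", "", m, ""])
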