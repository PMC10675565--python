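"""Precision/recall/F1 per flight and treatment, plus report emission.

Metrics are computed directly from TP/FP/FN counts:

    precision = 100 * TP / (TP + FP)
    recall    = 100 * TP / (TP + FN)
    F1        = 100 * TP / (TP + 0.5 * (FP + FN))

F1 is always derived from the counts, never from rounded precision/recall.
A zero denominator yields the NaN sentinel ``UNDEFINED``; undefined values
are excluded from treatment means.  Display rounding is one decimal, half
away from zero.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from droneval.detection_io import Treatment
from droneval.errors import ValidationError
from droneval.matcher import MatchCounts

UNDEFINED = float("nan")


def is_defined(value: float) -> bool:
    return not math.isnan(value)


def round_display(value: float, ndigits: int = 1) -> float:
    """Round half away from zero (banker's rounding would disagree with the
    reporting convention on ties like 48.95)."""
    if not is_defined(value):
        return UNDEFINED
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MetricRow:
    """Per-flight, per-treatment metric record (percent scale, unrounded)."""

    flight_id: str
    treatment: Treatment
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float

    def display(self) -> dict:
        return {
            "Flight": self.flight_id,
            "Sensor": self.treatment.display,
            "TP": self.tp,
            "FP": self.fp,
            "FN": self.fn,
            "Precision": round_display(self.precision),
            "Recall": round_display(self.recall),
            "F1": round_display(self.f1),
        }


@dataclass(frozen=True)
class TreatmentSummary:
    treatment: Treatment
    n_flights: int
    mean_f1: float
    sd_f1: float
    mean_precision: float
    mean_recall: float


@dataclass(frozen=True)
class IoUHistogram:
    bin_edges: tuple[float, ...]
    counts: tuple[int, ...]
    peaks: tuple[float, ...]  # bin-centre locations of accepted local maxima

    def __post_init__(self) -> None:
        if len(self.bin_edges) != len(self.counts) + 1:
            raise ValidationError("bin_edges must have one more entry than counts")


def metrics_from_counts(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """(precision, recall, f1) in percent; NaN where the denominator is zero."""
    precision = 100.0 * tp / (tp + fp) if tp + fp > 0 else UNDEFINED
    recall = 100.0 * tp / (tp + fn) if tp + fn > 0 else UNDEFINED
    denom = tp + 0.5 * (fp + fn)
    f1 = 100.0 * tp / denom if denom > 0 else UNDEFINED
    return precision, recall, f1


def compute_metrics(counts: MatchCounts, flight_id: str, treatment: Treatment) -> MetricRow:
    precision, recall, f1 = metrics_from_counts(counts.tp, counts.fp, counts.fn)
    return MetricRow(
        flight_id=flight_id,
        treatment=treatment,
        tp=counts.tp,
        fp=counts.fp,
        fn=counts.fn,
        precision=precision,
        recall=recall,
        f1=f1,
    )


def _mean_sd(values: list[float]) -> tuple[float, float]:
    defined = [v for v in values if is_defined(v)]
    if not defined:
        return UNDEFINED, UNDEFINED
    mean = float(np.mean(defined))
    sd = float(np.std(defined, ddof=1)) if len(defined) > 1 else UNDEFINED
    return mean, sd


def summarize_treatments(rows: Sequence[MetricRow]) -> list[TreatmentSummary]:
    """Unweighted per-treatment means (and n−1 sd of F1) over flights.

    Treatments appear in first-encounter order; undefined per-flight values
    are excluded from the averages.
    """
    order: list[Treatment] = []
    grouped: dict[Treatment, list[MetricRow]] = {}
    for row in rows:
        if row.treatment not in grouped:
            order.append(row.treatment)
            grouped[row.treatment] = []
        grouped[row.treatment].append(row)
    summaries = []
    for treatment in order:
        group = grouped[treatment]
        mean_f1, sd_f1 = _mean_sd([r.f1 for r in group])
        mean_p, _ = _mean_sd([r.precision for r in group])
        mean_r, _ = _mean_sd([r.recall for r in group])
        summaries.append(TreatmentSummary(
            treatment=treatment,
            n_flights=len(group),
            mean_f1=mean_f1,
            sd_f1=sd_f1,
            mean_precision=mean_p,
            mean_recall=mean_r,
        ))
    return summaries


def iou_histogram(
    ious: Iterable[float],
    bin_width: float = 0.02,
    prominence_floor: float = 0.25,
) -> IoUHistogram:
    """Histogram of IoU values on fixed bins spanning [0, 1].

    A peak is an interior bin strictly greater than both neighbours whose
    count is at least ``prominence_floor`` times the maximum count.
    """
    values = np.asarray(list(ious), dtype=float)
    if values.size and (values.min() < 0 or values.max() > 1):
        raise ValidationError("IoU values must lie in [0, 1]")
    n_bins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(values, bins=edges)
    peaks: list[float] = []
    if counts.size and counts.max() > 0:
        floor = prominence_floor * counts.max()
        for i in range(1, len(counts) - 1):
            if counts[i] > counts[i - 1] and counts[i] > counts[i + 1] and counts[i] >= floor:
                peaks.append(float(0.5 * (edges[i] + edges[i + 1])))
    return IoUHistogram(
        bin_edges=tuple(float(e) for e in edges),
        counts=tuple(int(c) for c in counts),
        peaks=tuple(peaks),
    )


# ---------------------------------------------------------------------------
# Report emission


def _fmt_metric(value: float) -> str:
    return "NA" if not is_defined(value) else f"{round_display(value):.1f}"


def render_report(
    rows: Sequence[MetricRow],
    summaries: Sequence[TreatmentSummary],
    histograms: dict[tuple[str, Treatment], IoUHistogram] | None,
    output_dir: str | Path,
) -> list[Path]:
    """Write the flight×treatment metric table, a Markdown summary with an
    embedded JSON block, and per-flight histogram CSVs.  Returns the paths
    written, deterministically ordered."""
    if not rows:
        raise ValidationError("no metric rows to report")
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    table_path = outdir / "metrics.csv"
    with table_path.open("w", newline="") as fh:
        fh.write("Flight,Sensor,TP,FP,FN,Precision,Recall,F1\n")
        for row in rows:
            d = row.display()
            fh.write(
                f"{d['Flight']},{d['Sensor']},{d['TP']},{d['FP']},{d['FN']},"
                f"{_fmt_metric(row.precision)},{_fmt_metric(row.recall)},{_fmt_metric(row.f1)}\n"
            )
    written.append(table_path)

    md_path = outdir / "summary.md"
    lines = ["# Detection-reliability report", ""]
    lines.append(f"{len(rows)} flight-by-treatment rows evaluated.")
    lines.append("")
    if summaries:
        lines.append("| Sensor | n flights | mean F1 | sd F1 | mean precision | mean recall |")
        lines.append("|---|---|---|---|---|---|")
        for s in summaries:
            lines.append(
                f"| {s.treatment.display} | {s.n_flights} | {_fmt_metric(s.mean_f1)} | "
                f"{_fmt_metric(s.sd_f1)} | {_fmt_metric(s.mean_precision)} | "
                f"{_fmt_metric(s.mean_recall)} |"
            )
        payload = [
            {
                "treatment": s.treatment.value,
                "n_flights": s.n_flights,
                "mean_f1": None if not is_defined(s.mean_f1) else round(s.mean_f1, 6),
                "sd_f1": None if not is_defined(s.sd_f1) else round(s.sd_f1, 6),
                "mean_precision": None if not is_defined(s.mean_precision) else round(s.mean_precision, 6),
                "mean_recall": None if not is_defined(s.mean_recall) else round(s.mean_recall, 6),
            }
            for s in summaries
        ]
        lines += ["", "```json", json.dumps(payload, indent=2), "```"]
    else:
        lines.append("_No treatment summaries available._")
    md_path.write_text("\n".join(lines) + "\n")
    written.append(md_path)

    if histograms:
        for (flight_id, treatment), hist in sorted(
            histograms.items(), key=lambda kv: (kv[0][0], kv[0][1].value)
        ):
            hist_path = outdir / f"iou_hist_{flight_id}_{treatment.value}.csv"
            with hist_path.open("w", newline="") as fh:
                fh.write("bin_lo,bin_hi,count\n")
                for lo, hi, count in zip(hist.bin_edges, hist.bin_edges[1:], hist.counts):
                    fh.write(f"{lo:.6f},{hi:.6f},{count}\n")
            written.append(hist_path)
    return written
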