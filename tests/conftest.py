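import numpy as np
import pytest

from droneval.detection_io import (
    Box,
    Detection,
    DetectionSet,
    FrameRange,
    Source,
    Treatment,
)


def make_box(x, y, w, h):
    return Box(x, y, x + w, y + h)


def random_detection_set(
    rng: np.random.Generator,
    n: int,
    *,
    n_frames: int = 50,
    frame_width: int = 1000,
    frame_height: int = 800,
    source: Source = Source.MODEL,
    flight_id: str = "f1",
    treatment: Treatment = Treatment.RGB,
) -> DetectionSet:
    """Uniformly random valid detections for property tests."""
    dets = []
    for i in range(n):
        frame = int(rng.integers(0, n_frames))
        w = float(rng.uniform(5, 80))
        h = float(rng.uniform(5, 80))
        x = float(rng.uniform(0, frame_width - w))
        y = float(rng.uniform(0, frame_height - h))
        if source is Source.GROUND_TRUTH:
            det = Detection(frame, Box(x, y, x + w, y + h), source, animal_id=f"a{i}")
        else:
            det = Detection(frame, Box(x, y, x + w, y + h), source,
                            confidence=float(rng.uniform(0, 1)))
        dets.append(det)
    dets.sort(key=lambda d: d.frame_index)
    return DetectionSet(
        flight_id=flight_id,
        treatment=treatment,
        frame_range=FrameRange(0, n_frames - 1),
        detections=tuple(dets),
        frame_width=frame_width,
        frame_height=frame_height,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
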