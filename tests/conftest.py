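"""Shared builders for detection tracks and codings."""

from __future__ import annotations

import pytest

from ethotrack import BehaviorLabel, BoundingBox, Detection, DetectionTrack


def make_detection(
    frame: int,
    behavior=BehaviorLabel.LOCOMOTION,
    confidence: float = 0.9,
    box: tuple[float, float, float, float] = (10.0, 20.0, 100.0, 150.0),
    fps: float = 1.0,
) -> Detection:
    return Detection(
        frame_index=frame,
        time_s=frame / fps,
        behavior=behavior,
        confidence=confidence,
        box=BoundingBox(*box),
    )


def make_track(specs, total_frames=None, fps: float = 1.0) -> DetectionTrack:
    """Build a track from (frame, behavior[, confidence[, box]]) tuples."""
    detections = []
    for spec in specs:
        frame, behavior = spec[0], spec[1]
        confidence = spec[2] if len(spec) > 2 else 0.9
        box = spec[3] if len(spec) > 3 else (10.0, 20.0, 100.0, 150.0)
        detections.append(make_detection(frame, behavior, confidence, box, fps))
    if total_frames is None:
        total_frames = max((d.frame_index for d in detections), default=-1) + 1
    return DetectionTrack(tuple(detections), total_frames=total_frames, fps=fps)


@pytest.fixture
def simple_track() -> DetectionTrack:
    B = BehaviorLabel
    return make_track(
        [
            (0, B.LOCOMOTION, 0.95),
            (1, B.INACTIVE, 0.85),
            (3, B.FORAGING_FEEDING, 0.79),
            (5, B.COVERED_INACTIVE, 0.90),
        ],
        total_frames=10,
    )
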