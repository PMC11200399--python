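"""Gross-posture calls from the label box's height/width ratio.

The box around a sitting ape is roughly as tall as it is wide; arms raised
overhead stretch it tall, lying down flattens it. Two ratio limits therefore
give a cheap posture channel on top of the behavior label: ratio at or above
the upper limit -> Arms Up, at or below the lower limit -> Lying Down,
otherwise Neutral. Boundaries are inclusive toward the extreme call.

The default limits (2.0 / 0.6) are placeholders: calibrate them on frames of
the actual subject and camera before real use.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum

from .labels import BoundingBox
from .records import DetectionTrack


class Posture(str, Enum):
    ARMS_UP = "Arms Up"
    LYING_DOWN = "Lying Down"
    NEUTRAL = "Neutral"

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class RatioConfig:
    """Upper/lower height-width ratio limits, dimensionless."""

    upper_limit: float = 2.0
    lower_limit: float = 0.6

    def __post_init__(self) -> None:
        if not 0 < self.lower_limit < self.upper_limit:
            raise ValueError(
                f"need 0 < lower_limit < upper_limit, got "
                f"({self.lower_limit}, {self.upper_limit})"
            )


@dataclass(frozen=True)
class PostureCall:
    frame_index: int
    ratio: float
    posture: Posture


@dataclass(frozen=True)
class PostureSeries:
    """Per-frame posture calls plus summary counts."""

    calls: tuple[PostureCall, ...]
    counts: dict[Posture, int]

    def __len__(self) -> int:
        return len(self.calls)


def compute_ratio(box: BoundingBox) -> float:
    """Height/width ratio of a label box (width must be positive)."""
    if box.width <= 0:
        raise ValueError(f"box width must be positive, got {box.width}")
    return box.height / box.width


def classify_posture(ratio: float, cfg: RatioConfig | None = None) -> Posture:
    """Pure threshold rule on the ratio; boundaries go to the extreme call."""
    cfg = cfg or RatioConfig()
    if ratio <= 0:
        raise ValueError(f"ratio must be positive, got {ratio}")
    if ratio >= cfg.upper_limit:
        return Posture.ARMS_UP
    if ratio <= cfg.lower_limit:
        return Posture.LYING_DOWN
    return Posture.NEUTRAL


def posture_series(
    track: DetectionTrack, cfg: RatioConfig | None = None
) -> PostureSeries:
    """One posture call per detection, in frame order, with summary counts."""
    cfg = cfg or RatioConfig()
    calls = tuple(
        PostureCall(
            frame_index=det.frame_index,
            ratio=compute_ratio(det.box),
            posture=classify_posture(compute_ratio(det.box), cfg),
        )
        for det in track
    )
    counts = Counter(call.posture for call in calls)
    return PostureSeries(
        calls=calls, counts={p: counts.get(p, 0) for p in Posture}
    )


__all__ = [
    "Posture",
    "RatioConfig",
    "PostureCall",
    "PostureSeries",
    "compute_ratio",
    "classify_posture",
    "posture_series",
]
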