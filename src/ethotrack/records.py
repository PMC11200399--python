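"""In-memory containers for detection streams and manual codings.

A session is a sequence of frames (~1 frame/s here). The detector sees a
single focal subject, so a frame carries at most one detection; frames with
no detection are invisible in the detection records themselves, which is why
``total_frames`` travels alongside them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence, Union

from .labels import (
    DETECTION_LABEL_NAMES,
    BehaviorLabel,
    BoundingBox,
)

#: A detection label: one of the four detector categories, or — in corrected
#: files only — the False Positive Locomotion marker string.
DetectionLabel = Union[BehaviorLabel, str]

_TIME_TOL = 1e-6


def _label_name(label: DetectionLabel) -> str:
    return label.value if isinstance(label, BehaviorLabel) else str(label)


@dataclass(frozen=True)
class Detection:
    """One frame's box, behavior label, and model confidence."""

    frame_index: int
    time_s: float
    behavior: DetectionLabel
    confidence: float
    box: BoundingBox

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError(f"frame_index must be >= 0, got {self.frame_index}")
        name = _label_name(self.behavior)
        if name not in DETECTION_LABEL_NAMES:
            valid = ", ".join(repr(n) for n in DETECTION_LABEL_NAMES)
            raise ValueError(
                f"detection label {name!r} is not a detector category; "
                f"valid names are: {valid}"
            )
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")

    @property
    def behavior_name(self) -> str:
        return _label_name(self.behavior)


@dataclass(frozen=True)
class DetectionTrack:
    """Ordered single-subject detections plus total-frame context.

    Invariants: strictly increasing frame indices (at most one detection per
    frame — one focal subject), every index below ``total_frames``, and
    ``time_s == frame_index / fps`` for every detection.
    """

    detections: tuple[Detection, ...]
    total_frames: int
    fps: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "detections", tuple(self.detections))
        if self.total_frames < 0:
            raise ValueError("total_frames must be >= 0")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if len(self.detections) > self.total_frames:
            raise ValueError(
                f"{len(self.detections)} detections exceed total_frames="
                f"{self.total_frames}"
            )
        prev = -1
        for det in self.detections:
            if det.frame_index <= prev:
                raise ValueError(
                    f"frame indices must be strictly increasing; "
                    f"frame {det.frame_index} follows {prev}"
                )
            if det.frame_index >= self.total_frames:
                raise ValueError(
                    f"frame {det.frame_index} outside [0, {self.total_frames})"
                )
            expected = det.frame_index / self.fps
            if abs(det.time_s - expected) > _TIME_TOL:
                raise ValueError(
                    f"frame {det.frame_index}: time_s={det.time_s} inconsistent "
                    f"with fps={self.fps} (expected {expected})"
                )
            prev = det.frame_index

    def __len__(self) -> int:
        return len(self.detections)

    def __iter__(self):
        return iter(self.detections)

    def with_detections(self, detections: Iterable[Detection]) -> "DetectionTrack":
        """Same session context, different detection list."""
        return replace(self, detections=tuple(detections))


@dataclass(frozen=True)
class ManualCoding:
    """Continuous focal sampling: one ethogram category per frame.

    Every frame in ``[0, total_frames)`` must be coded exactly once; gaps or
    duplicates are rejected with the offending frames listed.
    """

    records: tuple[tuple[int, BehaviorLabel], ...]
    total_frames: int = field(default=-1)

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        total = self.total_frames
        if total < 0:
            total = len(self.records)
            object.__setattr__(self, "total_frames", total)
        seen = [False] * total
        dupes: list[int] = []
        for frame, label in self.records:
            if not isinstance(label, BehaviorLabel):
                raise ValueError(f"frame {frame}: not an ethogram category: {label!r}")
            if not 0 <= frame < total:
                raise ValueError(f"frame {frame} outside [0, {total})")
            if seen[frame]:
                dupes.append(frame)
            seen[frame] = True
        if dupes:
            raise ValueError(f"duplicate frames in manual coding: {_preview(dupes)}")
        gaps = [i for i, s in enumerate(seen) if not s]
        if gaps:
            raise ValueError(
                f"manual coding incomplete; missing frames: {_preview(gaps)}"
            )

    def __len__(self) -> int:
        return self.total_frames

    def behaviors_by_frame(self) -> Sequence[BehaviorLabel]:
        ordered: list[BehaviorLabel] = [BehaviorLabel.OTHER] * self.total_frames
        for frame, label in self.records:
            ordered[frame] = label
        return ordered


def _preview(frames: Sequence[int], limit: int = 10) -> str:
    head = ", ".join(str(f) for f in frames[:limit])
    return head + (", ..." if len(frames) > limit else "")
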