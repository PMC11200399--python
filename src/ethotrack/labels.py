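"""Behavior categories and geometric primitives for detection records.

The ethogram has six categories. The object-detection model emits only the
first four; ``Out of View/Not Labeled`` absorbs every frame without a
(confident) detection, and ``Other`` exists only in manual codings. After
plateau correction a fifth model-side category, ``False Positive Locomotion``,
appears in corrected outputs; it is deliberately *not* an ethogram category.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class BehaviorLabel(str, Enum):
    """The six ethogram categories. Values are the canonical display names."""

    LOCOMOTION = "Locomotion"
    INACTIVE = "Inactive"
    COVERED_INACTIVE = "Covered Inactive"
    FORAGING_FEEDING = "Foraging/Feeding"
    OUT_OF_VIEW_NOT_LABELED = "Out of View/Not Labeled"
    OTHER = "Other"

    def __str__(self) -> str:  # serialize as the display name
        return self.value


#: Categories the detector can emit.
DETECTOR_LABELS: tuple[BehaviorLabel, ...] = (
    BehaviorLabel.LOCOMOTION,
    BehaviorLabel.INACTIVE,
    BehaviorLabel.COVERED_INACTIVE,
    BehaviorLabel.FORAGING_FEEDING,
)

#: Extra category carried by *corrected* detection files (plateau-flagged
#: Locomotion frames). Kept out of :class:`BehaviorLabel` on purpose.
FALSE_POSITIVE_LOCOMOTION = "False Positive Locomotion"

#: Labels legal on a single detection record.
DETECTION_LABEL_NAMES = tuple(b.value for b in DETECTOR_LABELS) + (
    FALSE_POSITIVE_LOCOMOTION,
)


def parse_behavior(name: str) -> BehaviorLabel:
    """Map a display name to its :class:`BehaviorLabel`.

    Raises ``ValueError`` listing the valid names on an unknown category.
    """
    for label in BehaviorLabel:
        if label.value == name:
            return label
    valid = ", ".join(repr(b.value) for b in BehaviorLabel)
    raise ValueError(f"unknown behavior {name!r}; valid names are: {valid}")


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in pixel units, top-left image origin.

    Stored as (x_min, y_min, width, height); y grows downward, so the box's
    bottom corner — the point tracked for plateau analysis — is
    ``(x_min, y_min + height)``.
    """

    x_min: float
    y_min: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError(
                f"box width and height must be positive, got "
                f"({self.width}, {self.height})"
            )
        if self.x_min < 0 or self.y_min < 0:
            raise ValueError(
                f"box origin must be non-negative, got ({self.x_min}, {self.y_min})"
            )

    @property
    def bottom_corner(self) -> tuple[float, float]:
        return (self.x_min, self.y_min + self.height)

    @property
    def aspect_ratio(self) -> float:
        """Height/width ratio used for posture classification."""
        return self.height / self.width

    @classmethod
    def from_voc(cls, xmin: float, ymin: float, xmax: float, ymax: float) -> "BoundingBox":
        """Convert PASCAL-VOC corner coordinates to (x, y, w, h)."""
        if xmax <= xmin or ymax <= ymin:
            raise ValueError(
                f"degenerate VOC box: ({xmin}, {ymin}, {xmax}, {ymax})"
            )
        return cls(x_min=xmin, y_min=ymin, width=xmax - xmin, height=ymax - ymin)
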