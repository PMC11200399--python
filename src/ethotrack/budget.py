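"""Frame-level time budgets and manual-vs-model comparison.

A time budget is the fraction of total observation time (frames, at ~1
frame/s) spent in each ethogram category. The model-side budget folds every
frame without a surviving detection into ``Out of View/Not Labeled`` — the
detector cannot distinguish a subject that is genuinely out of view from one
it simply was not confident about.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from ._rounding import round_half_up
from .labels import (
    DETECTOR_LABELS,
    FALSE_POSITIVE_LOCOMOTION,
    BehaviorLabel,
)
from .records import DetectionTrack, ManualCoding

_UNLABELED = BehaviorLabel.OUT_OF_VIEW_NOT_LABELED.value
_DETECTOR_NAMES = tuple(b.value for b in DETECTOR_LABELS)


@dataclass(frozen=True)
class TimeBudget:
    """Per-category frame counts over a session.

    ``counts`` is keyed by category display name (the six ethogram names,
    plus ``False Positive Locomotion`` in corrected model budgets) and always
    sums to ``total_frames``. ``percentages`` are unrounded; use
    :meth:`rounded` for display (one decimal, half up).
    """

    counts: Mapping[str, int]
    total_frames: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", dict(self.counts))
        if self.total_frames <= 0:
            raise ValueError("total_frames must be positive")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative category count")
        total = sum(self.counts.values())
        if total != self.total_frames:
            raise ValueError(
                f"category counts sum to {total}, expected total_frames="
                f"{self.total_frames}"
            )

    @property
    def percentages(self) -> dict[str, float]:
        return {
            name: 100.0 * count / self.total_frames
            for name, count in self.counts.items()
        }

    def rounded(self) -> dict[str, float]:
        return {name: round_half_up(p, 1) for name, p in self.percentages.items()}

    def percent(self, category: str | BehaviorLabel) -> float:
        name = category.value if isinstance(category, BehaviorLabel) else category
        return 100.0 * self.counts.get(name, 0) / self.total_frames


@dataclass(frozen=True)
class BudgetComparison:
    """Per-category (manual %, model %, model − manual) plus a summary.

    ``total_disagreement`` sums |model − manual| over the four detector
    categories only: ``Other`` is structurally absent from model output and
    the unlabeled category conflates out-of-view with low confidence.
    """

    rows: Mapping[str, tuple[float, float, float]]
    total_disagreement: float
    total_frames: int

    def rounded_rows(self) -> dict[str, tuple[float, float, float]]:
        return {
            name: tuple(round_half_up(v, 1) for v in row)  # type: ignore[misc]
            for name, row in self.rows.items()
        }


def apply_confidence_threshold(track: DetectionTrack, tau: float) -> DetectionTrack:
    """Drop detections below the acceptance threshold ``tau`` (inclusive: a
    detection at exactly ``tau`` survives). ``total_frames`` is unchanged —
    rejected frames become unlabeled, not nonexistent."""
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"tau must be in [0, 1], got {tau}")
    return track.with_detections(d for d in track if d.confidence >= tau)


def budget_from_detections(track: DetectionTrack) -> TimeBudget:
    """Model-side budget: one count per detection label, remainder unlabeled."""
    if track.total_frames <= 0:
        raise ValueError("cannot budget a session with total_frames == 0")
    counts: dict[str, int] = {name: 0 for name in _DETECTOR_NAMES}
    for det in track:
        counts[det.behavior_name] = counts.get(det.behavior_name, 0) + 1
    counts[_UNLABELED] = track.total_frames - len(track)
    return TimeBudget(counts=counts, total_frames=track.total_frames)


def budget_from_manual(coding: ManualCoding) -> TimeBudget:
    """Observer-side budget over all six ethogram categories."""
    if coding.total_frames <= 0:
        raise ValueError("cannot budget an empty manual coding")
    counts: dict[str, int] = {b.value: 0 for b in BehaviorLabel}
    for _, label in coding.records:
        counts[label.value] += 1
    return TimeBudget(counts=counts, total_frames=coding.total_frames)


def labeled_fraction(budget: TimeBudget) -> float:
    """Percent of frames carrying a surviving detection, one decimal."""
    return round_half_up(100.0 - budget.percent(_UNLABELED), 1)


def compare_budgets(manual: TimeBudget, model: TimeBudget) -> BudgetComparison:
    """Line up a manual and a model budget category by category.

    Differences are model − manual on unrounded percentages. Both budgets
    must cover the same session (equal ``total_frames``).
    """
    if manual.total_frames != model.total_frames:
        raise ValueError(
            f"budgets cover different sessions: {manual.total_frames} vs "
            f"{model.total_frames} frames"
        )
    categories = [b.value for b in BehaviorLabel]
    if FALSE_POSITIVE_LOCOMOTION in model.counts:
        categories.insert(
            categories.index(_UNLABELED), FALSE_POSITIVE_LOCOMOTION
        )
    for extra in list(manual.counts) + list(model.counts):
        if extra not in categories:
            categories.append(extra)
    rows = {
        name: (
            manual.percent(name),
            model.percent(name),
            model.percent(name) - manual.percent(name),
        )
        for name in categories
    }
    total = sum(abs(rows[name][2]) for name in _DETECTOR_NAMES)
    return BudgetComparison(
        rows=rows, total_disagreement=total, total_frames=manual.total_frames
    )


__all__ = [
    "TimeBudget",
    "BudgetComparison",
    "apply_confidence_threshold",
    "budget_from_detections",
    "budget_from_manual",
    "labeled_fraction",
    "compare_budgets",
]
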