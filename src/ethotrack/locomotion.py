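"""Coordinate-plateau correction of Locomotion false positives.

A detector trained on boxed frames can learn the background inside the box:
while the subject sits still in a spot resembling the training footage, the
model keeps emitting ``Locomotion`` even though nothing moves. Such frames
betray themselves in the trajectory of the label box's bottom corner — the
plot flatlines. This module finds those plateaus algorithmically (the
original analysis removed them by eye) and reclassifies the frames as
``False Positive Locomotion``, a category of their own in corrected budgets.

A *plateau* is a maximal run of Locomotion-labeled frames whose bottom-corner
coordinates stay within a pixel tolerance:

* range criterion — max − min of each coordinate over the run must not
  exceed ``epsilon`` (tolerates slowly accumulating sub-pixel jitter better
  than frame-to-frame deltas);
* ``min_run`` — too-short runs are ignored (a brief pause is not evidence);
* ``max_gap`` — missing frames inside a run are bridged up to this many
  frames (the detector occasionally drops a frame mid-plateau);
* both axes must be still by default; movement that shows in either axis
  exonerates the run. An either-axis-still mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .budget import TimeBudget
from .labels import FALSE_POSITIVE_LOCOMOTION, BehaviorLabel
from .records import DetectionTrack

_LOCO = BehaviorLabel.LOCOMOTION.value


@dataclass(frozen=True)
class CoordinateSeries:
    """Bottom-corner coordinates of every Locomotion-labeled frame."""

    frames: np.ndarray  # int, strictly increasing
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.int64)
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if not (len(frames) == len(self.x) == len(self.y)):
            raise ValueError("frames, x, y must have equal length")
        if len(frames) > 1 and not np.all(np.diff(frames) > 0):
            raise ValueError("frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class PlateauConfig:
    """Stillness tolerances for plateau detection (pixels and frames)."""

    epsilon_x: float = 5.0
    epsilon_y: float = 5.0
    min_run: int = 3
    max_gap: int = 2
    require_both_axes_still: bool = True

    def __post_init__(self) -> None:
        if self.epsilon_x < 0 or self.epsilon_y < 0:
            raise ValueError("epsilons must be >= 0")
        if self.min_run < 2:
            raise ValueError("min_run must be >= 2")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")


@dataclass(frozen=True)
class PlateauRun:
    """One maximal stationary run flagged as false-positive Locomotion."""

    start_frame: int
    end_frame: int
    n_frames: int  # number of Locomotion entries inside the run
    x_range: float
    y_range: float


@dataclass(frozen=True)
class CorrectedResult:
    """A track with plateau frames relabeled, plus the bookkeeping.

    ``fp_percent_of_total + corrected_locomotion_percent`` equals the
    original Locomotion percent exactly (all three share the denominator
    ``total_frames``).
    """

    corrected_track: DetectionTrack
    fp_frames: frozenset[int]
    fp_count: int
    original_locomotion_count: int
    total_frames: int
    runs: tuple[PlateauRun, ...] = field(default=())

    @property
    def fp_percent_of_total(self) -> float:
        return 100.0 * self.fp_count / self.total_frames

    @property
    def corrected_locomotion_percent(self) -> float:
        kept = self.original_locomotion_count - self.fp_count
        return 100.0 * kept / self.total_frames


def extract_coordinate_series(track: DetectionTrack) -> CoordinateSeries:
    """Bottom-corner trajectory of the Locomotion-labeled frames, in order."""
    frames, xs, ys = [], [], []
    for det in track:
        if det.behavior_name == _LOCO:
            bx, by = det.box.bottom_corner
            frames.append(det.frame_index)
            xs.append(bx)
            ys.append(by)
    return CoordinateSeries(np.array(frames, dtype=np.int64), np.array(xs), np.array(ys))


def _still(x_range: float, y_range: float, cfg: PlateauConfig) -> bool:
    x_ok = x_range <= cfg.epsilon_x
    y_ok = y_range <= cfg.epsilon_y
    return (x_ok and y_ok) if cfg.require_both_axes_still else (x_ok or y_ok)


def detect_plateaus(
    series: CoordinateSeries, cfg: PlateauConfig | None = None
) -> list[PlateauRun]:
    """Find maximal disjoint stationary runs in a Locomotion series.

    Greedy left-to-right: from each candidate start, the run is extended as
    far as the stillness predicate and ``max_gap`` allow; if it reaches
    ``min_run`` entries it is emitted and the scan resumes past its end.
    The range predicate is monotone in window growth, so each emitted run is
    maximal at its start.
    """
    cfg = cfg or PlateauConfig()
    n = len(series)
    frames, x, y = series.frames, series.x, series.y
    runs: list[PlateauRun] = []
    i = 0
    while i < n:
        j = i
        x_lo = x_hi = x[i]
        y_lo = y_hi = y[i]
        while j + 1 < n and frames[j + 1] - frames[j] <= cfg.max_gap + 1:
            nx_lo, nx_hi = min(x_lo, x[j + 1]), max(x_hi, x[j + 1])
            ny_lo, ny_hi = min(y_lo, y[j + 1]), max(y_hi, y[j + 1])
            if not _still(nx_hi - nx_lo, ny_hi - ny_lo, cfg):
                break
            x_lo, x_hi, y_lo, y_hi = nx_lo, nx_hi, ny_lo, ny_hi
            j += 1
        length = j - i + 1
        if length >= cfg.min_run:
            runs.append(
                PlateauRun(
                    start_frame=int(frames[i]),
                    end_frame=int(frames[j]),
                    n_frames=length,
                    x_range=float(x_hi - x_lo),
                    y_range=float(y_hi - y_lo),
                )
            )
            i = j + 1
        else:
            i += 1
    return runs


def reclassify_false_positives(
    track: DetectionTrack, runs: list[PlateauRun]
) -> CorrectedResult:
    """Relabel every Locomotion detection inside a plateau run.

    Flagged detections become ``False Positive Locomotion`` in the corrected
    track — the analysis does not presume what the subject was actually
    doing, only that it was not locomoting.
    """
    loco_frames = {
        det.frame_index for det in track if det.behavior_name == _LOCO
    }
    fp_frames: set[int] = set()
    for run in runs:
        in_run = {
            f for f in loco_frames if run.start_frame <= f <= run.end_frame
        }
        if not in_run:
            raise ValueError(
                f"plateau run [{run.start_frame}, {run.end_frame}] contains "
                "no Locomotion detection; runs must come from this track"
            )
        fp_frames |= in_run
    corrected = track.with_detections(
        det
        if det.frame_index not in fp_frames or det.behavior_name != _LOCO
        else _relabel(det)
        for det in track
    )
    return CorrectedResult(
        corrected_track=corrected,
        fp_frames=frozenset(fp_frames),
        fp_count=len(fp_frames),
        original_locomotion_count=len(loco_frames),
        total_frames=track.total_frames,
        runs=tuple(runs),
    )


def _relabel(det):
    return replace(det, behavior=FALSE_POSITIVE_LOCOMOTION)


def corrected_budget(result: CorrectedResult, base_budget: TimeBudget) -> TimeBudget:
    """Split the base budget's Locomotion row into retained + false positive.

    All other categories are untouched, so totals are conserved by
    construction.
    """
    if base_budget.total_frames != result.total_frames:
        raise ValueError(
            f"base budget covers {base_budget.total_frames} frames, corrected "
            f"result covers {result.total_frames}"
        )
    base_loco = base_budget.counts.get(_LOCO, 0)
    if base_loco != result.original_locomotion_count:
        raise ValueError(
            f"base budget has {base_loco} Locomotion frames, corrected result "
            f"was derived from {result.original_locomotion_count}"
        )
    counts = dict(base_budget.counts)
    counts[_LOCO] = base_loco - result.fp_count
    counts[FALSE_POSITIVE_LOCOMOTION] = result.fp_count
    return TimeBudget(counts=counts, total_frames=base_budget.total_frames)


__all__ = [
    "CoordinateSeries",
    "PlateauConfig",
    "PlateauRun",
    "CorrectedResult",
    "extract_coordinate_series",
    "detect_plateaus",
    "reclassify_false_positives",
    "corrected_budget",
]
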