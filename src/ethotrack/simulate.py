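"""Synthetic single-subject detection streams with known ground truth.

The generator emulates what a fixed CCTV camera plus a box detector produce
for one focal ape over a session sampled at ~1 frame/s:

1. **Behavior sequence** — a semi-Markov chain of bouts. Bout durations are
   geometric (memoryless; no published bout statistics to do better), and
   bout categories are drawn so that the *long-run frame occupancy* matches
   ``behavior_mix`` — i.e. the mix is a target time budget, so a scenario
   with 41.3% out-of-view really spends ~41.3% of frames out of view.
2. **Trajectory** — Locomotion bouts move the box at a constant speed in a
   per-bout random direction, reflecting off the arena walls; stationary
   bouts pin the box to an anchor with per-frame Gaussian jitter. Some
   stationary bouts carry a planted posture (tall or flat box).
3. **Detector** — each in-view frame is detected with a per-behavior
   probability; the emitted label comes from a confusion matrix whose key
   pathology is stationary frames emitted as ``Locomotion`` (the detector
   memorized background, so the error persists for a whole bout by default);
   confidence is drawn per correctness stratum. Every stationary frame
   emitted as Locomotion is recorded as a planted false positive.

Each stage has its own RNG stream derived from the master seed, so stages
are independently reproducible; identical (scenario, seed) pairs yield
byte-identical fixture files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .io import write_detections_csv, write_manual_csv
from .labels import BehaviorLabel, BoundingBox
from .posture import Posture
from .records import Detection, DetectionTrack, ManualCoding

_B = BehaviorLabel

#: Behaviors during which the subject does not travel.
STATIONARY_BEHAVIORS = frozenset(
    {_B.INACTIVE, _B.COVERED_INACTIVE, _B.FORAGING_FEEDING, _B.OTHER}
)

#: Manual time-budget proportions of the 12-h comparison session; the
#: default scenario targets this regime (41.3% out of view).
STUDY_BEHAVIOR_MIX: dict[BehaviorLabel, float] = {
    _B.LOCOMOTION: 0.036,
    _B.FORAGING_FEEDING: 0.181,
    _B.INACTIVE: 0.139,
    _B.COVERED_INACTIVE: 0.156,
    _B.OTHER: 0.075,
    _B.OUT_OF_VIEW_NOT_LABELED: 0.413,
}


def _default_bout_means() -> dict[BehaviorLabel, float]:
    # seconds; plausible zoo-ape bout scales (short travel bursts, long rests)
    return {
        _B.LOCOMOTION: 15.0,
        _B.FORAGING_FEEDING: 40.0,
        _B.INACTIVE: 60.0,
        _B.COVERED_INACTIVE: 90.0,
        _B.OTHER: 20.0,
        _B.OUT_OF_VIEW_NOT_LABELED: 120.0,
    }


def _default_detect_prob() -> dict[BehaviorLabel, float]:
    # an idealized well-trained detector; the filter, not detector recall,
    # is the phenomenon under study
    return {
        _B.LOCOMOTION: 0.95,
        _B.INACTIVE: 0.95,
        _B.COVERED_INACTIVE: 0.95,
        _B.FORAGING_FEEDING: 0.95,
        _B.OTHER: 0.0,
        _B.OUT_OF_VIEW_NOT_LABELED: 0.0,
    }


def _default_mislabel_matrix() -> dict[BehaviorLabel, dict[BehaviorLabel, float]]:
    # stationary behaviors are emitted as Locomotion 10% of the time —
    # the background-driven failure mode the plateau filter targets
    return {
        _B.LOCOMOTION: {_B.LOCOMOTION: 1.0},
        _B.INACTIVE: {_B.INACTIVE: 0.9, _B.LOCOMOTION: 0.1},
        _B.COVERED_INACTIVE: {_B.COVERED_INACTIVE: 0.9, _B.LOCOMOTION: 0.1},
        _B.FORAGING_FEEDING: {_B.FORAGING_FEEDING: 0.9, _B.LOCOMOTION: 0.1},
    }


@dataclass(frozen=True)
class SyntheticScenario:
    """Generative parameters for one synthetic session.

    Defaults describe a study-like session scaled to 4,348 frames (a tenth
    of the 12-h comparison video) at 1 frame/s with the published manual
    time budget as the occupancy target.
    """

    seed: int = 0
    total_frames: int = 4348
    fps: float = 1.0
    behavior_mix: Mapping[BehaviorLabel, float] = field(
        default_factory=lambda: dict(STUDY_BEHAVIOR_MIX)
    )
    bout_mean_s: Mapping[BehaviorLabel, float] = field(
        default_factory=_default_bout_means
    )
    arena: tuple[float, float] = (1280.0, 720.0)  # pixels (width, height)
    locomotion_speed: float = 15.0  # px/frame
    stationary_jitter_sd: float = 1.0  # px
    box_size_base: tuple[float, float] = (110.0, 150.0)  # (width, height) px
    detect_prob: Mapping[BehaviorLabel, float] = field(
        default_factory=_default_detect_prob
    )
    mislabel_matrix: Mapping[BehaviorLabel, Mapping[BehaviorLabel, float]] = field(
        default_factory=_default_mislabel_matrix
    )
    confidence_model: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"correct": (0.92, 0.05), "incorrect": (0.88, 0.05)}
    )
    armsup_ratio: float = 2.5
    lying_ratio: float = 0.4
    posture_bout_prob: float = 0.1  # chance an Inactive bout carries a posture
    mislabel_per_bout: bool = True  # persistent (background-driven) confusion

    def __post_init__(self) -> None:
        if self.total_frames <= 0:
            raise ValueError("total_frames must be positive")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        mix_sum = sum(self.behavior_mix.values())
        if abs(mix_sum - 1.0) > 1e-9:
            raise ValueError(f"behavior_mix must sum to 1, sums to {mix_sum}")
        for b, p in self.behavior_mix.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"behavior_mix[{b}] = {p} outside [0, 1]")
        for b, p in self.detect_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"detect_prob[{b}] = {p} outside [0, 1]")
        for truth, row in self.mislabel_matrix.items():
            row_sum = sum(row.values())
            if abs(row_sum - 1.0) > 1e-9:
                raise ValueError(
                    f"mislabel_matrix[{truth}] sums to {row_sum}, expected 1"
                )
        if not 0 < self.lying_ratio < self.armsup_ratio:
            raise ValueError("need 0 < lying_ratio < armsup_ratio")
        if not 0.0 <= self.posture_bout_prob <= 1.0:
            raise ValueError("posture_bout_prob must be in [0, 1]")


@dataclass(frozen=True)
class Bout:
    start: int
    end: int  # exclusive
    behavior: BehaviorLabel

    @property
    def n_frames(self) -> int:
        return self.end - self.start


@dataclass
class GroundTruth:
    """Per-frame truth accumulated across the three generator stages."""

    total_frames: int
    fps: float
    behaviors: tuple[BehaviorLabel, ...]
    bouts: tuple[Bout, ...]
    boxes: tuple[Optional[BoundingBox], ...] = ()
    postures: tuple[Posture, ...] = ()
    fp_frames: frozenset[int] = frozenset()

    def manual_coding(self) -> ManualCoding:
        """The idealized (error-free) focal observer's coding."""
        return ManualCoding(
            tuple((i, b) for i, b in enumerate(self.behaviors)),
            total_frames=self.total_frames,
        )


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), stage])


def simulate_behavior_sequence(
    scenario: SyntheticScenario, seed: int | None = None
) -> GroundTruth:
    """Stage 1: semi-Markov bout sequence with geometric durations.

    Bout categories are drawn with probability proportional to
    ``mix[b] / mean_bout_frames[b]`` so that expected frame occupancy equals
    ``behavior_mix`` (renewal-reward: occupancy is bout rate x mean length).
    """
    seed = scenario.seed if seed is None else seed
    rng = _rng(seed, 1)
    cats = [b for b, p in scenario.behavior_mix.items() if p > 0]
    if not cats:
        raise ValueError("behavior_mix has no positive entries")
    mean_frames = {
        b: max(1.0, scenario.bout_mean_s.get(b, 30.0) * scenario.fps) for b in cats
    }
    weights = np.array([scenario.behavior_mix[b] / mean_frames[b] for b in cats])
    weights = weights / weights.sum()
    behaviors: list[BehaviorLabel] = []
    bouts: list[Bout] = []
    while len(behaviors) < scenario.total_frames:
        b = cats[int(rng.choice(len(cats), p=weights))]
        length = int(rng.geometric(1.0 / mean_frames[b]))
        start = len(behaviors)
        end = min(start + length, scenario.total_frames)
        behaviors.extend([b] * (end - start))
        bouts.append(Bout(start, end, b))
    return GroundTruth(
        total_frames=scenario.total_frames,
        fps=scenario.fps,
        behaviors=tuple(behaviors),
        bouts=tuple(bouts),
    )


def _posture_box(
    base: tuple[float, float], ratio: float
) -> tuple[float, float]:
    """Box (width, height) with the given aspect ratio at the base box's area."""
    w0, h0 = base
    h = math.sqrt(w0 * h0 * ratio)
    return (h / ratio, h)


def simulate_trajectory(
    truth: GroundTruth, scenario: SyntheticScenario, seed: int | None = None
) -> GroundTruth:
    """Stage 2: box positions and sizes for every in-view frame.

    Locomotion: straight-line motion at ``locomotion_speed`` px/frame,
    direction drawn per bout, reflecting off the arena walls. Stationary
    bouts: fixed anchor + independent per-frame N(0, jitter_sd) offsets.
    Inactive bouts may carry a planted posture that reshapes the box.
    """
    seed = scenario.seed if seed is None else seed
    rng = _rng(seed, 2)
    arena_w, arena_h = scenario.arena
    candidates = [
        scenario.box_size_base,
        _posture_box(scenario.box_size_base, scenario.armsup_ratio),
        _posture_box(scenario.box_size_base, scenario.lying_ratio),
    ]
    for w, h in candidates:
        if w >= arena_w or h >= arena_h:
            raise ValueError(
                f"arena {scenario.arena} smaller than a required box ({w}, {h})"
            )
    pos = np.array(
        [
            rng.uniform(0.0, arena_w - scenario.box_size_base[0]),
            rng.uniform(0.0, arena_h - scenario.box_size_base[1]),
        ]
    )
    boxes: list[Optional[BoundingBox]] = [None] * truth.total_frames
    postures: list[Posture] = [Posture.NEUTRAL] * truth.total_frames
    for bout in truth.bouts:
        b = bout.behavior
        if b is _B.OUT_OF_VIEW_NOT_LABELED:
            continue  # no box; position carries over
        bw, bh = scenario.box_size_base
        posture = Posture.NEUTRAL
        if b is _B.INACTIVE:
            u = rng.random()
            if u < scenario.posture_bout_prob / 2:
                posture = Posture.ARMS_UP
                bw, bh = candidates[1]
            elif u < scenario.posture_bout_prob:
                posture = Posture.LYING_DOWN
                bw, bh = candidates[2]
        x_max, y_max = arena_w - bw, arena_h - bh
        pos = np.clip(pos, [0.0, 0.0], [x_max, y_max])
        if b is _B.LOCOMOTION:
            theta = rng.uniform(0.0, 2.0 * math.pi)
            vel = scenario.locomotion_speed * np.array(
                [math.cos(theta), math.sin(theta)]
            )
            for i in range(bout.start, bout.end):
                boxes[i] = BoundingBox(float(pos[0]), float(pos[1]), bw, bh)
                pos, vel = _step_reflect(pos, vel, x_max, y_max)
        else:
            anchor = pos.copy()
            for i in range(bout.start, bout.end):
                jitter = rng.normal(0.0, scenario.stationary_jitter_sd, size=2)
                p = np.clip(anchor + jitter, [0.0, 0.0], [x_max, y_max])
                boxes[i] = BoundingBox(float(p[0]), float(p[1]), bw, bh)
                postures[i] = posture
            pos = anchor
    truth.boxes = tuple(boxes)
    truth.postures = tuple(postures)
    return truth


def _step_reflect(
    pos: np.ndarray, vel: np.ndarray, x_max: float, y_max: float
) -> tuple[np.ndarray, np.ndarray]:
    new = pos + vel
    vel = vel.copy()
    for k, hi in enumerate((x_max, y_max)):
        if new[k] < 0.0:
            new[k] = -new[k]
            vel[k] = -vel[k]
        if new[k] > hi:
            new[k] = 2.0 * hi - new[k]
            vel[k] = -vel[k]
        new[k] = min(max(new[k], 0.0), hi)  # guards pathological tiny arenas
    return new, vel


def simulate_detections(
    truth: GroundTruth, scenario: SyntheticScenario, seed: int | None = None
) -> tuple[DetectionTrack, GroundTruth]:
    """Stage 3: detector output plus the planted false-positive frame set."""
    if not truth.boxes:
        raise ValueError("trajectory missing; run simulate_trajectory first")
    seed = scenario.seed if seed is None else seed
    rng = _rng(seed, 3)
    conf_mu_ok, conf_sd_ok = scenario.confidence_model["correct"]
    conf_mu_bad, conf_sd_bad = scenario.confidence_model["incorrect"]
    detections: list[Detection] = []
    fp_frames: set[int] = set()
    for bout in truth.bouts:
        b = bout.behavior
        row = scenario.mislabel_matrix.get(b)
        bout_label: BehaviorLabel | None = None
        if row is not None and scenario.mislabel_per_bout:
            bout_label = _draw_label(rng, row)
        for i in range(bout.start, bout.end):
            if truth.boxes[i] is None:
                continue
            if rng.random() >= scenario.detect_prob.get(b, 0.0):
                continue
            if row is None:
                continue  # behavior invisible to the detector (e.g. Other)
            emitted = bout_label if bout_label is not None else _draw_label(rng, row)
            correct = emitted is b
            mu, sd = (conf_mu_ok, conf_sd_ok) if correct else (conf_mu_bad, conf_sd_bad)
            confidence = float(np.clip(rng.normal(mu, sd), 0.0, 1.0))
            detections.append(
                Detection(
                    frame_index=i,
                    time_s=i / scenario.fps,
                    behavior=emitted,
                    confidence=confidence,
                    box=truth.boxes[i],
                )
            )
            if emitted is _B.LOCOMOTION and b in STATIONARY_BEHAVIORS:
                fp_frames.add(i)
    truth.fp_frames = frozenset(fp_frames)
    track = DetectionTrack(
        tuple(detections), total_frames=truth.total_frames, fps=scenario.fps
    )
    return track, truth


def _draw_label(
    rng: np.random.Generator, row: Mapping[BehaviorLabel, float]
) -> BehaviorLabel:
    labels = list(row.keys())
    probs = np.array([row[l] for l in labels])
    return labels[int(rng.choice(len(labels), p=probs / probs.sum()))]


def simulate_session(
    scenario: SyntheticScenario, seed: int | None = None
) -> tuple[DetectionTrack, GroundTruth]:
    """All three stages in sequence."""
    truth = simulate_behavior_sequence(scenario, seed)
    truth = simulate_trajectory(truth, scenario, seed)
    return simulate_detections(truth, scenario, seed)


def write_truth_csv(truth: GroundTruth, path: Path | str) -> Path:
    """Sidecar: ``frame,true_behavior,is_planted_fp,planted_posture``."""
    path = Path(path)
    lines = ["frame,true_behavior,is_planted_fp,planted_posture"]
    postures = truth.postures or tuple(
        [Posture.NEUTRAL] * truth.total_frames
    )
    for i, b in enumerate(truth.behaviors):
        fp = 1 if i in truth.fp_frames else 0
        lines.append(f"{i},{b.value},{fp},{postures[i].value}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_truth_csv(path: Path | str) -> tuple[list[BehaviorLabel], set[int], list[Posture]]:
    """Parse a truth sidecar back into (behaviors, fp frame set, postures)."""
    from .labels import parse_behavior

    behaviors: list[BehaviorLabel] = []
    fp: set[int] = set()
    postures: list[Posture] = []
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if lines[0] != "frame,true_behavior,is_planted_fp,planted_posture":
        raise ValueError(f"{path}: unexpected truth header {lines[0]!r}")
    for line in lines[1:]:
        frame_s, behavior_s, fp_s, posture_s = line.split(",")
        behaviors.append(parse_behavior(behavior_s))
        if fp_s == "1":
            fp.add(int(frame_s))
        postures.append(Posture(posture_s))
    return behaviors, fp, postures


def make_study_fixture(
    scenario: SyntheticScenario,
    seed: int | None = None,
    out_dir: Path | str = ".",
) -> dict[str, Path]:
    """Write detections.csv, manual.csv and truth.csv for one session.

    The manual coding is the ground-truth behavior sequence itself — an
    idealized error-free observer, since manual coding is the reference the
    automated budget is judged against.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    track, truth = simulate_session(scenario, seed)
    paths = {
        "detections": write_detections_csv(track, out_dir / "detections.csv"),
        "manual": write_manual_csv(truth.manual_coding(), out_dir / "manual.csv"),
        "truth": write_truth_csv(truth, out_dir / "truth.csv"),
    }
    return paths


__all__ = [
    "SyntheticScenario",
    "GroundTruth",
    "Bout",
    "STUDY_BEHAVIOR_MIX",
    "STATIONARY_BEHAVIORS",
    "simulate_behavior_sequence",
    "simulate_trajectory",
    "simulate_detections",
    "simulate_session",
    "make_study_fixture",
    "write_truth_csv",
    "read_truth_csv",
]
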