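"""Readers/writers for detection CSVs, PASCAL-VOC XML, and manual codings.

Detection CSV dialect (UTF-8, comma-separated)::

    #total_frames=43483
    #fps=1.0
    frame,time_s,behavior,confidence,x,y,width,height
    0,0.0,Locomotion,0.93,412.0,220.0,110.0,150.0

The two leading ``#key=value`` comment lines carry session context that the
detections alone cannot: frames with no detection are simply absent. Floats
are serialized with ``repr`` so that write -> read -> write is byte-identical.

Manual coding CSV: header ``frame,behavior``, one row per frame, all six
ethogram categories legal.

PASCAL-VOC annotations are one XML file per frame (the labeling tool's
native export), corners converted to (x, y, width, height) on read.
"""

from __future__ import annotations

import csv
import re
from pathlib import Path
from typing import Union
from xml.etree import ElementTree

from ._rounding import round_half_up
from .labels import (
    DETECTION_LABEL_NAMES,
    FALSE_POSITIVE_LOCOMOTION,
    BehaviorLabel,
    BoundingBox,
    parse_behavior,
)
from .records import Detection, DetectionTrack, ManualCoding

PathLike = Union[str, Path]

DETECTIONS_HEADER = ["frame", "time_s", "behavior", "confidence", "x", "y", "width", "height"]
MANUAL_HEADER = ["frame", "behavior"]

_META_RE = re.compile(r"^#(?P<key>[A-Za-z_]+)=(?P<value>.*)$")


def _fmt(x: float) -> str:
    return repr(float(x))


def _parse_detection_label(name: str, line_no: int) -> Union[BehaviorLabel, str]:
    if name == FALSE_POSITIVE_LOCOMOTION:
        return FALSE_POSITIVE_LOCOMOTION
    label = parse_behavior(name)  # raises with the valid-name list
    if label.value not in DETECTION_LABEL_NAMES:
        valid = ", ".join(repr(n) for n in DETECTION_LABEL_NAMES)
        raise ValueError(
            f"line {line_no}: {name!r} is an ethogram category but not a "
            f"detector output; valid detection labels: {valid}"
        )
    return label


def read_detections_csv(
    path: PathLike, *, keep_highest_confidence: bool = False
) -> DetectionTrack:
    """Read a detection CSV into a :class:`DetectionTrack`.

    Rows are sorted by frame index on read. ``total_frames`` comes from the
    ``#total_frames=N`` metadata line when present, else ``max frame + 1``.
    Duplicate frame indices are an error (single focal subject) unless
    ``keep_highest_confidence`` is set, in which case the most confident
    detection per frame wins.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[Detection] = []
    by_frame: dict[int, Detection] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        line_no = 0
        # leading comment block
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            if not line:
                break
            if not line.startswith("#"):
                fh.seek(pos)
                break
            line_no += 1
            m = _META_RE.match(line.strip())
            if m:
                meta[m.group("key")] = m.group("value")
        reader = csv.reader(fh)
        header = next(reader, None)
        line_no += 1
        if header != DETECTIONS_HEADER:
            raise ValueError(
                f"{path}: line {line_no}: expected header "
                f"{','.join(DETECTIONS_HEADER)!r}, got {header!r}"
            )
        fps = float(meta.get("fps", "1.0"))
        for raw in reader:
            line_no += 1
            if not raw:
                continue
            if len(raw) != len(DETECTIONS_HEADER):
                raise ValueError(
                    f"{path}: line {line_no}: expected "
                    f"{len(DETECTIONS_HEADER)} fields, got {len(raw)}"
                )
            try:
                frame = int(raw[0])
                time_s = float(raw[1])
                behavior = _parse_detection_label(raw[2], line_no)
                confidence = float(raw[3])
                box = BoundingBox(float(raw[4]), float(raw[5]), float(raw[6]), float(raw[7]))
                det = Detection(frame, time_s, behavior, confidence, box)
            except ValueError as exc:
                raise ValueError(f"{path}: line {line_no}: {exc}") from exc
            if frame in by_frame:
                if not keep_highest_confidence:
                    raise ValueError(
                        f"{path}: line {line_no}: duplicate frame_index {frame} "
                        "(single focal subject; pass keep_highest_confidence=True "
                        "to keep the most confident detection)"
                    )
                if det.confidence <= by_frame[frame].confidence:
                    continue
            by_frame[frame] = det
    rows = sorted(by_frame.values(), key=lambda d: d.frame_index)
    if "total_frames" in meta:
        total_frames = int(meta["total_frames"])
    else:
        total_frames = (rows[-1].frame_index + 1) if rows else 0
    return DetectionTrack(detections=tuple(rows), total_frames=total_frames, fps=fps)


def write_detections_csv(track: DetectionTrack, path: PathLike) -> Path:
    """Write ``track`` in the documented dialect; inverse of the reader."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        fh.write(f"#total_frames={track.total_frames}\n")
        fh.write(f"#fps={_fmt(track.fps)}\n")
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(DETECTIONS_HEADER)
        for det in track:
            writer.writerow(
                [
                    det.frame_index,
                    _fmt(det.time_s),
                    det.behavior_name,
                    _fmt(det.confidence),
                    _fmt(det.box.x_min),
                    _fmt(det.box.y_min),
                    _fmt(det.box.width),
                    _fmt(det.box.height),
                ]
            )
    return path


_STEM_INDEX_RE = re.compile(r"(\d+)$")


def read_voc_annotations(
    directory: PathLike,
    *,
    index_base: int = 0,
    total_frames: int | None = None,
    fps: float = 1.0,
    keep_first_of_multiple: bool = False,
) -> DetectionTrack:
    """Read a directory of per-frame PASCAL-VOC XML files as human labels.

    Each file contributes one detection with confidence 1.0. The frame index
    is the trailing integer of the filename stem (``frame_0012.xml`` -> 12),
    minus ``index_base`` for tools that number from 1. One ``<object>`` per
    file is expected — a single focal subject; extra objects are an error
    unless ``keep_first_of_multiple`` is set.
    """
    directory = Path(directory)
    files = sorted(directory.glob("*.xml"))
    detections: list[Detection] = []
    for f in files:
        m = _STEM_INDEX_RE.search(f.stem)
        if m is None:
            raise ValueError(f"{f.name}: filename stem carries no frame number")
        frame = int(m.group(1)) - index_base
        if frame < 0:
            raise ValueError(f"{f.name}: frame index {frame} negative after "
                             f"index_base={index_base} normalization")
        root = ElementTree.parse(f).getroot()
        objects = root.findall("object")
        if not objects:
            raise ValueError(f"{f.name}: no <object> element")
        if len(objects) > 1 and not keep_first_of_multiple:
            raise ValueError(
                f"{f.name}: {len(objects)} objects in one frame (single focal "
                "subject; pass keep_first_of_multiple=True to keep the first)"
            )
        obj = objects[0]
        name_el = obj.find("name")
        if name_el is None or not (name_el.text or "").strip():
            raise ValueError(f"{f.name}: <object> without <name>")
        behavior = parse_behavior(name_el.text.strip())
        bndbox = obj.find("bndbox")
        if bndbox is None:
            raise ValueError(f"{f.name}: <object> without <bndbox>")
        try:
            corners = {
                tag: float(bndbox.findtext(tag))  # type: ignore[arg-type]
                for tag in ("xmin", "ymin", "xmax", "ymax")
            }
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{f.name}: malformed <bndbox>") from exc
        box = BoundingBox.from_voc(**corners)
        detections.append(
            Detection(frame, frame / fps, behavior, confidence=1.0, box=box)
        )
    detections.sort(key=lambda d: d.frame_index)
    if total_frames is None:
        total_frames = (detections[-1].frame_index + 1) if detections else 0
    return DetectionTrack(tuple(detections), total_frames=total_frames, fps=fps)


def read_manual_csv(path: PathLike) -> ManualCoding:
    """Read a ``frame,behavior`` manual-coding table (all six categories legal)."""
    path = Path(path)
    records: list[tuple[int, BehaviorLabel]] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != MANUAL_HEADER:
            raise ValueError(
                f"{path}: expected header {','.join(MANUAL_HEADER)!r}, got {header!r}"
            )
        for line_no, raw in enumerate(reader, start=2):
            if not raw:
                continue
            if len(raw) != 2:
                raise ValueError(f"{path}: line {line_no}: expected 2 fields")
            try:
                records.append((int(raw[0]), parse_behavior(raw[1])))
            except ValueError as exc:
                raise ValueError(f"{path}: line {line_no}: {exc}") from exc
    return ManualCoding(tuple(records))


def write_manual_csv(coding: ManualCoding, path: PathLike) -> Path:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(MANUAL_HEADER)
        for frame, label in sorted(coding.records):
            writer.writerow([frame, label.value])
    return path


def sample_every_nth(total_frames: int, n: int) -> list[int]:
    """Frame indices 0, n, 2n, ... below ``total_frames``.

    This is the labeling workflow's subsampling step (label every tenth
    extracted frame); ``len(result) == ceil(total_frames / n)``.
    """
    if n < 1:
        raise ValueError(f"sampling step must be >= 1, got {n}")
    if total_frames < 0:
        raise ValueError("total_frames must be >= 0")
    return list(range(0, total_frames, n))


def autolabel_coverage(labeled_count: int, total_frames: int) -> float:
    """Percent of frames a model auto-labeled, to one decimal (half up)."""
    if total_frames <= 0:
        raise ValueError("total_frames must be positive")
    if not 0 <= labeled_count <= total_frames:
        raise ValueError(
            f"labeled_count {labeled_count} outside [0, {total_frames}]"
        )
    return round_half_up(100.0 * labeled_count / total_frames, 1)


__all__ = [
    "read_detections_csv",
    "write_detections_csv",
    "read_voc_annotations",
    "read_manual_csv",
    "write_manual_csv",
    "sample_every_nth",
    "autolabel_coverage",
    "DETECTIONS_HEADER",
    "MANUAL_HEADER",
]
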