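"""MOTChallenge-style text files and the per-frame detection container.

File dialect: comma-separated ``frame, id, x, y, w, h, conf`` followed by
three ``-1`` placeholders.  Frames are 1-based; boxes are pixel-unit
top-left/width/height.  Raw detections carry ``id = -1``; ground-truth and
hypothesis files carry positive track ids.  The confidence column is
required for detection files and ignored for ground truth.  Extra trailing
columns are preserved verbatim on round-trip.

Appearance features ride in a sidecar CSV ``frame, det_index, f0, f1, ...``
aligned with the detection file by (frame, within-frame index).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .geometry import BoundingBox

__all__ = [
    "MotRecord",
    "DetectionFrame",
    "read_mot_file",
    "write_mot_file",
    "detection_frames_from_records",
    "records_from_tracks",
    "read_feature_file",
    "write_feature_file",
]


@dataclass(frozen=True)
class MotRecord:
    frame: int
    track_id: int
    x: float
    y: float
    w: float
    h: float
    conf: float = 1.0
    extras: tuple[str, ...] = ("-1", "-1", "-1")

    @property
    def box(self) -> BoundingBox:
        return BoundingBox(self.x, self.y, self.w, self.h)


@dataclass
class DetectionFrame:
    """All detections for one frame; features optionally aligned to boxes."""

    frame_index: int
    boxes: list[BoundingBox] = field(default_factory=list)
    confidences: list[float] = field(default_factory=list)
    features: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.frame_index < 1:
            raise ValueError("frame indices are 1-based and positive")
        if len(self.boxes) != len(self.confidences):
            raise ValueError("boxes and confidences must have equal length")
        if self.features is not None and len(self.features) != len(self.boxes):
            raise ValueError("features must align one-to-one with boxes")

    def __len__(self) -> int:
        return len(self.boxes)


def read_mot_file(path: str | Path, kind: str = "gt") -> list[MotRecord]:
    """Parse a MOT text file; ``kind`` is 'gt', 'det' or 'hyp'.

    Raises ``ValueError`` naming the offending line on malformed input.
    """
    if kind not in ("gt", "det", "hyp"):
        raise ValueError(f"unknown file kind {kind!r}")
    min_fields = 7 if kind == "det" else 6
    records: list[MotRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) < min_fields:
                raise ValueError(
                    f"{path}:{lineno}: expected >= {min_fields} comma-separated "
                    f"fields, got {len(parts)}"
                )
            try:
                frame = int(float(parts[0]))
                track_id = int(float(parts[1]))
                x, y, w, h = (float(p) for p in parts[2:6])
                conf = float(parts[6]) if len(parts) > 6 else 1.0
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable field ({exc})") from exc
            if w <= 0 or h <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive box size w={w}, h={h}")
            if frame < 1:
                raise ValueError(f"{path}:{lineno}: frame index must be >= 1")
            records.append(
                MotRecord(frame, track_id, x, y, w, h, conf, tuple(parts[7:]))
            )
    return records


def _fmt(v: float) -> str:
    return format(v, ".6g") if v != int(v) else str(int(v))


def write_mot_file(records: Iterable[MotRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in sorted(records, key=lambda r: (r.frame, r.track_id)):
            fields = [
                str(r.frame),
                str(r.track_id),
                _fmt(r.x),
                _fmt(r.y),
                _fmt(r.w),
                _fmt(r.h),
                _fmt(r.conf),
                *r.extras,
            ]
            fh.write(",".join(fields) + "\n")


def detection_frames_from_records(
    records: Sequence[MotRecord],
    features: dict[tuple[int, int], np.ndarray] | None = None,
) -> list[DetectionFrame]:
    """Group detection records into per-frame containers, frame-ordered.

    ``features`` maps (frame, within-frame index) to an appearance vector.
    """
    by_frame: dict[int, list[MotRecord]] = {}
    for r in records:
        by_frame.setdefault(r.frame, []).append(r)
    frames = []
    for idx in sorted(by_frame):
        recs = by_frame[idx]
        feats = None
        if features is not None:
            feats = [features[(idx, j)] for j in range(len(recs))]
        frames.append(
            DetectionFrame(
                frame_index=idx,
                boxes=[r.box for r in recs],
                confidences=[r.conf for r in recs],
                features=feats,
            )
        )
    return frames


def records_from_tracks(
    outputs: Iterable[tuple[int, int, BoundingBox]], conf: float = 1.0
) -> list[MotRecord]:
    """Build hypothesis records from (frame, track_id, box) triples."""
    return [
        MotRecord(frame, tid, b.x, b.y, b.w, b.h, conf)
        for frame, tid, b in outputs
    ]


def write_feature_file(
    features: dict[tuple[int, int], np.ndarray], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for (frame, j) in sorted(features):
            vec = features[(frame, j)]
            fh.write(
                ",".join([str(frame), str(j), *(format(v, ".9g") for v in vec)]) + "\n"
            )


def read_feature_file(path: str | Path) -> dict[tuple[int, int], np.ndarray]:
    out: dict[tuple[int, int], np.ndarray] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: malformed feature line")
            out[(int(parts[0]), int(parts[1]))] = np.array(
                [float(p) for p in parts[2:]]
            )
    return out
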