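"""Virtual counting-line counter over confirmed track trajectories.

A fixed vertical line spans the full frame height.  Every track carries a
*counting flag* (1 once counted, never reset) and a *direction flag*
(1 = moving left, i.e. decreasing x; 0 = moving right), inferred from the
net displacement over a short window of recent observed centers.  Each
frame, tracks already counted are skipped; tracks moving against the
configured counting direction are skipped; a remaining track whose center
crossed the line between its previous and current observation increments
the total and sets its counting flag.  A track therefore contributes at
most one count, and the running total is non-decreasing.

The crossing test compares consecutive *observed* centers, so a brief
detector dropout that straddles the line still counts on reappearance.  A
center exactly on the line counts on the frame it first reaches strictly
beyond it.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable

__all__ = ["CountingLine", "CountLedger", "LineCounter", "infer_direction"]

LEFT, RIGHT = "left", "right"


@dataclass(frozen=True)
class CountingLine:
    """Vertical line at a fixed x position, spanning the frame height."""

    x_position: float


@dataclass
class TrackCountRecord:
    counted_flag: int = 0
    direction_flag: int | None = None
    crossing_frame: int | None = None


@dataclass
class CountLedger:
    total: int = 0
    records: dict[int, TrackCountRecord] = field(default_factory=dict)

    def record(self, track_id: int) -> TrackCountRecord:
        return self.records.setdefault(track_id, TrackCountRecord())


def infer_direction(centers_x: Iterable[float]) -> int | None:
    """1 if net displacement is leftward (x decreasing), 0 if rightward.

    Returns None (unset) for fewer than two positions or zero net
    displacement; such tracks are skipped for the frame.
    """
    xs = list(centers_x)
    if len(xs) < 2:
        return None
    net = xs[-1] - xs[0]
    if net < 0:
        return 1
    if net > 0:
        return 0
    return None


class LineCounter:
    """Accumulates line crossings of identity-stable tracks.

    Consumes (track_id, center_x) observations per frame, so it runs both
    live behind the tracker and offline over a written track file.
    """

    def __init__(
        self,
        line: CountingLine,
        direction: str = LEFT,
        window: int = 5,
    ) -> None:
        if direction not in (LEFT, RIGHT):
            raise ValueError(f"direction must be 'left' or 'right', got {direction!r}")
        self.line = line
        self.direction = direction
        self.window = window
        self.ledger = CountLedger()
        self._history: dict[int, deque[float]] = {}
        self._last_frame: int | None = None

    @property
    def required_flag(self) -> int:
        return 1 if self.direction == LEFT else 0

    def update(
        self, frame_index: int, observations: Iterable[tuple[int, float]]
    ) -> CountLedger:
        """Process one frame of (track_id, center_x) observations."""
        if self._last_frame is not None and frame_index <= self._last_frame:
            raise ValueError("frames must be processed in increasing order")
        self._last_frame = frame_index
        for track_id, cx in observations:
            hist = self._history.setdefault(
                track_id, deque(maxlen=max(2, self.window))
            )
            prev_x = hist[-1] if hist else None
            hist.append(cx)
            rec = self.ledger.record(track_id)
            rec.direction_flag = infer_direction(hist)
            if rec.counted_flag:  # already counted: omit
                continue
            if rec.direction_flag != self.required_flag:  # wrong/unknown direction
                continue
            if prev_x is None:
                continue
            if self._crossed(prev_x, cx):
                rec.counted_flag = 1
                rec.crossing_frame = frame_index
                self.ledger.total += 1
        return self.ledger

    def _crossed(self, prev_x: float, cur_x: float) -> bool:
        lx = self.line.x_position
        if self.direction == LEFT:
            return prev_x >= lx and cur_x < lx
        return prev_x <= lx and cur_x > lx

    def finalize(self) -> int:
        """Total crossings in the configured direction; idempotent."""
        return self.ledger.total
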