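"""Tracking-by-detection with cascade matching and a CIoU second stage.

Per frame the tracker (i) predicts every track one step forward with the
constant-velocity Kalman filter, (ii) runs the matching cascade — confirmed
tracks claim detections in ascending order of frames-since-last-update,
within a tier by minimum-cost assignment on the min-gallery cosine distance
with Mahalanobis-gated pairs excluded — and (iii) offers the leftovers to a
second association stage that scores track-prediction/detection box pairs
with Complete-IoU (or plain IoU, kept for ablation).  Matched tracks are
Kalman-updated and their appearance galleries extended; unmatched tentative
tracks die immediately, confirmed tracks survive ``max_age`` missed frames,
and unmatched detections found new tentative tracks that confirm after
``n_init`` consecutive hits.

Appearance matching degrades gracefully: when detections carry no feature
vectors the cascade cost falls back to the gated Mahalanobis distance, i.e.
motion-only association.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import scipy.optimize

from .appearance import INFEASIBLE, FeatureGallery, cosine_cost
from .geometry import BoundingBox, ciou, iou
from .io import DetectionFrame
from .kalman import CHI2_GATE_4DOF, ConstantVelocityKalman, KalmanTrackState

__all__ = ["TrackerConfig", "Track", "Tracker", "AssociationResult", "solve_assignment"]

TENTATIVE, CONFIRMED, DELETED = "tentative", "confirmed", "deleted"


@dataclass
class TrackerConfig:
    """Tunable association and lifecycle parameters.

    Defaults follow the standard Deep SORT reference values; every one is
    overridable.  ``second_stage`` selects the box-overlap metric of the
    second association stage ('ciou', 'iou', or 'none' to disable it);
    ``use_appearance`` switches the cascade between appearance-based and
    motion-only costs.
    """

    max_age: int = 30
    n_init: int = 3
    appearance_threshold: float = 0.2
    gating_chi2: float = CHI2_GATE_4DOF
    second_stage: Literal["ciou", "iou", "none"] = "ciou"
    second_stage_max_age: int = 30  # confirmed tracks eligible for stage 2
    ciou_cost_floor: float = 0.35  # max accepted (1 - ciou)/2, i.e. ciou >= 0.3
    iou_cost_floor: float = 0.7  # max accepted 1 - iou, i.e. iou >= 0.3
    use_appearance: bool = True
    gallery_budget: int = 100
    min_confidence: float = 0.3


@dataclass
class Track:
    track_id: int
    state: KalmanTrackState
    gallery: FeatureGallery
    status: str = TENTATIVE
    hits: int = 1
    time_since_update: int = 0
    counted_flag: int = 0
    direction_flag: int | None = None
    # observed (frame, center_x, center_y) at each successful update
    center_history: list[tuple[int, float, float]] = field(default_factory=list)

    @property
    def is_confirmed(self) -> bool:
        return self.status == CONFIRMED

    @property
    def is_tentative(self) -> bool:
        return self.status == TENTATIVE

    def predicted_box(self) -> BoundingBox:
        return self.state.to_box()


@dataclass(frozen=True)
class AssociationResult:
    matches: tuple[tuple[int, int], ...]  # (track index, detection index)
    unmatched_tracks: tuple[int, ...]
    unmatched_detections: tuple[int, ...]


def solve_assignment(cost: np.ndarray) -> list[tuple[int, int]]:
    """Minimum-cost one-to-one assignment with a deterministic tie-break.

    Pairs with infeasible (sentinel) cost are dropped from the solution.
    Among cost-equivalent optima, prefer giving the lower row index the
    lower column index: any matched pair of rows whose columns could be
    swapped at identical total cost is put in lexicographic order.
    """
    if cost.size == 0:
        return []
    rows, cols = scipy.optimize.linear_sum_assignment(cost)
    pairs = [(int(r), int(c)) for r, c in zip(rows, cols) if cost[r, c] < INFEASIBLE]
    pairs.sort()
    changed = True
    while changed:
        changed = False
        for i in range(len(pairs)):
            for j in range(i + 1, len(pairs)):
                (r1, c1), (r2, c2) = pairs[i], pairs[j]
                if c2 < c1 and np.isclose(
                    cost[r1, c1] + cost[r2, c2], cost[r1, c2] + cost[r2, c1]
                ):
                    pairs[i], pairs[j] = (r1, c2), (r2, c1)
                    changed = True
    return pairs


class Tracker:
    """Stateful multi-object tracker; feed frames in increasing index order."""

    def __init__(
        self,
        config: TrackerConfig | None = None,
        kalman: ConstantVelocityKalman | None = None,
    ) -> None:
        self.config = config or TrackerConfig()
        self.kf = kalman or ConstantVelocityKalman()
        self.tracks: list[Track] = []
        self._next_id = 1
        self._last_frame = 0
        # full observation history per track id, kept past deletion so
        # hypothesis files can include the tentative prefix of tracks that
        # later confirmed (backfill); never-confirmed tracks are dropped
        self._observations: dict[int, list[tuple[int, BoundingBox]]] = {}
        self._ever_confirmed: set[int] = set()

    # -- association stages -------------------------------------------------

    def matching_cascade(
        self, tracks: Sequence[Track], frame: DetectionFrame
    ) -> AssociationResult:
        """Tiered appearance association of confirmed tracks (fresher first)."""
        n_det = len(frame)
        unmatched_det = list(range(n_det))
        matches: list[tuple[int, int]] = []
        for age in range(1, self.config.max_age + 1):
            if not unmatched_det:
                break
            tier = [i for i, t in enumerate(tracks) if t.time_since_update == age]
            if not tier:
                continue
            det_idx = list(unmatched_det)
            cost = self._cascade_cost(
                [tracks[i] for i in tier], frame, det_idx
            )
            for r, c in solve_assignment(cost):
                matches.append((tier[r], det_idx[c]))
                unmatched_det.remove(det_idx[c])
        matched_tracks = {m[0] for m in matches}
        return AssociationResult(
            tuple(sorted(matches)),
            tuple(i for i in range(len(tracks)) if i not in matched_tracks),
            tuple(unmatched_det),
        )

    def _cascade_cost(
        self, tier: Sequence[Track], frame: DetectionFrame, det_idx: Sequence[int]
    ) -> np.ndarray:
        boxes = [frame.boxes[j] for j in det_idx]
        gate = np.stack(
            [self.kf.gating_distance(t.state, boxes) for t in tier]
        )
        have_features = (
            self.config.use_appearance and frame.features is not None
        )
        if have_features:
            cost = cosine_cost(
                [t.gallery for t in tier],
                [frame.features[j] for j in det_idx],
            )
            cost[cost > self.config.appearance_threshold] = INFEASIBLE
        else:
            # motion-only fallback: gated nearest-Mahalanobis
            cost = gate / self.config.gating_chi2
        cost[gate > self.config.gating_chi2] = INFEASIBLE
        return cost

    def second_stage(
        self, tracks: Sequence[Track], frame: DetectionFrame, det_idx: Sequence[int]
    ) -> AssociationResult:
        """Box-overlap association of the cascade leftovers.

        Costs are (1 - CIoU)/2 (default) or 1 - IoU; pairs above the
        configured floor are left unmatched.
        """
        n_t, n_d = len(tracks), len(det_idx)
        cost = np.full((n_t, n_d), INFEASIBLE)
        for i, t in enumerate(tracks):
            pb = t.predicted_box()
            for j, dj in enumerate(det_idx):
                db = frame.boxes[dj]
                if self.config.second_stage == "ciou":
                    c = (1.0 - ciou(pb, db).ciou) / 2.0
                    if c <= self.config.ciou_cost_floor:
                        cost[i, j] = c
                else:
                    c = 1.0 - iou(pb, db)
                    if c <= self.config.iou_cost_floor:
                        cost[i, j] = c
        pairs = solve_assignment(cost)
        matched_t = {p[0] for p in pairs}
        matched_d = {p[1] for p in pairs}
        return AssociationResult(
            tuple(sorted((i, det_idx[j]) for i, j in pairs)),
            tuple(i for i in range(n_t) if i not in matched_t),
            tuple(det_idx[j] for j in range(n_d) if j not in matched_d),
        )

    # -- per-frame stepping --------------------------------------------------

    def step(self, frame: DetectionFrame) -> list[Track]:
        """Process one frame; returns confirmed tracks updated this frame."""
        if frame.frame_index <= self._last_frame:
            raise ValueError(
                f"frames must arrive in increasing order "
                f"(got {frame.frame_index} after {self._last_frame})"
            )
        self._last_frame = frame.frame_index

        frame = self._filter_confidence(frame)
        self.tracks = [t for t in self.tracks if t.status != DELETED]
        for t in self.tracks:
            t.state = self.kf.predict(t.state)
            t.time_since_update += 1

        confirmed = [t for t in self.tracks if t.is_confirmed]
        cascade = self.matching_cascade(confirmed, frame)

        # second stage: tentative tracks + every confirmed track the cascade
        # left unmatched.  Serving all ages (not only tracks missed exactly
        # once) lets box overlap recover a track whose motion gate went bad
        # before its prediction drifts out of reach.
        stage2_tracks = [t for t in self.tracks if t.is_tentative] + [
            confirmed[i]
            for i in cascade.unmatched_tracks
            if confirmed[i].time_since_update <= self.config.second_stage_max_age
        ]
        if self.config.second_stage != "none" and stage2_tracks:
            stage2 = self.second_stage(
                stage2_tracks, frame, cascade.unmatched_detections
            )
        else:
            stage2 = AssociationResult(
                (), tuple(range(len(stage2_tracks))), cascade.unmatched_detections
            )

        for ti, dj in cascade.matches:
            self._apply_update(confirmed[ti], frame, dj)
        for ti, dj in stage2.matches:
            self._apply_update(stage2_tracks[ti], frame, dj)

        for t in self.tracks:
            if t.time_since_update > 0:
                if t.is_tentative:
                    t.status = DELETED
                elif t.time_since_update > self.config.max_age:
                    t.status = DELETED

        for dj in stage2.unmatched_detections:
            self._initiate(frame, dj)

        return [t for t in self.tracks if t.is_confirmed and t.time_since_update == 0]

    # -- helpers -------------------------------------------------------------

    def _filter_confidence(self, frame: DetectionFrame) -> DetectionFrame:
        keep = [
            j for j, c in enumerate(frame.confidences)
            if c >= self.config.min_confidence
        ]
        if len(keep) == len(frame):
            return frame
        return DetectionFrame(
            frame_index=frame.frame_index,
            boxes=[frame.boxes[j] for j in keep],
            confidences=[frame.confidences[j] for j in keep],
            features=None
            if frame.features is None
            else [frame.features[j] for j in keep],
        )

    def _apply_update(self, track: Track, frame: DetectionFrame, dj: int) -> None:
        box = frame.boxes[dj]
        track.state = self.kf.update(track.state, box, frame.frame_index)
        track.hits += 1
        track.time_since_update = 0
        if frame.features is not None:
            track.gallery.add(frame.features[dj])
        if track.is_tentative and track.hits >= self.config.n_init:
            track.status = CONFIRMED
        if track.is_confirmed:
            self._ever_confirmed.add(track.track_id)
        track.center_history.append((frame.frame_index, box.cx, box.cy))
        self._observations[track.track_id].append((frame.frame_index, box))

    def _initiate(self, frame: DetectionFrame, dj: int) -> None:
        box = frame.boxes[dj]
        gallery = FeatureGallery(self.config.gallery_budget)
        if frame.features is not None:
            gallery.add(frame.features[dj])
        t = Track(
            track_id=self._next_id,
            state=self.kf.initiate(box, frame.frame_index),
            gallery=gallery,
        )
        t.center_history.append((frame.frame_index, box.cx, box.cy))
        self._observations[t.track_id] = [(frame.frame_index, box)]
        self._next_id += 1
        self.tracks.append(t)

    def output_triples(self) -> list[tuple[int, int, BoundingBox]]:
        """(frame, track_id, box) for every observation of a track that was
        ever confirmed, in frame order — the material of a hypothesis file."""
        out = [
            (f, tid, box)
            for tid in sorted(self._ever_confirmed)
            for f, box in self._observations[tid]
        ]
        out.sort(key=lambda t: (t[0], t[1]))
        return out
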