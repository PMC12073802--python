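"""Detection and multi-object tracking evaluation.

Detection side: precision TP/(TP+FP), recall TP/(TP+FN) from greedy
one-to-one matching at an IoU threshold (detections visited in descending
confidence), average precision as the area under the all-points
interpolated precision–recall curve, and the F1 harmonic mean.  With a
single object class, mAP equals AP.

Tracking side: the CLEAR metrics and IDF1.

* MOTA = 1 − (ΣFN + ΣFP + ΣIDSW) / ΣGT, possibly negative.  Frame-by-frame
  correspondences carry over from the previous frame while still above the
  IoU threshold; the remainder is resolved by minimum-cost assignment on
  1 − IoU.  An identity switch is counted when a ground-truth identity's
  matched hypothesis id differs from its most recent previous match.
* MOTP here is the **mean IoU overlap of matched pairs** (higher is
  better), Σ d / Σ C with d the overlap of each match — not the
  distance-based variant some toolkits report.  The two conventions are
  complementary (distance = 1 − overlap).
* IDF1 = 2·IDTP / (2·IDTP + IDFP + IDFN) under the single global
  identity assignment between ground-truth and hypothesis ids that
  maximises IDTP (frames where the paired boxes overlap at the threshold).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.optimize

from .geometry import iou
from .io import MotRecord

__all__ = [
    "EvalReport",
    "detection_pr",
    "average_precision",
    "f1_score",
    "clear_mot",
    "idf1",
    "evaluate_tracking",
    "evaluate_detections",
]


@dataclass(frozen=True)
class EvalReport:
    precision: float | None = None
    recall: float | None = None
    ap: float | None = None
    map: float | None = None
    f1: float | None = None
    mota: float | None = None
    motp: float | None = None
    idf1: float | None = None
    idsw: int | None = None
    fn: int | None = None
    fp: int | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def _by_frame(records: Sequence[MotRecord]) -> dict[int, list[MotRecord]]:
    out: dict[int, list[MotRecord]] = {}
    for r in records:
        out.setdefault(r.frame, []).append(r)
    return out


# --------------------------------------------------------------------------
# Detection metrics
# --------------------------------------------------------------------------


def _match_detections(
    detections: Sequence[MotRecord],
    ground_truth: Sequence[MotRecord],
    iou_threshold: float,
) -> list[bool]:
    """Per-detection TP labels in descending-confidence order (greedy 1:1)."""
    gt_frames = _by_frame(ground_truth)
    order = sorted(
        range(len(detections)), key=lambda i: -detections[i].conf
    )
    used: set[tuple[int, int]] = set()  # (frame, gt index within frame)
    labels = [False] * len(detections)
    for i in order:
        det = detections[i]
        gts = gt_frames.get(det.frame, [])
        best_j, best_iou = -1, iou_threshold
        for j, g in enumerate(gts):
            if (det.frame, j) in used:
                continue
            ov = iou(det.box, g.box)
            if ov >= best_iou:
                best_iou, best_j = ov, j
        if best_j >= 0:
            used.add((det.frame, best_j))
            labels[i] = True
    return [labels[i] for i in order]


def detection_pr(
    detections: Sequence[MotRecord],
    ground_truth: Sequence[MotRecord],
    confidence_cutoff: float = 0.0,
    iou_threshold: float = 0.5,
) -> tuple[float | None, float]:
    """Precision and recall at a confidence cutoff.

    Precision is None (undefined) when no detection survives the cutoff.
    """
    kept = [d for d in detections if d.conf >= confidence_cutoff]
    n_gt = len(ground_truth)
    if n_gt == 0:
        raise ValueError("empty ground truth")
    if not kept:
        return None, 0.0
    labels = _match_detections(kept, ground_truth, iou_threshold)
    tp = sum(labels)
    return tp / len(kept), tp / n_gt


def average_precision(
    detections: Sequence[MotRecord],
    ground_truth: Sequence[MotRecord],
    iou_threshold: float = 0.5,
) -> tuple[float, float]:
    """(AP, mAP) via the all-points interpolated PR curve; mAP = AP (1 class)."""
    if len(ground_truth) == 0:
        raise ValueError("empty ground truth")
    if len(detections) == 0:
        return 0.0, 0.0
    labels = _match_detections(detections, ground_truth, iou_threshold)
    tp = np.cumsum(labels)
    fp = np.cumsum([not l for l in labels])
    recall = tp / len(ground_truth)
    precision = tp / (tp + fp)
    # precision envelope, then integrate over recall steps
    mrec = np.concatenate(([0.0], recall, [recall[-1]]))
    mpre = np.concatenate(([0.0], precision, [0.0]))
    for i in range(len(mpre) - 2, -1, -1):
        mpre[i] = max(mpre[i], mpre[i + 1])
    idx = np.where(mrec[1:] != mrec[:-1])[0]
    ap = float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))
    return ap, ap


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean 2PR/(P+R); 0 by convention when both are 0."""
    if not (0.0 <= precision <= 1.0 and 0.0 <= recall <= 1.0):
        raise ValueError("precision and recall must lie in [0, 1]")
    if precision == 0.0 and recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


# --------------------------------------------------------------------------
# CLEAR-MOT
# --------------------------------------------------------------------------


def clear_mot(
    ground_truth: Sequence[MotRecord],
    hypotheses: Sequence[MotRecord],
    iou_threshold: float = 0.5,
) -> dict:
    """MOTA, MOTP (mean matched IoU), IDSW, FN, FP over a sequence."""
    if len(ground_truth) == 0:
        raise ValueError("empty ground truth")
    gt_frames = _by_frame(ground_truth)
    hyp_frames = _by_frame(hypotheses)
    frames = sorted(set(gt_frames) | set(hyp_frames))

    total_fn = total_fp = total_idsw = total_gt = 0
    overlap_sum = 0.0
    n_matches = 0
    active: dict[int, int] = {}  # gt id -> hyp id matched in previous frame
    last_match: dict[int, int] = {}  # gt id -> most recent hyp id ever matched

    for f in frames:
        gts = gt_frames.get(f, [])
        hyps = hyp_frames.get(f, [])
        total_gt += len(gts)
        gt_ids = [g.track_id for g in gts]
        hyp_ids = [h.track_id for h in hyps]

        matches: dict[int, int] = {}  # gt index -> hyp index
        used_h: set[int] = set()
        # carry over surviving correspondences first
        for gi, g in enumerate(gts):
            prev_h = active.get(g.track_id)
            if prev_h is None or prev_h not in hyp_ids:
                continue
            hi = hyp_ids.index(prev_h)
            if hi in used_h:
                continue
            ov = iou(g.box, hyps[hi].box)
            if ov >= iou_threshold:
                matches[gi] = hi
                used_h.add(hi)
                overlap_sum += ov
                n_matches += 1
        # assignment on the remainder
        free_g = [gi for gi in range(len(gts)) if gi not in matches]
        free_h = [hi for hi in range(len(hyps)) if hi not in used_h]
        if free_g and free_h:
            cost = np.full((len(free_g), len(free_h)), 1e5)
            for a, gi in enumerate(free_g):
                for b, hi in enumerate(free_h):
                    ov = iou(gts[gi].box, hyps[hi].box)
                    if ov >= iou_threshold:
                        cost[a, b] = 1.0 - ov
            rows, cols = scipy.optimize.linear_sum_assignment(cost)
            for a, b in zip(rows, cols):
                if cost[a, b] < 1e5:
                    gi, hi = free_g[a], free_h[b]
                    matches[gi] = hi
                    used_h.add(hi)
                    overlap_sum += 1.0 - cost[a, b]
                    n_matches += 1

        total_fn += len(gts) - len(matches)
        total_fp += len(hyps) - len(matches)

        new_active: dict[int, int] = {}
        for gi, hi in matches.items():
            gid, hid = gt_ids[gi], hyp_ids[hi]
            if gid in last_match and last_match[gid] != hid:
                total_idsw += 1
            last_match[gid] = hid
            new_active[gid] = hid
        active = new_active

    mota = 1.0 - (total_fn + total_fp + total_idsw) / total_gt
    motp = overlap_sum / n_matches if n_matches else math.nan
    return {
        "mota": mota,
        "motp": motp,
        "idsw": total_idsw,
        "fn": total_fn,
        "fp": total_fp,
        "gt": total_gt,
        "matches": n_matches,
    }


def idf1(
    ground_truth: Sequence[MotRecord],
    hypotheses: Sequence[MotRecord],
    iou_threshold: float = 0.5,
) -> float:
    """Identification F1 under the IDTP-maximising global id assignment."""
    if len(ground_truth) == 0 or len(hypotheses) == 0:
        raise ValueError("empty input")
    gt_frames = _by_frame(ground_truth)
    hyp_frames = _by_frame(hypotheses)
    gt_ids = sorted({r.track_id for r in ground_truth})
    hyp_ids = sorted({r.track_id for r in hypotheses})
    gi = {g: i for i, g in enumerate(gt_ids)}
    hi = {h: i for i, h in enumerate(hyp_ids)}

    # potential IDTP for each (gt id, hyp id) pair
    overlap_frames = np.zeros((len(gt_ids), len(hyp_ids)), dtype=int)
    for f in set(gt_frames) & set(hyp_frames):
        for g in gt_frames[f]:
            for h in hyp_frames[f]:
                if iou(g.box, h.box) >= iou_threshold:
                    overlap_frames[gi[g.track_id], hi[h.track_id]] += 1

    # maximise total IDTP; unpaired ids contribute zero
    rows, cols = scipy.optimize.linear_sum_assignment(-overlap_frames)
    idtp = int(overlap_frames[rows, cols].sum())
    n_gt = len(ground_truth)
    n_hyp = len(hypotheses)
    idfn = n_gt - idtp
    idfp = n_hyp - idtp
    return 2.0 * idtp / (2.0 * idtp + idfp + idfn)


def evaluate_tracking(
    ground_truth: Sequence[MotRecord],
    hypotheses: Sequence[MotRecord],
    iou_threshold: float = 0.5,
) -> EvalReport:
    c = clear_mot(ground_truth, hypotheses, iou_threshold)
    score = idf1(ground_truth, hypotheses, iou_threshold) if hypotheses else 0.0
    return EvalReport(
        mota=c["mota"], motp=c["motp"], idf1=score,
        idsw=c["idsw"], fn=c["fn"], fp=c["fp"],
    )


def evaluate_detections(
    detections: Sequence[MotRecord],
    ground_truth: Sequence[MotRecord],
    confidence_cutoff: float = 0.0,
    iou_threshold: float = 0.5,
) -> EvalReport:
    p, r = detection_pr(detections, ground_truth, confidence_cutoff, iou_threshold)
    ap, mean_ap = average_precision(detections, ground_truth, iou_threshold)
    f1 = f1_score(p, r) if p is not None else 0.0
    return EvalReport(precision=p, recall=r, ap=ap, map=mean_ap, f1=f1)
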