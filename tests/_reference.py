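"""Independent oracle implementations used only by the tests.

Everything here is deliberately written as a straight-line transcription of
the underlying definitions, sharing no code with the library: CIoU from its
closed form, assignment by exhaustive permutation enumeration, and the
CLEAR-MOT / IDF1 metrics with their own matching bookkeeping (IDF1 by
exhaustive enumeration of id pairings when small, otherwise via a separate
greedy-free reduction).
"""

from __future__ import annotations

import itertools
import math


def ref_iou(a, b) -> float:
    ax1, ay1, ax2, ay2 = a.x, a.y, a.x + a.w, a.y + a.h
    bx1, by1, bx2, by2 = b.x, b.y, b.x + b.w, b.y + b.h
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return inter / (a.w * a.h + b.w * b.h - inter)


def ref_ciou(pred, gt) -> float:
    """CIoU = IoU - rho^2/c^2 - alpha*v, transcribed term by term."""
    o = ref_iou(pred, gt)
    bx, by = pred.x + pred.w / 2, pred.y + pred.h / 2
    gx, gy = gt.x + gt.w / 2, gt.y + gt.h / 2
    rho2 = (bx - gx) ** 2 + (by - gy) ** 2
    cw = max(pred.x + pred.w, gt.x + gt.w) - min(pred.x, gt.x)
    ch = max(pred.y + pred.h, gt.y + gt.h) - min(pred.y, gt.y)
    c2 = cw**2 + ch**2
    v = (4 / math.pi**2) * (math.atan(gt.w / gt.h) - math.atan(pred.w / pred.h)) ** 2
    alpha = 0.0 if v == 0 else v / ((1 - o) + v)
    return o - rho2 / c2 - alpha * v


def brute_force_assignment(cost, infeasible: float = 1e5):
    """Best feasible one-to-one assignment by enumerating all permutations.

    Returns a set of (row, col) pairs of a minimum-total-cost assignment of
    maximum cardinality (infeasible pairs are never used).  Among optima,
    lexicographically smallest pair set.
    """
    n_r, n_c = cost.shape
    best = (float("inf"), -1, None)  # (total, -cardinality, pairs)
    k = min(n_r, n_c)
    rows = range(n_r)
    for rsub in itertools.combinations(rows, k):
        for csub in itertools.permutations(range(n_c), k):
            pairs = [
                (r, c) for r, c in zip(rsub, csub) if cost[r, c] < infeasible
            ]
            total = sum(cost[r, c] for r, c in pairs)
            key = (-len(pairs), total, sorted(pairs))
            if best[2] is None or key < (-best[1], best[0], best[2]):
                best = (total, len(pairs), sorted(pairs))
    return set(best[2] or [])


def ref_clear_mot(gt_records, hyp_records, iou_threshold: float = 0.5):
    """CLEAR-MOT transcription with its own per-frame bookkeeping.

    Matching per frame: keep the previous frame's gt->hyp pairs while still
    overlapping at the threshold, then greedily... no: resolve the rest by
    enumerating all pairings of the (small) remainder to minimise total
    (1 - IoU); frames in the simulated fixtures never leave more than a few
    unresolved pairs, so enumeration is exact and independent of the
    library's Hungarian solver.
    """
    frames = sorted({r.frame for r in gt_records} | {r.frame for r in hyp_records})
    gt_by = {f: [r for r in gt_records if r.frame == f] for f in frames}
    hyp_by = {f: [r for r in hyp_records if r.frame == f] for f in frames}
    fn = fp = idsw = n_gt = 0
    d_sum, c_sum = 0.0, 0
    prev_pair: dict[int, int] = {}
    ever_pair: dict[int, int] = {}
    for f in frames:
        gts, hyps = gt_by[f], hyp_by[f]
        n_gt += len(gts)
        pairs = {}
        used = set()
        for gi, g in enumerate(gts):
            h_prev = prev_pair.get(g.track_id)
            for hi, h in enumerate(hyps):
                if h.track_id == h_prev and hi not in used:
                    ov = ref_iou(g.box, h.box)
                    if ov >= iou_threshold:
                        pairs[gi] = (hi, ov)
                        used.add(hi)
                    break
        free_g = [gi for gi in range(len(gts)) if gi not in pairs]
        free_h = [hi for hi in range(len(hyps)) if hi not in used]
        # exact small assignment by enumeration over feasible subsets
        best = None
        k = min(len(free_g), len(free_h))
        for size in range(k, -1, -1):
            for gsub in itertools.combinations(free_g, size):
                for hsub in itertools.permutations(free_h, size):
                    ovs = [
                        ref_iou(gts[gi].box, hyps[hi].box)
                        for gi, hi in zip(gsub, hsub)
                    ]
                    if any(o < iou_threshold for o in ovs):
                        continue
                    total = sum(1 - o for o in ovs)
                    cand = (total, list(zip(gsub, hsub, ovs)))
                    if best is None or cand[0] < best[0]:
                        best = cand
            if best is not None:
                break
        for gi, hi, ov in (best[1] if best else []):
            pairs[gi] = (hi, ov)
            used.add(hi)
        fn += len(gts) - len(pairs)
        fp += len(hyps) - len(pairs)
        new_prev = {}
        for gi, (hi, ov) in pairs.items():
            gid, hid = gts[gi].track_id, hyps[hi].track_id
            if gid in ever_pair and ever_pair[gid] != hid:
                idsw += 1
            ever_pair[gid] = hid
            new_prev[gid] = hid
            d_sum += ov
            c_sum += 1
        prev_pair = new_prev
    mota = 1 - (fn + fp + idsw) / n_gt
    motp = d_sum / c_sum if c_sum else float("nan")
    return {"mota": mota, "motp": motp, "idsw": idsw, "fn": fn, "fp": fp}


def ref_idf1(gt_records, hyp_records, iou_threshold: float = 0.5, max_enum: int = 7):
    """IDF1 by exhaustive enumeration over one-to-one id pairings."""
    gt_ids = sorted({r.track_id for r in gt_records})
    hyp_ids = sorted({r.track_id for r in hyp_records})
    frames = sorted({r.frame for r in gt_records} | {r.frame for r in hyp_records})
    counts = {}
    for f in frames:
        for g in (r for r in gt_records if r.frame == f):
            for h in (r for r in hyp_records if r.frame == f):
                if ref_iou(g.box, h.box) >= iou_threshold:
                    key = (g.track_id, h.track_id)
                    counts[key] = counts.get(key, 0) + 1
    k = min(len(gt_ids), len(hyp_ids))
    if max(len(gt_ids), len(hyp_ids)) > max_enum:
        raise ValueError("fixture too large for exhaustive IDF1 oracle")
    best_idtp = 0
    for gsub in itertools.combinations(gt_ids, k):
        for hsub in itertools.permutations(hyp_ids, k):
            idtp = sum(counts.get((g, h), 0) for g, h in zip(gsub, hsub))
            best_idtp = max(best_idtp, idtp)
    idfn = len(gt_records) - best_idtp
    idfp = len(hyp_records) - best_idtp
    return 2 * best_idtp / (2 * best_idtp + idfp + idfn)
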