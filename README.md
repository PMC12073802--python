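# motcount

Tracking-by-detection and virtual-line counting of animals moving through a
narrow corridor, built for overhead fixed-camera footage of livestock
passageways (the motivating case: counting pigs herded through a 1.6 m-wide
farm passage). The package takes per-frame detections from any external
detector, links them into identity-stable trajectories, counts each identity
exactly once as it crosses a virtual vertical line, and scores both the
detector and the tracker — entirely on plain-text MOTChallenge-style files,
with a deterministic corridor simulator standing in for video when you need
ground-truthed data.

## The method

**Tracking.** Each track carries an 8-dimensional constant-velocity Kalman
state over (cx, cy, a, h) — box center, aspect ratio w/h, height — and
their per-frame velocities, with height-scaled process/observation noise.
Association per frame is two-staged:

1. *Matching cascade.* Confirmed tracks claim detections in ascending order
   of frames-since-last-update. Within a tier, a minimum-cost assignment is
   solved on the appearance cost
   `d(i, j) = min_{g in gallery_i} (1 - g · f_j)` — cosine distance against
   a bounded per-track gallery of unit-norm embeddings — with pairs whose
   squared Mahalanobis distance exceeds the chi-square gate
   (9.4877, 4 dof, 0.95) excluded. Without appearance vectors the cascade
   degrades to gated nearest-Mahalanobis (motion-only) matching.
2. *Complete-IoU stage.* Leftover tracks and detections are matched on box
   overlap scored by CIoU,

   `CIoU = IoU − ρ²(b, b_gt)/c² − αv`,

   where ρ is the distance between centers, c the diagonal of the smallest
   enclosing box, `v = (4/π²)(arctan(w_gt/h_gt) − arctan(w/h))²` and
   `α = v/((1 − IoU) + v)`. Unlike plain IoU it stays informative for
   slightly separated or deformed boxes, which is exactly the regime of
   crowded, occluding animals. A plain-IoU stage is kept as a switch for
   ablation.

Track lifecycle: tentative until `n_init = 3` consecutive hits, deleted
after `max_age = 30` missed frames; unmatched detections found new tracks.

**Counting.** A vertical line (default: frame center) spans the corridor.
Each track has a *counting flag* (set once, never cleared) and a *direction
flag* (1 = leftward) inferred from the net displacement of its last 5
observed centers. A not-yet-counted track moving in the configured
direction whose center crosses the line increments the total and sets its
flag — so a track contributes at most one count, and wrong-direction
crossers are ignored.

**Evaluation.** Detection: precision, recall, all-points-interpolated AP
(mAP = AP for the single class), F1. Tracking: MOTA
`= 1 − (ΣFN + ΣFP + ΣIDSW)/ΣGT`, MOTP as the **mean IoU overlap of matched
pairs** (higher is better), IDF1 under the globally optimal identity
pairing, and the identity-switch count IDSW, all at IoU ≥ 0.5.

**Simulator.** Agents of pig-like footprint (0.9 × 0.35 m at 200 px/m)
enter a 1.6 m corridor from the right on a staggered schedule and walk left
at 0.8–1.5 m/s (capped at 2.5 m/s, 25 fps), so every agent crosses the
line once. Detector imperfection is emulated with per-box dropout,
Gaussian box jitter and Poisson false positives; appearance vectors come
from a deterministic synthetic embedder (fixed mean unit vector per
identity plus renormalised Gaussian perturbation). An
`occlusion_intensity` knob compresses spawn gaps and lanes to raise
crowding. A DenseNet-121 layer-plan validator documents the re-ID backbone
contract (dense blocks of 6/12/24/16 composite layers, spatial sizes
112→56→28→14→7→1 from a 224² input) for anyone plugging in a real embedder.

## Worked example

```
$ motcount run --seed 1 --n-agents 10 --miss-prob 0.1 --box-jitter-sigma 2 --out-dir demo
{
  "count": 10,
  "ground_truth": "demo/gt.txt",
  "hypothesis": "demo/hyp.txt",
  "summary": "demo/summary.json",
  "true_count": 10
}
$ python -m json.tool demo/summary.json
{
    "config_hash": "0ccf9c049aae",
    "evaluation": {
        "fn": 144,
        "fp": 0,
        "idf1": 0.9457013574660633,
        "idsw": 0,
        "mota": 0.8969957081545065,
        "motp": 0.9320688675418052
    },
    ...
    "seed": 1,
    "total": 10
}
```

Reading: with 10% detector dropout and 2 px box jitter, 144 of ~1400
ground-truth box-frames went unmatched (mostly the dropped detections
themselves — the tracker only emits observed positions), none were
spurious, giving MOTA 0.897; matched boxes overlapped truth at 0.932 on
average (MOTP); no identity was ever swapped between agents (IDSW 0, IDF1
0.946) — and the line counter reports exactly the 10 animals that truly
crossed.

The same steps decompose into `motcount simulate`, `motcount track`,
`motcount count --tracks hyp.txt --line-x 640 --direction left` and
`motcount evaluate --gt gt.txt --hyp hyp.txt` for use with an external
detector's files.

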