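# Methods

This note records the model, the parameter choices that matter, what the
synthetic scenario generator does and does not emulate, and the numerical
decisions a maintainer would otherwise have to reverse-engineer.

## Motion model

Each track is a constant-velocity Kalman filter over the state
(cx, cy, a, h, ċx, ċy, ȧ, ḣ): box center in pixels, aspect ratio w/h,
height in pixels, and their per-frame derivatives. The time step is fixed
at one frame; variable frame rates are out of scope. Process and
observation standard deviations scale with the current height
(position weight 1/20, velocity weight 1/160), the standard
tracking-by-detection parameterisation; all weights are constructor
arguments. Candidate detections are gated by the squared Mahalanobis
distance of their (cx, cy, a, h) measurement against the predicted
measurement distribution, at the 0.95 chi-square quantile for 4 degrees of
freedom (9.4877).

Two numerical guards: covariances are symmetrised after every propagation,
and `predict` clamps aspect ≥ 1e-3 and height ≥ 1 px, because extrapolating
a shrinking box many frames past its last update can otherwise drive the
nominal box size negative.

With exact measurements of a constant-velocity target, the one-step
prediction error decays geometrically at the steady-state gain; with the
default noise weights it falls below 1e-6 px after roughly a hundred
frames, not instantly — the filter deliberately keeps a nonzero gain so it
can follow speed changes.

## Appearance model

Appearance costs are cosine distances `1 − g·f` between unit-norm
embeddings, min-pooled over a per-track FIFO gallery (budget 100 — large
enough to remember an identity across a long occlusion, small enough that
a slow appearance drift ages out). The embedder is a pluggable callable.
The bundled synthetic embedder maps identity k to a fixed unit mean vector
(dimension 128 by default) and perturbs each sample with isotropic
Gaussian noise whose expected *norm* is `noise_sigma` (default 0.1), then
renormalises. Distinct identities are therefore nearly orthogonal
(inter-identity cost ≈ 1) while within-identity cost is of order sigma²;
the separation is what the cascade's 0.2 acceptance threshold assumes. A
real DenseNet-121 embedder can be registered through the same contract;
the repository ships a shape-checked layer plan of that backbone (dense
blocks of 6/12/24/16 composite 1×1+3×3 layers, each concatenating all
earlier outputs in its block; spatial sizes 112, 56, 28, 14, 7, 1 from a
224×224 input) rather than weights, and deliberately does not prescribe
which internal layer supplies the re-ID vector.

## Association and lifecycle

Per frame: predict all tracks; run the matching cascade over confirmed
tracks in ascending frames-since-update tiers (minimum-cost assignment on
gated cosine costs, matches above 0.2 dropped); then the second stage on
box overlap for tentative tracks and any confirmed track still unmatched;
update matched tracks; delete unmatched tentative tracks immediately and
confirmed tracks after `max_age` = 30 misses; found tentative tracks from
unmatched detections, confirming after `n_init` = 3 consecutive hits.
Assignments are solved by the Hungarian algorithm with an infeasible-cost
sentinel, followed by an epsilon-free lexicographic tie-break (among
cost-equal optima the lower track index gets the lower detection index),
so outputs are bit-reproducible.

Two deliberate departures from the classic lifecycle, both adopted after
the failure modes showed up in simulation:

* **Second-stage eligibility.** The overlap stage serves *all* unmatched
  confirmed tracks, not only those missed exactly once
  (`second_stage_max_age`, default = `max_age`). Restricting it to
  one-frame misses left tracks permanently stranded whenever a single
  dropout coincided with a motion-model transient (e.g. just after the
  entry clipping regime): the Mahalanobis gate never readmitted them, the
  appearance match was never consulted, and every such event cost one
  deleted track plus one identity switch.
* **CIoU acceptance floor.** Second-stage costs are `(1 − CIoU)/2`;
  matches are accepted up to cost 0.35, i.e. CIoU ≥ 0.3 — the same nominal
  overlap strictness as the classic `1 − IoU ≤ 0.7` rule. Accepting the
  full nominal range (cost up to 0.7, CIoU ≥ −0.4) admits *non-overlapping*
  pairs and lets neighbouring detections steal identities wholesale; in
  the occlusion-heavy family this doubled identity switches rather than
  reducing them.

Detections below confidence 0.3 are discarded before tracking. Detections
without appearance vectors are legal: the cascade then ranks by gated
Mahalanobis distance (motion-only matching), which is also exposed as the
`use_appearance=False` ablation switch alongside `second_stage="iou"`.

Hypothesis files contain every *observed* position of every track that was
ever confirmed — including its tentative prefix, backfilled at
confirmation — and nothing from tracks that died tentative. This makes the
output an honest record of what the tracker believed about real objects:
confirmation delay does not manufacture false negatives, and rejected
clutter does not appear at all. Coasted (predicted-only) positions are
never emitted.

## Counting

A vertical line at a fixed x (default: frame center) spanning the full
frame height. Direction flag: 1 if the net displacement over the last 5
observed centers is leftward, 0 if rightward, unset on ties or a single
observation — unset tracks are skipped that frame. Crossing is a sign
change of `center_x − line_x` between *consecutive observed* centers, so a
dropout that straddles the line still counts on reappearance; a center
exactly on the line counts on the frame it first moves strictly beyond.
The counting flag is monotone (0→1 once), so each track id contributes at
most one count, totals never decrease, and the total is bounded by the
number of distinct confirmed ids — which is precisely why identity
fragmentation can inflate counts and why the counter only consumes
confirmed tracks. Counting direction is configurable {left, right};
bidirectional net counting is out of scope.

## Evaluation

Detection matching is greedy one-to-one in descending confidence at
IoU ≥ 0.5; AP integrates the all-points-interpolated precision–recall
staircase; mAP = AP for the single class. CLEAR-MOT matching carries over
the previous frame's correspondences while they still overlap at the
threshold and resolves the remainder by minimum-cost assignment on
1 − IoU; an identity switch is counted when a ground-truth identity's
hypothesis id differs from its most recent previous match (gaps included).
**MOTP here is the mean IoU of matched pairs — higher is better.** Several
toolkits report the complementary distance (1 − IoU) under the same name;
this package follows the overlap reading consistently. IDF1 maximises
total per-frame matches over a global one-to-one pairing of ground-truth
and hypothesis ids. The test suite pins all metrics to hand-computed
fixtures and to an independent straight-line transcription of the
definitions on simulated scenarios.

## Synthetic scenarios

The generator emulates the target deployment: a fixed overhead camera over
a 1.6 m-wide passage (rendered at 200 px/m inside a 1280×720 frame),
animals of 0.9 × 0.35 m footprint entering right on a staggered schedule
(base gap 14 frames ± 4), walking left in a fixed lane with 1 px lateral
jitter at a per-agent speed drawn from 0.8–1.5 m/s and capped at the
physical 2.5 m/s at an assumed 25 fps. Every agent traverses fully, so the
true count equals the agent count and every crossing is leftward.
`occlusion_intensity` ∈ [0, 1] compresses spawn gaps and lane spread by up
to 80%, monotonically raising pairwise box overlap (verified over seeds).
Detector corruption: independent per-box dropout, Gaussian jitter on
center and size, Poisson false positives with agent-like sizes, fresh
identities and therefore uninformative appearance vectors, confidences
U(0.6, 1) for real boxes and U(0.3, 0.8) for clutter. An object is neither
annotated nor detected until ≥ 25% of its body is inside the frame
(`min_visibility`), mirroring benchmark visibility filtering — without it
the first visible slivers are a few pixels wide and no overlap metric can
link them. All randomness flows from one seeded generator; identical seeds
give byte-identical files.

What the generator does *not* emulate — and hence what green tests do not
certify about real footage: body articulation and shape change, lighting
and low-light appearance degradation, correlated (rather than independent)
detector failures under crowding, stalling or reversing animals, and any
appearance statistics of a trained embedder. Results on the synthetic
family support *relative* statements (e.g. the CIoU stage does not switch
identities more than a plain-IoU stage at the studied crowding level), not
absolute field accuracy.

## Problem sizes

The standard study conditions used throughout the tests and the acceptance
script: a noise-free 10-agent scenario (~290 frames, ~1 500 ground-truth
boxes); an occlusion-heavy family of 20 agents with 10% dropout and 2 px
jitter over 10 seeds; a 20-scenario counting batch with dropout, jitter
and false positives; and a 12-agent detection-metrics scenario (~1 900
detections). These sizes give stable medians while keeping a full run in
the low tens of seconds on one CPU.
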