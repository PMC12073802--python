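"""Synthetic corridor scenarios: ground truth plus corrupted detections.

The generator emulates the study setting the tracker is built for: a fixed
overhead camera viewing a 1.6 m-wide farm passageway, with animals herded
through it in one direction at bounded speed (capped at the pixel
equivalent of 2.5 m/s).  Agents enter from the right edge on a staggered
schedule, keep a lane with small lateral jitter, and exit on the left, so
every agent crosses a vertical counting line at the frame center exactly
once, moving left.

The detector is emulated by corrupting the ground-truth boxes: independent
per-box dropout (``miss_prob``), Gaussian localisation jitter
(``box_jitter_sigma``), and Poisson false positives per frame (``fp_rate``)
with sizes drawn from the agent distribution and fresh random identities.
Appearance features come from the deterministic synthetic embedder keyed by
agent identity.  ``occlusion_intensity`` in [0, 1] compresses the spawn
schedule and lane spread so boxes overlap more, giving a controllable
crowding/occlusion axis for ablation studies.  All randomness flows from
the single mandatory seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .appearance import SyntheticEmbedder
from .geometry import BoundingBox, iou
from .io import DetectionFrame, MotRecord

__all__ = ["ScenarioConfig", "ScenarioTruth", "simulate", "occlusion_profile"]

FP_ID_BASE = 100_000  # false-positive identities for the embedder


@dataclass(frozen=True)
class ScenarioConfig:
    """Physical and noise parameters of one corridor scenario.

    Units: lengths in metres where suffixed ``_m``, speeds in m/s,
    everything else in pixels/frames.  Defaults describe the emulated
    setting: a 1280x720 frame, a 1.6 m corridor at 200 px/m, 25 fps, and
    agents of roughly pig-like footprint (0.9 x 0.35 m) walking at
    0.8-1.5 m/s, all below the 2.5 m/s cap.
    """

    seed: int
    n_agents: int = 10
    frame_width: int = 1280
    frame_height: int = 720
    px_per_m: float = 200.0
    corridor_width_m: float = 1.6
    fps: float = 25.0
    max_speed_mps: float = 2.5
    speed_range_mps: tuple[float, float] = (0.8, 1.5)
    agent_length_m: float = 0.9
    agent_width_m: float = 0.35
    size_jitter_frac: float = 0.1
    spawn_gap_frames: float = 14.0
    spawn_jitter_frames: float = 4.0
    lane_jitter_px: float = 1.0
    min_visibility: float = 0.25  # fraction of the body visible before it is annotated/detected
    occlusion_intensity: float = 0.0
    miss_prob: float = 0.0
    fp_rate: float = 0.0
    box_jitter_sigma: float = 0.0
    embed_dim: int = 128
    embed_noise_sigma: float = 0.1
    with_features: bool = True

    def __post_init__(self) -> None:
        for name in ("occlusion_intensity", "miss_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.agent_width_m > self.corridor_width_m:
            raise ValueError(
                f"agents ({self.agent_width_m} m) wider than the corridor "
                f"({self.corridor_width_m} m)"
            )
        if self.n_agents < 1:
            raise ValueError("need at least one agent")

    @property
    def line_x(self) -> float:
        return self.frame_width / 2.0

    @property
    def max_speed_px(self) -> float:
        return self.max_speed_mps * self.px_per_m / self.fps

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ScenarioTruth:
    """Ground-truth tracks and the crossing bookkeeping of one scenario."""

    config: ScenarioConfig
    records: list[MotRecord] = field(default_factory=list)
    crossing_frame: dict[int, int] = field(default_factory=dict)
    n_frames: int = 0

    @property
    def true_count(self) -> int:
        return len(self.crossing_frame)


def _clip_box(
    cx: float, cy: float, w: float, h: float, cfg: ScenarioConfig,
    min_visibility: float = 0.0,
):
    """Clip to the frame; None when the visible fraction is too small.

    Mirrors benchmark practice: an object is neither annotated nor detected
    until a sufficient fraction of its body is inside the view.
    """
    x1 = max(cx - w / 2.0, 0.0)
    y1 = max(cy - h / 2.0, 0.0)
    x2 = min(cx + w / 2.0, float(cfg.frame_width))
    y2 = min(cy + h / 2.0, float(cfg.frame_height))
    if x2 - x1 < 2.0 or y2 - y1 < 2.0:
        return None
    if (x2 - x1) * (y2 - y1) < min_visibility * w * h:
        return None
    return BoundingBox(x1, y1, x2 - x1, y2 - y1)


def simulate(cfg: ScenarioConfig) -> tuple[ScenarioTruth, list[DetectionFrame]]:
    """Run one scenario; returns ground truth and the detection stream."""
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(cfg.seed)))
    embedder = SyntheticEmbedder(cfg.embed_dim, cfg.embed_noise_sigma, cfg.seed)

    corridor_px = cfg.corridor_width_m * cfg.px_per_m
    band_top = (cfg.frame_height - corridor_px) / 2.0
    half_spread = max(
        0.0,
        (corridor_px - cfg.agent_width_m * cfg.px_per_m)
        / 2.0
        * (1.0 - 0.8 * cfg.occlusion_intensity),
    )
    gap = cfg.spawn_gap_frames * (1.0 - 0.8 * cfg.occlusion_intensity)

    agents = []
    t_spawn = 1.0
    for aid in range(1, cfg.n_agents + 1):
        speed = min(
            rng.uniform(*cfg.speed_range_mps), cfg.max_speed_mps
        ) * cfg.px_per_m / cfg.fps
        length = cfg.agent_length_m * cfg.px_per_m * (
            1.0 + cfg.size_jitter_frac * rng.uniform(-1, 1)
        )
        width = cfg.agent_width_m * cfg.px_per_m * (
            1.0 + cfg.size_jitter_frac * rng.uniform(-1, 1)
        )
        lane_y = band_top + corridor_px / 2.0 + rng.uniform(-1, 1) * half_spread
        agents.append(
            {
                "id": aid,
                "spawn": int(round(t_spawn)),
                "speed": speed,
                "w": length,  # moving along x, so box width = body length
                "h": width,
                "y": lane_y,
                "x0": cfg.frame_width + length / 2.0,
            }
        )
        t_spawn += max(1.0, gap + rng.uniform(-1, 1) * cfg.spawn_jitter_frames)

    truth = ScenarioTruth(config=cfg)
    frames: list[DetectionFrame] = []
    prev_cx: dict[int, float] = {}
    frame = 0
    while True:
        frame += 1
        visible = []
        all_exited = True
        for a in agents:
            if frame < a["spawn"]:
                all_exited = False
                continue
            cx = a["x0"] - a["speed"] * (frame - a["spawn"])
            if cx > -a["w"] / 2.0:
                all_exited = False
            cy = a["y"] + rng.normal(0.0, cfg.lane_jitter_px)
            box = _clip_box(cx, cy, a["w"], a["h"], cfg, cfg.min_visibility)
            if box is None:
                continue
            visible.append((a["id"], box))
            # crossing bookkeeping on the true (unclipped) center
            if a["id"] in prev_cx and prev_cx[a["id"]] >= cfg.line_x > cx:
                truth.crossing_frame.setdefault(a["id"], frame)
            prev_cx[a["id"]] = cx
        if all_exited:
            break
        for aid, box in visible:
            truth.records.append(
                MotRecord(frame, aid, box.x, box.y, box.w, box.h, 1.0)
            )
        frames.append(_detect(frame, visible, cfg, rng, embedder))
        if frame > 100_000:  # pragma: no cover - guard against bad configs
            raise RuntimeError("scenario failed to terminate")
    truth.n_frames = frame - 1
    return truth, frames


def _detect(
    frame: int,
    visible: list[tuple[int, BoundingBox]],
    cfg: ScenarioConfig,
    rng: np.random.Generator,
    embedder: SyntheticEmbedder,
) -> DetectionFrame:
    boxes, confs, idents = [], [], []
    for aid, box in visible:
        if rng.uniform() < cfg.miss_prob:
            continue
        if cfg.box_jitter_sigma > 0:
            j = rng.normal(0.0, cfg.box_jitter_sigma, size=4)
            b = _clip_box(
                box.cx + j[0],
                box.cy + j[1],
                max(4.0, box.w + j[2]),
                max(4.0, box.h + j[3]),
                cfg,
            )
            if b is None:
                continue
        else:
            b = box
        boxes.append(b)
        confs.append(float(rng.uniform(0.6, 1.0)))
        idents.append(aid)
    n_fp = rng.poisson(cfg.fp_rate)
    corridor_px = cfg.corridor_width_m * cfg.px_per_m
    band_top = (cfg.frame_height - corridor_px) / 2.0
    for k in range(n_fp):
        w = cfg.agent_length_m * cfg.px_per_m * rng.uniform(0.6, 1.1)
        h = cfg.agent_width_m * cfg.px_per_m * rng.uniform(0.6, 1.1)
        cx = rng.uniform(w / 2.0, cfg.frame_width - w / 2.0)
        cy = rng.uniform(band_top + h / 2.0, band_top + corridor_px - h / 2.0)
        boxes.append(BoundingBox(cx - w / 2.0, cy - h / 2.0, w, h))
        confs.append(float(rng.uniform(0.3, 0.8)))
        idents.append(FP_ID_BASE + int(rng.integers(0, 2**20)))
    features = None
    if cfg.with_features:
        features = [embedder.embed(i, sample=frame) for i in idents]
    return DetectionFrame(frame, boxes, confs, features)


def occlusion_profile(truth: ScenarioTruth) -> np.ndarray:
    """Per-frame maximum pairwise IoU among ground-truth boxes."""
    by_frame: dict[int, list[BoundingBox]] = {}
    for r in truth.records:
        by_frame.setdefault(r.frame, []).append(r.box)
    out = []
    for f in sorted(by_frame):
        boxes = by_frame[f]
        best = 0.0
        for i in range(len(boxes)):
            for j in range(i + 1, len(boxes)):
                best = max(best, iou(boxes[i], boxes[j]))
        out.append(best)
    return np.array(out)
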