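import numpy as np
import pytest

from motcount.appearance import INFEASIBLE, SyntheticEmbedder
from motcount.geometry import BoundingBox
from motcount.io import DetectionFrame
from motcount.simulate import ScenarioConfig, simulate
from motcount.tracker import Tracker, TrackerConfig, solve_assignment

from _reference import brute_force_assignment


def frame_of(idx, boxes, features=None, conf=0.95):
    return DetectionFrame(
        idx, list(boxes), [conf] * len(boxes),
        None if features is None else list(features),
    )


class TestAssignmentSolver:
    @pytest.mark.parametrize("shape", [(2, 2), (3, 3), (4, 4), (3, 4), (4, 2)])
    def test_matches_exhaustive_enumeration(self, shape, rng):
        for trial in range(60):
            cost = rng.uniform(0, 1, size=shape)
            # sprinkle infeasible entries
            mask = rng.uniform(size=shape) < 0.3
            cost[mask] = INFEASIBLE
            got = set(solve_assignment(cost))
            expected = brute_force_assignment(cost)
            got_total = sum(cost[r, c] for r, c in got)
            exp_total = sum(cost[r, c] for r, c in expected)
            assert len(got) == len(expected)
            assert got_total == pytest.approx(exp_total, abs=1e-9)

    def test_tie_break_prefers_low_track_then_low_detection(self):
        cost = np.array([[0.5, 0.5], [0.5, 0.5]])
        assert solve_assignment(cost) == [(0, 0), (1, 1)]


class TestCascade:
    def make_tracker(self, **kw):
        return Tracker(TrackerConfig(**kw))

    def confirm_one_track(self, tr, embedder, identity=1):
        box = BoundingBox(500, 300, 60, 40)
        for t in range(1, 4):
            b = BoundingBox(box.x - 8 * t, box.y, box.w, box.h)
            tr.step(frame_of(t, [b], [embedder.embed(identity, t)]))
        return tr

    def test_gallery_identical_feature_in_gate_matches(self):
        e = SyntheticEmbedder(dim=16, noise_sigma=0.0, seed=0)
        tr = self.confirm_one_track(self.make_tracker(), e)
        track = tr.tracks[0]
        assert track.is_confirmed
        b4 = BoundingBox(500 - 8 * 4, 300, 60, 40)
        out = tr.step(frame_of(4, [b4], [e.embed(1, 4)]))
        assert [t.track_id for t in out] == [track.track_id]

    def test_out_of_gate_detection_unmatched_despite_perfect_appearance(self):
        e = SyntheticEmbedder(dim=16, noise_sigma=0.0, seed=0)
        tr = self.make_tracker()
        self.confirm_one_track(tr, e)
        tid = tr.tracks[0].track_id
        far = BoundingBox(50, 600, 60, 40)  # hundreds of px from prediction
        out = tr.step(frame_of(4, [far], [e.embed(1, 4)]))
        assert out == []  # gating dominates appearance
        assert tr.tracks[0].track_id == tid and tr.tracks[0].time_since_update == 1


class TestLifecycle:
    def test_single_detection_confirms_after_n_init(self):
        tr = Tracker(TrackerConfig(n_init=3))
        e = SyntheticEmbedder(dim=8, noise_sigma=0.0, seed=0)
        outs = []
        for t in range(1, 4):
            b = BoundingBox(500 - 8 * t, 300, 60, 40)
            outs.append(tr.step(frame_of(t, [b], [e.embed(1, t)])))
        assert outs[0] == [] and outs[1] == []
        assert [t.track_id for t in outs[2]] == [1]
        assert outs[2][0].is_confirmed

    def test_disappearance_beyond_max_age_founds_new_id(self):
        cfg = TrackerConfig(n_init=2, max_age=3)
        e = SyntheticEmbedder(dim=8, noise_sigma=0.0, seed=0)
        tr = Tracker(cfg)
        for t in range(1, 4):
            b = BoundingBox(500 - 8 * t, 300, 60, 40)
            tr.step(frame_of(t, [b], [e.embed(1, t)]))
        first_id = tr.tracks[0].track_id
        # vanish for max_age + 1 frames
        for t in range(4, 8):
            tr.step(frame_of(t, []))
        assert all(t.status == "deleted" or t.track_id != first_id for t in tr.tracks)
        for t in range(8, 10):
            b = BoundingBox(500 - 8 * t, 300, 60, 40)
            out = tr.step(frame_of(t, [b], [e.embed(1, t)]))
        assert out and out[0].track_id != first_id

    def test_out_of_order_frames_rejected(self):
        tr = Tracker()
        tr.step(frame_of(5, []))
        with pytest.raises(ValueError):
            tr.step(frame_of(5, []))

    def test_low_confidence_detections_filtered(self):
        tr = Tracker(TrackerConfig(min_confidence=0.3))
        tr.step(frame_of(1, [BoundingBox(0, 0, 10, 10)], conf=0.1))
        assert tr.tracks == []


class TestSecondStage:
    def test_identical_predicted_box_matches_at_zero_cost(self):
        tr = Tracker(TrackerConfig(use_appearance=False))
        b = BoundingBox(500, 300, 60, 40)
        tr.step(frame_of(1, [b]))
        track = tr.tracks[0]
        res = tr.second_stage([track], frame_of(2, [track.predicted_box()]), [0])
        assert res.matches == ((0, 0),)

    def test_all_below_floor_leaves_everything_unmatched(self):
        tr = Tracker()
        b = BoundingBox(500, 300, 60, 40)
        tr.step(frame_of(1, [b]))
        track = tr.tracks[0]
        far = BoundingBox(50, 650, 60, 40)
        res = tr.second_stage([track], frame_of(2, [far]), [0])
        assert res.matches == ()
        assert res.unmatched_tracks == (0,) and res.unmatched_detections == (0,)

    def test_random_4x4_instances_match_enumeration(self, rng):
        # second-stage assignment on random geometry equals brute force on
        # the same cost matrix
        from motcount.geometry import ciou

        tr = Tracker()
        for trial in range(20):
            tracks = []
            track_boxes = [
                BoundingBox(*rng.uniform(100, 400, 2), *rng.uniform(30, 80, 2))
                for _ in range(4)
            ]
            for b in track_boxes:
                t = Tracker()
                t.step(frame_of(1, [b]))
                tracks.append(t.tracks[0])
            det_boxes = [
                BoundingBox(b.x + rng.uniform(-30, 30), b.y + rng.uniform(-30, 30),
                            b.w, b.h)
                for b in track_boxes
            ]
            res = tr.second_stage(tracks, frame_of(2, det_boxes), list(range(4)))
            cost = np.full((4, 4), INFEASIBLE)
            for i, t in enumerate(tracks):
                for j, d in enumerate(det_boxes):
                    c = (1 - ciou(t.predicted_box(), d).ciou) / 2
                    if c <= tr.config.ciou_cost_floor:
                        cost[i, j] = c
            expected = brute_force_assignment(cost)
            got = {(i, j) for i, j in res.matches}
            assert len(got) == len(expected)
            assert sum(cost[p] for p in got) == pytest.approx(
                sum(cost[p] for p in expected), abs=1e-9
            )


class TestEndToEnd:
    def test_noise_free_corridor_preserves_identities(self):
        from motcount.metrics import evaluate_tracking
        from motcount.io import records_from_tracks

        truth, frames = simulate(ScenarioConfig(seed=0, n_agents=10))
        tr = Tracker()
        for f in frames:
            tr.step(f)
        hyp = records_from_tracks(tr.output_triples())
        report = evaluate_tracking(truth.records, hyp)
        assert report.mota == pytest.approx(1.0)
        assert report.idsw == 0
        assert len({r.track_id for r in hyp}) == 10

    def test_identical_streams_give_identical_track_files(self):
        truth, frames = simulate(
            ScenarioConfig(seed=5, n_agents=6, miss_prob=0.1, box_jitter_sigma=2.0)
        )
        outs = []
        for _ in range(2):
            tr = Tracker()
            for f in frames:
                tr.step(f)
            outs.append(tr.output_triples())
        assert outs[0] == outs[1]
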