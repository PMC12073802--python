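import numpy as np
import pytest

from motcount.geometry import BoundingBox
from motcount.io import MotRecord, records_from_tracks
from motcount.metrics import (
    average_precision,
    clear_mot,
    detection_pr,
    evaluate_tracking,
    f1_score,
    idf1,
)
from motcount.simulate import ScenarioConfig, simulate
from motcount.tracker import Tracker

from _reference import ref_clear_mot, ref_idf1


def rec(frame, tid, x, y=0.0, w=10.0, h=10.0, conf=1.0):
    return MotRecord(frame, tid, x, y, w, h, conf)


class TestDetectionPR:
    def test_nine_of_ten_detections_correct(self):
        # 12 ground-truth boxes; 9 detected correctly, 1 spurious, 3 missed
        gt = [rec(1, i, 100.0 * i) for i in range(12)]
        det = [rec(1, -1, 100.0 * i, conf=0.9) for i in range(9)]
        det.append(rec(1, -1, 5000.0, conf=0.9))
        p, r = detection_pr(det, gt)
        assert p == pytest.approx(9 / 10)
        assert r == pytest.approx(9 / 12)

    def test_no_detections_gives_undefined_precision_zero_recall(self):
        gt = [rec(1, 1, 0.0)]
        p, r = detection_pr([], gt)
        assert p is None and r == 0.0

    def test_greedy_matching_is_one_to_one_and_confidence_ordered(self, rng):
        # random 20-box instance against a transparent double-loop oracle
        gt = [rec(1, i, float(x)) for i, x in enumerate(rng.uniform(0, 2000, 10))]
        det = []
        for g in gt[:7]:
            det.append(rec(1, -1, g.x + rng.uniform(-2, 2), conf=float(rng.uniform(0.5, 1))))
        for _ in range(3):
            det.append(rec(1, -1, float(rng.uniform(4000, 8000)), conf=float(rng.uniform(0.5, 1))))
        # oracle: visit by confidence, claim best unclaimed gt with IoU >= 0.5
        from motcount.geometry import iou as iou_fn

        claimed, tp = set(), 0
        for d in sorted(det, key=lambda d: -d.conf):
            best, best_ov = None, 0.5
            for j, g in enumerate(gt):
                if j in claimed:
                    continue
                ov = iou_fn(d.box, g.box)
                if ov >= best_ov:
                    best, best_ov = j, ov
            if best is not None:
                claimed.add(best)
                tp += 1
        p, r = detection_pr(det, gt)
        assert p == pytest.approx(tp / len(det))
        assert r == pytest.approx(tp / len(gt))


class TestAveragePrecision:
    def test_perfect_ranking_gives_one(self):
        gt = [rec(1, i, 100.0 * i) for i in range(5)]
        det = [rec(1, -1, 100.0 * i, conf=1 - 0.1 * i) for i in range(5)]
        ap, mean_ap = average_precision(det, gt)
        assert ap == pytest.approx(1.0)
        assert mean_ap == ap

    def test_no_true_positive_gives_zero(self):
        gt = [rec(1, 1, 0.0)]
        det = [rec(1, -1, 9000.0, conf=0.9)]
        ap, _ = average_precision(det, gt)
        assert ap == 0.0

    def test_six_detection_staircase_matches_hand_integration(self):
        # labels in confidence order: T F T T F T over 4 ground truths;
        # all-points AP = 0.25*(1 + 0.75 + 0.75 + 2/3) = 0.7916667
        gt = [rec(1, i, 100.0 * i) for i in range(4)]
        hits = [0, None, 1, 2, None, 3]
        det = []
        for rank, hit in enumerate(hits):
            x = 100.0 * hit if hit is not None else 7000.0 + rank
            det.append(rec(1, -1, x, conf=1.0 - 0.1 * rank))
        ap, _ = average_precision(det, gt)
        assert ap == pytest.approx(0.25 * (1 + 0.75 + 0.75 + 2 / 3), abs=1e-9)

    def test_rejects_empty_ground_truth(self):
        with pytest.raises(ValueError):
            average_precision([rec(1, -1, 0.0)], [])


class TestF1:
    @pytest.mark.parametrize("p,r,expected", [
        (0.9, 0.9, 0.9),
        (1.0, 0.0, 0.0),
        (0.5, 1.0, 2 / 3),
        (0.0, 0.0, 0.0),
    ])
    def test_harmonic_mean(self, p, r, expected):
        assert f1_score(p, r) == pytest.approx(expected)

    def test_consistency_with_definition(self, rng):
        for _ in range(50):
            p, r = rng.uniform(0.01, 1, 2)
            assert f1_score(p, r) == pytest.approx(2 * p * r / (p + r), abs=1e-9)


class TestClearMot:
    def test_perfect_hypothesis(self):
        gt = [rec(f, i, 50.0 * i) for f in (1, 2, 3) for i in (1, 2)]
        out = clear_mot(gt, gt)
        assert out["mota"] == 1.0
        assert out["motp"] == pytest.approx(1.0)
        assert out["idsw"] == 0

    def test_one_miss_one_switch_over_four_objects(self):
        # 2 frames x 2 ground-truth objects; frame 2: object B missed and
        # object A's id flips -> MOTA = 1 - (1 + 0 + 1)/4 = 0.5
        gt = [rec(1, 1, 0.0), rec(1, 2, 100.0), rec(2, 1, 0.0), rec(2, 2, 100.0)]
        hyp = [rec(1, 11, 0.0), rec(1, 12, 100.0), rec(2, 12, 0.0)]
        out = clear_mot(gt, hyp)
        assert out["fn"] == 1 and out["fp"] == 0 and out["idsw"] == 1
        assert out["mota"] == pytest.approx(0.5)

    def test_motp_is_mean_matched_overlap(self):
        # two matched pairs with IoU exactly 0.8 and 0.6 -> MOTP 0.7
        gt = [rec(1, 1, 0.0, 0.0, 10, 10), rec(1, 2, 500.0, 0.0, 10, 10)]
        hyp = [rec(1, 1, 0.0, 0.0, 10, 8), rec(1, 2, 500.0, 0.0, 10, 6)]
        out = clear_mot(gt, hyp)
        assert out["motp"] == pytest.approx(0.7)

    def test_mota_decreases_as_misses_injected(self):
        gt = [rec(f, i, 60.0 * i) for f in range(1, 11) for i in range(1, 4)]
        motas = []
        hyp = list(gt)
        for k in (0, 3, 6, 9):
            motas.append(clear_mot(gt, hyp[: len(hyp) - k])["mota"])
        assert motas == sorted(motas, reverse=True) and len(set(motas)) == 4

    def test_rejects_empty_ground_truth(self):
        with pytest.raises(ValueError):
            clear_mot([], [rec(1, 1, 0.0)])


class TestIdf1:
    def test_identical_files_give_one(self):
        gt = [rec(f, i, 70.0 * i) for f in range(1, 6) for i in (1, 2)]
        assert idf1(gt, gt) == 1.0

    def test_eight_two_two_fixture(self):
        # 10 gt frames; hypothesis correct on 8, elsewhere on 2:
        # IDTP=8, IDFP=2, IDFN=2 -> 0.8
        gt = [rec(f, 1, 10.0 * f) for f in range(1, 11)]
        hyp = [rec(f, 5, 10.0 * f) for f in range(1, 9)]
        hyp += [rec(f, 5, 9000.0) for f in (9, 10)]
        assert idf1(gt, hyp) == pytest.approx(0.8)

    def test_small_instance_matches_exhaustive_pairing_oracle(self, rng):
        gt, hyp = [], []
        for f in range(1, 8):
            for i in range(1, 5):
                x = 200.0 * i + 3 * f
                gt.append(rec(f, i, x))
                # hypothesis occasionally swaps ids
                hid = i if rng.uniform() > 0.2 else 1 + (i % 4)
                hyp.append(rec(f, hid, x + rng.uniform(-2, 2)))
        assert idf1(gt, hyp) == pytest.approx(ref_idf1(gt, hyp), abs=1e-12)


class TestAgainstReferenceTranscription:
    """Library CLEAR-MOT/IDF1 vs the independent definitional transcription
    on tracker output from seeded simulated scenarios."""

    @pytest.mark.parametrize("seed", [100, 101, 102, 103, 104])
    def test_agreement_on_simulated_scenarios(self, seed):
        truth, frames = simulate(
            ScenarioConfig(seed=seed, n_agents=6, miss_prob=0.05,
                           box_jitter_sigma=1.5, occlusion_intensity=0.3)
        )
        tr = Tracker()
        for f in frames:
            tr.step(f)
        hyp = records_from_tracks(tr.output_triples())
        got = clear_mot(truth.records, hyp)
        want = ref_clear_mot(truth.records, hyp)
        for key in ("mota", "motp"):
            assert got[key] == pytest.approx(want[key], abs=1e-6)
        for key in ("idsw", "fn", "fp"):
            assert got[key] == want[key]
        assert idf1(truth.records, hyp) == pytest.approx(
            ref_idf1(truth.records, hyp, max_enum=10), abs=1e-6
        )


class TestSingleClassConsistency:
    def test_map_equals_ap_exactly(self, rng):
        gt = [rec(1, i, 80.0 * i) for i in range(6)]
        det = [rec(1, -1, 80.0 * i + rng.uniform(-2, 2), conf=float(rng.uniform(0.3, 1)))
               for i in range(6)]
        ap, mean_ap = average_precision(det, gt)
        assert mean_ap == ap

    def test_report_f1_consistency(self):
        gt = [rec(f, i, 90.0 * i) for f in range(1, 4) for i in (1, 2, 3)]
        report = evaluate_tracking(gt, gt)
        assert report.mota == 1.0 and report.idf1 == 1.0 and report.idsw == 0
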