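"""MAE, tolerance accuracy, tolerance derivation, occlusion events, identity scoring."""

import numpy as np
import pytest

from mosquitrack.evaluation import (
    GroundTruthTrack,
    accuracy_percentage,
    derive_tolerance,
    detect_occlusions,
    frame_is_accurate,
    mae,
    match_trajectories_to_ground_truth,
    read_ground_truth,
    score_identity_preservation,
)
from mosquitrack.geometry import BoundingBox, Point2D, iou
from mosquitrack.postprocess import PointSource, Trajectory, round_pct


def est_traj(track_id, frame_to_xy):
    t = Trajectory(track_id=track_id)
    for f, (x, y) in frame_to_xy.items():
        t.points[f] = (Point2D(x, y), PointSource.OBSERVED)
    return t


def gt_track(agent_id, frame_to_xy):
    g = GroundTruthTrack(agent_id=agent_id)
    for f, (x, y) in frame_to_xy.items():
        g.points[f] = Point2D(x, y)
    return g


class TestMAE:
    def test_identical_is_zero(self):
        pts = {f: (float(f), 2.0 * f) for f in range(5)}
        assert mae(est_traj(1, pts), gt_track(1, pts)) == 0.0

    def test_single_frame_l1(self):
        est = est_traj(1, {0: (10.0, 10.0)})
        gt = gt_track(1, {0: (12.0, 9.0)})
        assert mae(est, gt) == pytest.approx(3.0)

    def test_mean_over_frames(self):
        est = est_traj(1, {0: (0.0, 0.0), 1: (0.0, 0.0)})
        gt = gt_track(1, {0: (2.0, 1.0), 1: (1.0, 0.0)})
        assert mae(est, gt) == pytest.approx(2.0)

    def test_frame_mismatch_raises(self):
        est = est_traj(1, {0: (0.0, 0.0)})
        gt = gt_track(1, {0: (0.0, 0.0), 1: (1.0, 1.0)})
        with pytest.raises(ValueError, match="missing"):
            mae(est, gt)

    def test_matches_brute_force_on_random_data(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(1, 30))
            e = rng.normal(0, 50, size=(n, 2))
            g = rng.normal(0, 50, size=(n, 2))
            est = est_traj(1, {f: tuple(e[f]) for f in range(n)})
            gt = gt_track(1, {f: tuple(g[f]) for f in range(n)})
            brute = np.abs(e - g).sum(axis=1).mean()
            assert mae(est, gt) == pytest.approx(brute)


class TestAccuracy:
    @pytest.mark.parametrize(
        "delta, accurate",
        [((0, 0), True), ((5, 5), True), ((6, 0), False), ((0, 6), False), ((5.999, 5.999), True)],
    )
    def test_strict_tolerance_boundary(self, delta, accurate):
        assert frame_is_accurate(Point2D(10 + delta[0], 10 + delta[1]), Point2D(10, 10), 6.0) is accurate

    def test_all_accurate(self):
        pts = {f: (float(f), 0.0) for f in range(10)}
        assert accuracy_percentage(est_traj(1, pts), gt_track(1, pts)) == 100.0

    @pytest.mark.parametrize(
        "n_bad, total, expected", [(3, 3241, 99.91), (1, 7861, 99.99)]
    )
    def test_table_style_percentages(self, n_bad, total, expected):
        est_pts = {f: (0.0, 0.0) for f in range(total)}
        gt_pts = {f: ((10.0 if f < n_bad else 0.0), 0.0) for f in range(total)}
        pct = accuracy_percentage(est_traj(1, est_pts), gt_track(1, gt_pts))
        assert round_pct(pct) == expected

    def test_translation_invariance(self):
        rng = np.random.default_rng(5)
        e = rng.normal(0, 20, size=(20, 2))
        g = e + rng.normal(0, 4, size=(20, 2))
        base = accuracy_percentage(
            est_traj(1, {f: tuple(e[f]) for f in range(20)}),
            gt_track(1, {f: tuple(g[f]) for f in range(20)}),
        )
        shift = np.array([100.0, -50.0])
        moved = accuracy_percentage(
            est_traj(1, {f: tuple(e[f] + shift) for f in range(20)}),
            gt_track(1, {f: tuple(g[f] + shift) for f in range(20)}),
        )
        assert moved == base


class TestToleranceDerivation:
    @pytest.mark.parametrize(
        "lengths, expected", [([12.0] * 20, 6.0), ([10.0, 14.0], 6.0), ([13.0], 6.5)]
    )
    def test_half_mean_length(self, lengths, expected):
        assert derive_tolerance(lengths) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            derive_tolerance([])


def static_box(cx, cy, half=2.0):
    return BoundingBox(cx - half, cy - half, cx + half, cy + half)


class TestOcclusionEvents:
    def test_no_overlap_no_events(self):
        boxes = {
            1: {f: static_box(0, 0) for f in range(5)},
            2: {f: static_box(50, 50) for f in range(5)},
        }
        assert detect_occlusions(boxes) == []

    def test_run_extraction(self):
        # IoU series approx [0, 0.33.., 0.45.., 0] via sliding box
        offsets = [10.0, 2.0, 1.5, 10.0]
        boxes = {
            1: {f: static_box(0, 0) for f in range(4)},
            2: {f: static_box(offsets[f], 0) for f in range(4)},
        }
        events = detect_occlusions(boxes, 0.25)
        assert len(events) == 1
        assert (events[0].start_frame, events[0].end_frame) == (1, 2)

    def test_exactly_at_threshold_not_occluded(self):
        a = static_box(0, 0)
        b = static_box(2.4, 0)
        assert iou(a, b) == pytest.approx(0.25)
        boxes = {1: {f: a for f in range(3)}, 2: {f: b for f in range(3)}}
        assert detect_occlusions(boxes, 0.25) == []

    def test_events_match_brute_force_on_random_series(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(5, 40))
            xs = rng.uniform(0, 8, size=n)
            boxes = {
                1: {f: static_box(0, 0) for f in range(n)},
                2: {f: static_box(float(xs[f]), 0) for f in range(n)},
            }
            events = detect_occlusions(boxes, 0.25)
            over = [iou(boxes[1][f], boxes[2][f]) > 0.25 for f in range(n)]
            # brute-force run extraction
            runs = []
            start = None
            for f, o in enumerate(over):
                if o and start is None:
                    start = f
                if not o and start is not None:
                    runs.append((start, f - 1))
                    start = None
            if start is not None:
                runs.append((start, n - 1))
            assert [(e.start_frame, e.end_frame) for e in events] == runs
            for e in events:
                assert all(over[f] for f in range(e.start_frame, e.end_frame + 1))
                if e.start_frame > 0:
                    assert not over[e.start_frame - 1]
                if e.end_frame < n - 1:
                    assert not over[e.end_frame + 1]


class TestIdentityPreservation:
    def crossing_fixture(self, swap):
        """Two agents crossing in x; estimates either follow or swap at exit."""
        n = 21
        g1 = {f: (float(f), 0.0) for f in range(n)}
        g2 = {f: (float(n - 1 - f), 0.5 * abs(f - 10)) for f in range(n)}
        # force an overlap interval around f=10
        gts = [gt_track(1, g1), gt_track(2, g2)]
        for g in gts:
            for f, p in g.points.items():
                g.boxes[f] = static_box(p.x, p.y, half=3.0)
        if swap:
            e1 = {f: (g1[f] if f <= 10 else g2[f]) for f in range(n)}
            e2 = {f: (g2[f] if f <= 10 else g1[f]) for f in range(n)}
        else:
            e1, e2 = g1, g2
        est = [est_traj(101, e1), est_traj(102, e2)]
        events = detect_occlusions({g.agent_id: g.boxes for g in gts}, 0.25)
        assert events, "fixture must contain an occlusion event"
        return events, est, gts

    def test_no_events(self):
        assert score_identity_preservation([], [], []) == (0, 0)

    def test_preserved_crossing_counts_correct(self):
        events, est, gts = self.crossing_fixture(swap=False)
        correct, total = score_identity_preservation(events, est, gts)
        assert total >= 1 and correct == total

    def test_swapped_crossing_counts_incorrect(self):
        events, est, gts = self.crossing_fixture(swap=True)
        correct, total = score_identity_preservation(events, est, gts)
        assert total >= 1 and correct == 0

    def test_paper_style_ratio_exceeds_91(self):
        assert 100.0 * 92 / 101 > 91.0


class TestMatching:
    def test_minimal_distance_matching(self):
        e1 = est_traj(1, {f: (0.0, 0.0) for f in range(5)})
        e2 = est_traj(2, {f: (50.0, 50.0) for f in range(5)})
        g1 = gt_track(7, {f: (49.0, 50.0) for f in range(5)})
        g2 = gt_track(8, {f: (1.0, 0.0) for f in range(5)})
        assert match_trajectories_to_ground_truth([e1, e2], [g1, g2]) == {1: 8, 2: 7}


class TestGroundTruthIO:
    def test_round_trip(self, tmp_path):
        p = tmp_path / "gt.csv"
        p.write_text(
            "frame,agent_id,x,y,x_min,y_min,x_max,y_max\n"
            "0,1,10.5,20.5,8,18,13,23\n"
            "1,1,11.5,21.5,9,19,14,24\n"
            "0,2,50,60,48,58,52,62\n"
        )
        tracks = read_ground_truth(p)
        assert [t.agent_id for t in tracks] == [1, 2]
        assert tracks[0].points[0] == Point2D(10.5, 20.5)
        assert tracks[0].boxes[1] == BoundingBox(9, 19, 14, 24)
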