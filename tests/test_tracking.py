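"""Kalman filter, association, and track lifecycle."""

import itertools

import numpy as np
import pytest

from mosquitrack.detection import Frame
from mosquitrack.geometry import BoundingBox, Detection
from mosquitrack.tracking import (
    KalmanFilter,
    MultiObjectTracker,
    TrackerConfig,
    TrackStatus,
    UNMATCHED_COST,
    box_to_measurement,
    cosine_distance,
    extract_descriptor,
    squared_mahalanobis,
)


def make_frame(idx=0, size=64):
    return Frame(index=idx, pixels=np.full((size, size), 230, dtype=np.uint8))


def det_at(cx, cy, frame=0, w=8.0, h=8.0, conf=0.9):
    return Detection(
        frame=frame,
        box=BoundingBox(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2),
        confidence=conf,
    )


class TestKalman:
    def test_zero_velocity_prediction(self):
        kf = KalmanFilter()
        s = kf.initiate(np.array([10.0, 10.0, 1.0, 8.0]))
        s2 = kf.predict(s)
        assert s2.mean[:2] == pytest.approx([10.0, 10.0])

    def test_linear_motion_prediction(self):
        kf = KalmanFilter()
        s = kf.initiate(np.array([10.0, 10.0, 1.0, 8.0]))
        s.mean[4:6] = [2.0, -1.0]
        s2 = kf.predict(s)
        assert s2.mean[:2] == pytest.approx([12.0, 9.0])

    def test_predict_inflates_uncertainty(self):
        kf = KalmanFilter()
        s = kf.initiate(np.array([10.0, 10.0, 1.0, 8.0]))
        assert np.trace(kf.predict(s).covariance) > np.trace(s.covariance)

    def test_update_with_zero_innovation_keeps_position(self):
        kf = KalmanFilter()
        z = np.array([10.0, 10.0, 1.0, 8.0])
        s = kf.initiate(z)
        s2 = kf.update(s, z)
        assert s2.mean[:4] == pytest.approx(z)

    def test_update_moves_toward_measurement(self):
        kf = KalmanFilter()
        s = kf.initiate(np.array([10.0, 10.0, 1.0, 8.0]))
        s = kf.predict(s)
        z = np.array([14.0, 10.0, 1.0, 8.0])
        s2 = kf.update(s, z)
        assert 10.0 < s2.mean[0] < 14.0

    def test_gain_limits(self):
        z0 = np.array([10.0, 10.0, 1.0, 8.0])
        z1 = np.array([16.0, 12.0, 1.0, 8.0])
        # tiny measurement noise: posterior hugs the measurement
        tight = KalmanFilter(min_std_position=1e-4, min_std_size=1e-4, aspect_std=1e-4,
                             std_weight_position=1e-6)
        s = tight.initiate(z0)
        s.covariance = np.eye(8) * 100.0
        assert tight.update(s, z1).mean[:4] == pytest.approx(z1, abs=1e-2)
        # huge measurement noise: posterior stays at the prediction
        loose = KalmanFilter(min_std_position=1e4, min_std_size=1e4, aspect_std=1e4)
        s = loose.initiate(z0)
        s.covariance = np.eye(8)
        assert loose.update(s, z1).mean[:4] == pytest.approx(z0, abs=1e-2)

    def test_non_finite_measurement_rejected(self):
        kf = KalmanFilter()
        s = kf.initiate(np.array([10.0, 10.0, 1.0, 8.0]))
        with pytest.raises(ValueError):
            kf.update(s, np.array([np.nan, 0.0, 1.0, 8.0]))


class TestMahalanobis:
    def test_zero_innovation(self):
        assert squared_mahalanobis(np.zeros(4), np.eye(4)) == 0.0

    def test_identity_covariance(self):
        assert squared_mahalanobis(np.array([3.0, 4.0, 0.0, 0.0]), np.eye(4)) == pytest.approx(25.0)

    def test_covariance_scaling(self):
        e = np.array([1.0, 2.0, 0.5, -1.0])
        S = np.diag([2.0, 3.0, 1.0, 4.0])
        d = squared_mahalanobis(e, S)
        assert squared_mahalanobis(e, 5.0 * S) == pytest.approx(d / 5.0)

    def test_singular_covariance_raises(self):
        with pytest.raises(ValueError):
            squared_mahalanobis(np.ones(2), np.zeros((2, 2)))


class TestDescriptor:
    def test_unit_norm(self, disk_frame):
        d = extract_descriptor(disk_frame, BoundingBox(14, 24, 26, 36))
        assert np.linalg.norm(d) == pytest.approx(1.0)

    def test_identical_patches_identical_descriptors(self, disk_frame):
        box = BoundingBox(14, 24, 26, 36)
        a = extract_descriptor(disk_frame, box)
        b = extract_descriptor(disk_frame, box)
        assert np.array_equal(a, b)

    def test_contrast_inversion_changes_descriptor(self, disk_frame):
        box = BoundingBox(14, 24, 26, 36)
        a = extract_descriptor(disk_frame, box)
        inverted = Frame(index=0, pixels=(255 - disk_frame.pixels))
        b = extract_descriptor(inverted, box)
        assert cosine_distance(a, b) > 0

    def test_box_outside_frame_raises(self, disk_frame):
        with pytest.raises(ValueError):
            extract_descriptor(disk_frame, BoundingBox(100, 100, 120, 120))


class TestCosineDistance:
    def test_equal_vectors(self):
        v = np.array([0.6, 0.8])
        assert cosine_distance(v, v) == pytest.approx(0.0)

    def test_orthogonal(self):
        assert cosine_distance(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == pytest.approx(1.0)

    def test_partial_angle(self):
        b = np.array([np.sqrt(2) / 2, np.sqrt(2) / 2])
        assert cosine_distance(np.array([1.0, 0.0]), b) == pytest.approx(1 - np.sqrt(2) / 2)


class TestAssociate:
    def test_no_tracks_all_dets_unmatched(self):
        from mosquitrack.tracking import associate

        frame = make_frame()
        dets = [det_at(10, 10), det_at(40, 40)]
        matches, ut, ud = associate([], dets, frame)
        assert matches == [] and ut == [] and ud == [0, 1]

    def test_gated_pair_left_unmatched(self):
        from mosquitrack.tracking import associate

        frame = make_frame(size=128)
        tracker = MultiObjectTracker()
        tracker.step(make_frame(0, 128), [det_at(10, 10, frame=0)])
        track = tracker.tracks[0]
        far_det = det_at(110, 110, frame=1)
        matches, ut, ud = associate([track], [far_det], frame)
        assert matches == []
        assert ut == [0]
        assert ud == [0]  # far from every track: spawnable

    def test_hungarian_matches_brute_force_on_random_costs(self):
        # the assignment core: linear_sum_assignment against permutation
        # enumeration with the same finite unmatched cost semantics
        from scipy.optimize import linear_sum_assignment

        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = int(rng.integers(1, 7))
            m = int(rng.integers(1, 7))
            cost = rng.uniform(0, 1, size=(n, m))
            cost[rng.uniform(size=(n, m)) < 0.2] = UNMATCHED_COST
            rows, cols = linear_sum_assignment(cost)
            lsa_total = cost[rows, cols].sum()
            k = min(n, m)
            best = np.inf
            for subset in itertools.permutations(range(m), k):
                for rows_subset in itertools.combinations(range(n), k):
                    total = sum(cost[r, c] for r, c in zip(rows_subset, subset))
                    best = min(best, total)
            assert lsa_total == pytest.approx(best)


class TestLifecycle:
    def track_single(self, positions, max_age=30, n_init=3, size=128):
        tracker = MultiObjectTracker(TrackerConfig(max_age=max_age, n_init=n_init))
        for f, pos in enumerate(positions):
            dets = [det_at(*pos, frame=f)] if pos is not None else []
            tracker.step(make_frame(f, size), dets)
        return tracker

    def test_single_agent_single_confirmed_track(self):
        positions = [(10 + f, 10 + f) for f in range(10)]
        tracker = self.track_single(positions)
        confirmed = tracker.confirmed_tracks()
        assert len(confirmed) == 1
        assert sorted(confirmed[0].history) == list(range(10))

    def test_track_deleted_after_max_age_exceeded(self):
        positions = [(10 + f, 10) for f in range(6)] + [None] * 6
        tracker = self.track_single(positions, max_age=5)
        assert tracker.tracks == []  # deleted once time_since_update > max_age
        assert len(tracker.finished) == 1

    def test_dropout_within_max_age_keeps_identity(self):
        positions = [(10 + 2 * f, 10) for f in range(6)] + [None, None] + [
            (10 + 2 * f, 10) for f in range(8, 14)
        ]
        tracker = self.track_single(positions)
        confirmed = tracker.confirmed_tracks()
        assert len(confirmed) == 1
        frames = sorted(confirmed[0].history)
        assert 6 not in frames and 7 not in frames
        assert frames[-1] == 13

    def test_tentative_track_dies_on_miss(self):
        positions = [(10, 10), (12, 10), None]
        tracker = self.track_single(positions)
        assert tracker.confirmed_tracks() == []

    def test_out_of_order_frame_rejected(self):
        tracker = MultiObjectTracker()
        tracker.step(make_frame(3), [])
        with pytest.raises(ValueError):
            tracker.step(make_frame(3), [])

    def test_ids_unique_and_never_reused(self):
        tracker = MultiObjectTracker(TrackerConfig(max_age=1, n_init=1))
        seen = set()
        rng = np.random.default_rng(0)
        for f in range(30):
            dets = []
            if f % 3 != 2:  # intermittent far-apart detections force respawns
                x = 10 + 40 * (f % 3)
                dets = [det_at(x, 100, frame=f)]
            tracker.step(make_frame(f, 256), dets)
            live_ids = [t.id for t in tracker.tracks]
            assert len(live_ids) == len(set(live_ids))
            seen.update(live_ids)
        all_ids = [t.id for t in tracker.finished] + [t.id for t in tracker.tracks]
        assert len(all_ids) == len(set(all_ids))
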