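"""Multi-object tracking: Kalman prediction, Hungarian association, lifecycle.

The tracker follows the classic detection-based tracking-by-association
design: each identity carries a constant-velocity Kalman filter over the
box state (cx, cy, a, h) — center, width/height aspect ratio, height — and
their per-frame velocities. Candidate track/detection pairings are scored
by motion (squared Mahalanobis distance of the detection from the track's
predicted measurement distribution, gated at a chi-square quantile) plus
appearance (cosine distance between intensity-histogram descriptors,
minimized over a per-track gallery); the Hungarian algorithm solves the
assignment against a finite unmatched cost, so implausible forced pairings
lose to coasting. See :func:`associate` for the occlusion-specific rules
that carry identities through merged detections.

Track lifecycle: a new detection spawns a tentative track; n_init
consecutive hits confirm it; a miss while tentative deletes it; a confirmed
track survives up to max_age consecutive missed frames before deletion
(coasting on its motion model in between), which is what carries identities
through short occlusions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import chi2

from .geometry import BoundingBox, Detection
from .detection import Frame

__all__ = [
    "KalmanState",
    "KalmanFilter",
    "Track",
    "TrackStatus",
    "TrackerConfig",
    "MultiObjectTracker",
    "mahalanobis_sq",
    "UNMATCHED_COST",
    "squared_mahalanobis",
    "extract_descriptor",
    "cosine_distance",
    "associate",
    "box_to_measurement",
    "measurement_to_box",
]

_NDIM = 4  # measurement: (cx, cy, a, h)


def box_to_measurement(box: BoundingBox) -> np.ndarray:
    """(x_min, y_min, x_max, y_max) -> (cx, cy, aspect, height)."""
    w = box.width
    h = box.height
    cx = box.x_min + w / 2.0
    cy = box.y_min + h / 2.0
    a = w / h if h > 0 else 1.0
    return np.array([cx, cy, a, h], dtype=float)


def measurement_to_box(z: np.ndarray) -> BoundingBox:
    cx, cy, a, h = (float(v) for v in z[:4])
    w = a * h
    return BoundingBox(cx - w / 2.0, cy - h / 2.0, cx + w / 2.0, cy + h / 2.0)


@dataclass
class KalmanState:
    """8-dim Gaussian state: (cx, cy, a, h, vcx, vcy, va, vh)."""

    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).reshape(8)
        self.covariance = np.asarray(self.covariance, dtype=float).reshape(8, 8)


class KalmanFilter:
    """Constant-velocity Kalman filter on (cx, cy, a, h).

    Process and measurement noise scale with box height: the per-frame
    position standard deviation is h * std_weight_position and the velocity
    one h * std_weight_velocity, keeping uncertainty proportional to
    apparent target size. For very small targets (a mosquito body spans
    only ~10 px) the height-scaled stds would shrink below a pixel, far
    tighter than real detector jitter and flight maneuvering, so absolute
    floors apply. The aspect ratio of a small elongated body swings quickly
    as it turns, hence its own generous measurement std.
    """

    def __init__(
        self,
        std_weight_position: float = 1.0 / 20,
        std_weight_velocity: float = 1.0 / 160,
        min_std_position: float = 2.0,
        min_std_velocity: float = 0.6,
        aspect_std: float = 1.0,
        min_std_size: float = 2.0,
    ):
        self._std_pos = std_weight_position
        self._std_vel = std_weight_velocity
        self._min_pos = min_std_position
        self._min_vel = min_std_velocity
        self._aspect_std = aspect_std
        self._min_size = min_std_size
        self._F = np.eye(8)
        for i in range(4):
            self._F[i, i + 4] = 1.0  # dt = 1 frame
        self._H = np.eye(4, 8)

    def _pos_std(self, h: float) -> float:
        return max(self._std_pos * h, self._min_pos)

    def _vel_std(self, h: float) -> float:
        return max(self._std_vel * h, self._min_vel)

    def _size_std(self, h: float) -> float:
        return max(self._std_pos * h, self._min_size)

    def initiate(self, measurement: np.ndarray) -> KalmanState:
        """New track state from an unassociated detection: zero velocity,
        broad velocity uncertainty."""
        z = np.asarray(measurement, dtype=float)
        mean = np.concatenate([z, np.zeros(4)])
        h = z[3]
        std = [
            2 * self._pos_std(h),
            2 * self._pos_std(h),
            2 * self._aspect_std,
            2 * self._size_std(h),
            10 * self._vel_std(h),
            10 * self._vel_std(h),
            1e-2,
            10 * self._vel_std(h),
        ]
        return KalmanState(mean, np.diag(np.square(std)))

    def predict(self, state: KalmanState) -> KalmanState:
        """Propagate one frame under constant velocity, adding process noise."""
        h = state.mean[3]
        std = [
            self._pos_std(h),
            self._pos_std(h),
            1e-1 * self._aspect_std,
            0.5 * self._size_std(h),
            self._vel_std(h),
            self._vel_std(h),
            1e-3,
            self._vel_std(h),
        ]
        Q = np.diag(np.square(std))
        mean = self._F @ state.mean
        cov = self._F @ state.covariance @ self._F.T + Q
        return KalmanState(mean, cov)

    def project(self, state: KalmanState) -> tuple[np.ndarray, np.ndarray]:
        """Predicted measurement distribution (mean, innovation covariance)."""
        h = state.mean[3]
        std = [self._pos_std(h), self._pos_std(h), self._aspect_std, self._size_std(h)]
        R = np.diag(np.square(std))
        z = self._H @ state.mean
        S = self._H @ state.covariance @ self._H.T + R
        return z, S

    def project_for_gating(self, state: KalmanState) -> tuple[np.ndarray, np.ndarray]:
        """Like :meth:`project`, with the positional innovation variance
        capped at (10 x the position std)²: a track coasting for many frames
        would otherwise accumulate an arbitrarily large capture basin and
        swallow unrelated targets passing its last known neighbourhood. The
        cap applies to gating only — the measurement update uses the
        consistent, uncapped covariance.
        """
        z, S = self.project(state)
        cap = (10.0 * self._pos_std(state.mean[3])) ** 2
        S = S.copy()
        S[0, 0] = min(S[0, 0], cap)
        S[1, 1] = min(S[1, 1], cap)
        return z, S

    def update(self, state: KalmanState, measurement: np.ndarray) -> KalmanState:
        """Standard Kalman measurement update."""
        z = np.asarray(measurement, dtype=float)
        if not np.all(np.isfinite(z)):
            raise ValueError(f"non-finite measurement: {z}")
        z_pred, S = self.project(state)
        K = np.linalg.solve(S.T, (state.covariance @ self._H.T).T).T
        innovation = z - z_pred
        mean = state.mean + K @ innovation
        cov = state.covariance - K @ S @ K.T
        cov = (cov + cov.T) / 2.0  # enforce symmetry
        return KalmanState(mean, cov)

    def gating_distance(self, state: KalmanState, measurement: np.ndarray) -> float:
        z_pred, S = self.project_for_gating(state)
        return squared_mahalanobis(np.asarray(measurement, dtype=float) - z_pred, S)


def squared_mahalanobis(innovation: np.ndarray, S: np.ndarray) -> float:
    """d² = e' S⁻¹ e for innovation e and innovation covariance S."""
    innovation = np.asarray(innovation, dtype=float)
    S = np.asarray(S, dtype=float)
    try:
        sol = np.linalg.solve(S, innovation)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular innovation covariance") from exc
    return float(innovation @ sol)


def mahalanobis_sq(state: KalmanState, det: Detection, kf: KalmanFilter | None = None) -> float:
    """Squared Mahalanobis distance of a detection from a track's predicted
    measurement distribution."""
    kf = kf or KalmanFilter()
    return kf.gating_distance(state, box_to_measurement(det.box))


def extract_descriptor(frame: Frame, box: BoundingBox, bins: int = 16) -> np.ndarray:
    """L2-normalized intensity histogram of the patch under a box.

    A crude but deterministic appearance signature; a uniform (zero-mass)
    patch maps to the uniform unit vector so cosine distances stay defined.
    """
    H, W = frame.pixels.shape
    x0 = int(np.floor(box.x_min))
    y0 = int(np.floor(box.y_min))
    x1 = int(np.ceil(box.x_max))
    y1 = int(np.ceil(box.y_max))
    if x1 <= 0 or y1 <= 0 or x0 >= W or y0 >= H:
        raise ValueError(f"box {box} lies fully outside a {W}x{H} frame")
    patch = frame.pixels[max(y0, 0) : min(y1, H), max(x0, 0) : min(x1, W)]
    hist, _ = np.histogram(patch, bins=bins, range=(0, 255))
    hist = hist.astype(float)
    norm = np.linalg.norm(hist)
    if norm == 0:
        return np.full(bins, 1.0 / np.sqrt(bins))
    return hist / norm


def cosine_distance(a: np.ndarray, b: np.ndarray) -> float:
    """1 − a·b for unit vectors; in [0, 2]."""
    return float(1.0 - np.dot(a, b))


class TrackStatus(Enum):
    TENTATIVE = "tentative"
    CONFIRMED = "confirmed"
    DELETED = "deleted"


@dataclass
class TrackerConfig:
    """Tracker settings.

    max_age — consecutive undetected frames before a confirmed track is
    dropped (default 30, i.e. half a second at 60 frames/s); n_init —
    consecutive hits before a new track is confirmed; gating_quantile —
    chi-square quantile of the Mahalanobis gate on the 4-dim measurement.
    """

    max_age: int = 30
    n_init: int = 3
    gating_quantile: float = 0.95
    descriptor_bins: int = 16
    gallery_size: int = 50

    def __post_init__(self) -> None:
        if self.max_age < 1 or self.n_init < 1:
            raise ValueError("max_age and n_init must be >= 1")

    @property
    def gating_threshold(self) -> float:
        # 0.95 quantile at 4 d.o.f. is 9.4877
        return float(chi2.ppf(self.gating_quantile, df=_NDIM))


@dataclass
class Track:
    """One tracked identity and its lifecycle bookkeeping."""

    id: int
    state: KalmanState
    history: dict[int, BoundingBox] = field(default_factory=dict)
    descriptor_gallery: list[np.ndarray] = field(default_factory=list)
    hits: int = 0
    time_since_update: int = 0
    status: TrackStatus = TrackStatus.TENTATIVE

    @property
    def is_confirmed(self) -> bool:
        return self.status is TrackStatus.CONFIRMED


UNMATCHED_COST = 1.3  # cost of leaving a track/detection unassigned


def associate(
    tracks: list[Track],
    dets: list[Detection],
    frame: Frame,
    config: TrackerConfig = TrackerConfig(),
    kf: KalmanFilter | None = None,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Match tracks to detections by gated motion-plus-appearance cost.

    Cost(i, j) combines the normalized squared Mahalanobis distance (the
    motion term, in [0, 1] inside the chi-square gate) with the minimum
    cosine distance between detection j's descriptor and track i's gallery;
    pairs beyond the gate are infeasible. The assignment is solved by the
    Hungarian algorithm against a finite unmatched cost, so a track whose
    own detection is momentarily ungated coasts rather than forcing a
    worse cross-assignment. A small deterministic bias favours confirmed
    and recently updated tracks, so a freshly spawned duplicate can never
    take a detection from an established track on a cost tie.

    Two occlusion-specific rules, both using an absolute body-scale
    proximity test (within two box heights of a track's predicted
    position) rather than the covariance gate, so that a long-coasting
    track's inflated uncertainty cannot trigger them:

    * a matched detection that is also in the proximity of an *unmatched*
      confirmed track is treated as a merged measurement of two
      overlapping bodies and left unmatched, so both tracks coast through
      the overlap on their motion models;
    * an unmatched detection in the proximity of any track does not spawn
      a new track (it is a plausible measurement of an existing identity,
      not a new one).

    Returns (matches as (track_idx, det_idx) pairs, unmatched track
    indices, spawnable unmatched detection indices).
    """
    if not tracks or not dets:
        return [], list(range(len(tracks))), list(range(len(dets)))
    kf = kf or KalmanFilter()
    gate = config.gating_threshold
    descriptors = [extract_descriptor(frame, d.box, config.descriptor_bins) for d in dets]
    measurements = [box_to_measurement(d.box) for d in dets]
    cost = np.full((len(tracks), len(dets)), UNMATCHED_COST)
    near = np.zeros((len(tracks), len(dets)), dtype=bool)
    for i, trk in enumerate(tracks):
        bias = 0.01 * min(trk.time_since_update, 20)
        if trk.status is TrackStatus.TENTATIVE:
            bias += 0.02
        z_pred, S = kf.project_for_gating(trk.state)
        for j, z in enumerate(measurements):
            dist = float(np.hypot(z[0] - z_pred[0], z[1] - z_pred[1]))
            near[i, j] = dist <= 2.0 * max(z_pred[3], z[3])
            d2 = squared_mahalanobis(z - z_pred, S)
            if d2 > gate:
                continue
            if trk.descriptor_gallery:
                appearance = min(cosine_distance(g, descriptors[j]) for g in trk.descriptor_gallery)
            else:
                appearance = 1.0
            cost[i, j] = min(d2 / gate + 0.5 * appearance + bias, UNMATCHED_COST - 1e-9)
    rows, cols = linear_sum_assignment(cost)
    matches = [(int(r), int(c)) for r, c in zip(rows, cols) if cost[r, c] < UNMATCHED_COST]

    # merged-measurement rule: drop matches also claimed by a nearby
    # unmatched confirmed track, so both parties coast
    unmatched_now = {i for i in range(len(tracks))} - {r for r, _ in matches}
    ambiguous = [
        (r, c)
        for (r, c) in matches
        if any(
            tracks[u].status is TrackStatus.CONFIRMED and near[u, c]
            for u in unmatched_now
        )
    ]
    for pair in ambiguous:
        matches.remove(pair)

    # rescue: an unmatched detection near exactly one unmatched track is a
    # plain gate miss (e.g. a sharp turn blew the chi-square gate), not an
    # ambiguity — re-associate by proximity
    matched_t = {r for r, _ in matches}
    matched_d = {c for _, c in matches}
    ambiguous_t = {r for r, _ in ambiguous}
    ambiguous_d = {c for _, c in ambiguous}
    for j in range(len(dets)):
        if j in matched_d or j in ambiguous_d:
            continue
        cands = [
            i
            for i in range(len(tracks))
            if i not in matched_t and i not in ambiguous_t and near[i, j]
        ]
        if len(cands) == 1:
            matches.append((cands[0], j))
            matched_t.add(cands[0])
            matched_d.add(j)

    unmatched_tracks = [i for i in range(len(tracks)) if i not in matched_t]
    unmatched_dets = [
        j for j in range(len(dets)) if j not in matched_d and not near[:, j].any()
    ]
    return matches, unmatched_tracks, unmatched_dets


class MultiObjectTracker:
    """Frame-by-frame tracker maintaining a set of live tracks.

    Call :meth:`step` once per frame in increasing frame order; it returns
    the live (non-deleted) tracks after that frame. Identities are positive
    integers, unique within a run and never reused.
    """

    def __init__(self, config: TrackerConfig = TrackerConfig(), kf: KalmanFilter | None = None):
        self.config = config
        self.kf = kf or KalmanFilter()
        self.tracks: list[Track] = []
        self.finished: list[Track] = []  # confirmed tracks that aged out
        self._next_id = 1
        self._last_frame: int | None = None

    def step(self, frame: Frame, dets: list[Detection]) -> list[Track]:
        if self._last_frame is not None and frame.index <= self._last_frame:
            raise ValueError(f"frames must be strictly increasing, got {frame.index} after {self._last_frame}")
        self._last_frame = frame.index

        for trk in self.tracks:
            trk.state = self.kf.predict(trk.state)

        matches, unmatched_tracks, unmatched_dets = associate(self.tracks, dets, frame, self.config, self.kf)

        for ti, di in matches:
            trk = self.tracks[ti]
            det = dets[di]
            trk.state = self.kf.update(trk.state, box_to_measurement(det.box))
            trk.history[frame.index] = det.box
            trk.hits += 1
            trk.time_since_update = 0
            desc = extract_descriptor(frame, det.box, self.config.descriptor_bins)
            trk.descriptor_gallery.append(desc)
            if len(trk.descriptor_gallery) > self.config.gallery_size:
                trk.descriptor_gallery.pop(0)
            if trk.status is TrackStatus.TENTATIVE and trk.hits >= self.config.n_init:
                trk.status = TrackStatus.CONFIRMED

        for ti in unmatched_tracks:
            trk = self.tracks[ti]
            trk.time_since_update += 1
            if trk.status is TrackStatus.TENTATIVE:
                trk.status = TrackStatus.DELETED
            elif trk.time_since_update > self.config.max_age:
                trk.status = TrackStatus.DELETED

        for di in unmatched_dets:
            det = dets[di]
            state = self.kf.initiate(box_to_measurement(det.box))
            trk = Track(id=self._next_id, state=state, hits=1)
            self._next_id += 1
            trk.history[frame.index] = det.box
            trk.descriptor_gallery.append(extract_descriptor(frame, det.box, self.config.descriptor_bins))
            if self.config.n_init <= 1:
                trk.status = TrackStatus.CONFIRMED
            self.tracks.append(trk)

        for t in self.tracks:
            if t.status is TrackStatus.DELETED and t.hits >= self.config.n_init:
                self.finished.append(t)
        self.tracks = [t for t in self.tracks if t.status is not TrackStatus.DELETED]
        return list(self.tracks)

    def confirmed_tracks(self) -> list[Track]:
        """All tracks that ever reached confirmation, live or finished."""
        live = [t for t in self.tracks if t.is_confirmed]
        return sorted(self.finished + live, key=lambda t: t.id)
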