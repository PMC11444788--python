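"""Trajectory evaluation against ground truth.

Two headline statistics for a tracked flight:

* **MAE** — mean absolute error over frames, summing the absolute x and y
  deviations of the estimated centroid from the ground-truth centroid, in
  pixels: ``MAE = (1/n) Σ_f |x_f − x̂_f| + |y_f − ŷ_f|``.
* **Tolerance accuracy** — the percentage of frames whose estimated
  centroid deviates by strictly less than a tolerance (default 6 px) on
  *both* axes. Six pixels is half an average mosquito body length; a
  :func:`derive_tolerance` helper recomputes it from measured body lengths.

Occlusion analysis finds frame intervals where two identities' boxes
overlap with IoU strictly above a threshold (default 0.25), and scores
whether the tracker carried each identity through the event by comparing
nearest-centroid assignments immediately before and after it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import linear_sum_assignment

from .geometry import BoundingBox, Point2D, iou
from .postprocess import Trajectory, round_pct

__all__ = [
    "GroundTruthTrack",
    "OcclusionEvent",
    "EvalReport",
    "mae",
    "frame_is_accurate",
    "accuracy_percentage",
    "derive_tolerance",
    "detect_occlusions",
    "score_identity_preservation",
    "match_trajectories_to_ground_truth",
    "read_ground_truth",
]

DEFAULT_TOLERANCE_PX = 6.0
DEFAULT_OCCLUSION_IOU = 0.25


@dataclass
class GroundTruthTrack:
    """True per-frame centroid (and optionally box) series for one agent."""

    agent_id: int
    points: dict[int, Point2D] = field(default_factory=dict)
    boxes: dict[int, BoundingBox] = field(default_factory=dict)


@dataclass
class OcclusionEvent:
    """A maximal run of frames where a pair of identities overlap."""

    pair: tuple[int, int]
    start_frame: int
    end_frame: int
    resolved_correctly: bool | None = None

    def __post_init__(self) -> None:
        if self.start_frame > self.end_frame:
            raise ValueError("start_frame must be <= end_frame")


@dataclass
class EvalReport:
    n_frames: int
    mae: float
    accuracy_pct: float
    n_inaccurate: int
    tolerance: float
    occlusions_total: int = 0
    occlusions_correct: int = 0

    def to_dict(self) -> dict:
        return {
            "n_frames": self.n_frames,
            "mae": self.mae,
            "accuracy_pct": self.accuracy_pct,
            "n_inaccurate": self.n_inaccurate,
            "tolerance": self.tolerance,
            "occlusions_total": self.occlusions_total,
            "occlusions_correct": self.occlusions_correct,
        }


def _shared_frames(est: Trajectory, gt: GroundTruthTrack) -> list[int]:
    est_frames = set(est.points)
    gt_frames = set(gt.points)
    if est_frames != gt_frames:
        missing_est = sorted(gt_frames - est_frames)[:10]
        missing_gt = sorted(est_frames - gt_frames)[:10]
        raise ValueError(
            "estimate and ground truth must cover the same frames; "
            f"missing from estimate: {missing_est}; missing from ground truth: {missing_gt}"
        )
    return sorted(est_frames)


def mae(est: Trajectory, gt: GroundTruthTrack) -> float:
    """Mean absolute error in pixels, L1 over both axes, averaged over frames."""
    frames = _shared_frames(est, gt)
    if not frames:
        raise ValueError("empty frame set")
    total = 0.0
    for f in frames:
        e, g = est.point(f), gt.points[f]
        total += abs(e.x - g.x) + abs(e.y - g.y)
    return total / len(frames)


def frame_is_accurate(est: Point2D, gt: Point2D, tolerance: float = DEFAULT_TOLERANCE_PX) -> bool:
    """Strictly-within-tolerance test on both axes."""
    return abs(est.x - gt.x) < tolerance and abs(est.y - gt.y) < tolerance


def accuracy_percentage(
    est: Trajectory, gt: GroundTruthTrack, tolerance: float = DEFAULT_TOLERANCE_PX
) -> float:
    """Percentage of frames accurate at the given pixel tolerance."""
    frames = _shared_frames(est, gt)
    if not frames:
        raise ValueError("empty frame set")
    good = sum(1 for f in frames if frame_is_accurate(est.point(f), gt.points[f], tolerance))
    return 100.0 * good / len(frames)


def derive_tolerance(body_lengths: list[float]) -> float:
    """Half the mean body length: the recommended accuracy tolerance.

    Callers sample body lengths from a handful of frames of their own
    footage (a seeded random selection of ~20 frames is conventional).
    """
    if not body_lengths:
        raise ValueError("body_lengths must be non-empty")
    return float(np.mean(body_lengths)) / 2.0


def detect_occlusions(
    boxes_by_id: dict[int, dict[int, BoundingBox]],
    iou_threshold: float = DEFAULT_OCCLUSION_IOU,
) -> list[OcclusionEvent]:
    """Extract occlusion events from per-identity box series.

    For every unordered identity pair, each maximal run of consecutive
    frames where the pair's IoU strictly exceeds ``iou_threshold`` becomes
    one event. Overlap exactly at the threshold does not count.
    """
    events: list[OcclusionEvent] = []
    for id_a, id_b in itertools.combinations(sorted(boxes_by_id), 2):
        frames = sorted(set(boxes_by_id[id_a]) & set(boxes_by_id[id_b]))
        start: int | None = None
        prev: int | None = None
        for f in frames:
            overlapping = iou(boxes_by_id[id_a][f], boxes_by_id[id_b][f]) > iou_threshold
            contiguous = prev is not None and f == prev + 1
            if overlapping:
                if start is None or not contiguous:
                    if start is not None:
                        events.append(OcclusionEvent((id_a, id_b), start, prev))
                    start = f
            else:
                if start is not None:
                    events.append(OcclusionEvent((id_a, id_b), start, prev))
                    start = None
            prev = f
        if start is not None:
            events.append(OcclusionEvent((id_a, id_b), start, prev))
    events.sort(key=lambda e: (e.start_frame, e.pair))
    return events


def _nearest_agent(p: Point2D, gts: list[GroundTruthTrack], frame: int) -> int | None:
    best_id, best_d = None, np.inf
    for gt in gts:
        if frame not in gt.points:
            continue
        g = gt.points[frame]
        d = (p.x - g.x) ** 2 + (p.y - g.y) ** 2
        if d < best_d or (d == best_d and best_id is not None and gt.agent_id < best_id):
            best_id, best_d = gt.agent_id, d
    return best_id


def _observed(t: Trajectory, frame: int) -> bool:
    if frame not in t.points:
        return False
    from .postprocess import PointSource

    return t.points[frame][1] is PointSource.OBSERVED


def _nearest_trajectory(g: Point2D, trajs: list[Trajectory], frame: int) -> Trajectory | None:
    best, best_d = None, np.inf
    for t in trajs:
        if not _observed(t, frame):
            continue
        p = t.point(frame)
        d = (p.x - g.x) ** 2 + (p.y - g.y) ** 2
        if d < best_d or (d == best_d and best is not None and t.track_id < best.track_id):
            best, best_d = t, d
    return best


def score_identity_preservation(
    events: list[OcclusionEvent],
    est: list[Trajectory],
    gt: list[GroundTruthTrack],
) -> tuple[int, int]:
    """Count occlusion events the tracker resolved with identities intact.

    For each event (over ground-truth agent pairs), each involved agent is
    paired with its nearest estimated trajectory at the last frame before
    the event, and each of those estimated identities is mapped back to its
    nearest agent at the first frame after the event where all parties are
    observed. The event is correct iff both round trips return the original
    agent. Events where any mapping is undefined (missing frames, or both
    agents claiming the same estimated identity) are undetermined and
    excluded from the total. Returns (correct, total).
    """
    gt_by_id = {g.agent_id: g for g in gt}
    correct = 0
    total = 0
    for ev in events:
        a_id, b_id = ev.pair
        if a_id not in gt_by_id or b_id not in gt_by_id:
            continue
        ga, gb = gt_by_id[a_id], gt_by_id[b_id]
        pre_map = _mapping_at(ga, gb, est, range(ev.start_frame - 1, -1, -1))
        if pre_map is None:
            continue
        ta, tb = pre_map
        last_frame = max(max(ga.points, default=-1), max(gb.points, default=-1))
        post = _first_frame_after(ga, gb, ta, tb, ev.end_frame, last_frame)
        if post is None:
            continue
        ok_a = _nearest_agent(ta.point(post), [ga, gb], post) == a_id
        ok_b = _nearest_agent(tb.point(post), [ga, gb], post) == b_id
        total += 1
        ev.resolved_correctly = ok_a and ok_b
        if ev.resolved_correctly:
            correct += 1
    return correct, total


def _mapping_at(
    ga: GroundTruthTrack, gb: GroundTruthTrack, est: list[Trajectory], frames
) -> tuple[Trajectory, Trajectory] | None:
    """First frame in the given order where each agent has its own distinct
    nearest observed estimated trajectory."""
    for f in frames:
        if f not in ga.points or f not in gb.points:
            continue
        ta = _nearest_trajectory(ga.points[f], est, f)
        tb = _nearest_trajectory(gb.points[f], est, f)
        if ta is not None and tb is not None and ta.track_id != tb.track_id:
            return ta, tb
    return None


def _first_frame_after(
    ga: GroundTruthTrack,
    gb: GroundTruthTrack,
    ta: Trajectory,
    tb: Trajectory,
    end: int,
    last_frame: int,
) -> int | None:
    """First frame after the event where both pre-event estimated identities
    are observed again and both agents are in ground truth."""
    for f in range(end + 1, last_frame + 1):
        if f not in ga.points or f not in gb.points:
            continue
        if _observed(ta, f) and _observed(tb, f):
            return f
    return None


def match_trajectories_to_ground_truth(
    est: list[Trajectory], gt: list[GroundTruthTrack]
) -> dict[int, int]:
    """One-to-one trajectory/agent matching by minimal summed centroid distance.

    Returns a map track_id -> agent_id (Hungarian over mean per-frame
    centroid distance on shared frames; pairs with no shared frames are
    infeasible and left unmatched).
    """
    if not est or not gt:
        return {}
    BIG = 1e12
    cost = np.full((len(est), len(gt)), BIG)
    for i, t in enumerate(est):
        for j, g in enumerate(gt):
            shared = [f for f in t.points if f in g.points]
            if not shared:
                continue
            d = 0.0
            for f in shared:
                p, q = t.point(f), g.points[f]
                d += np.hypot(p.x - q.x, p.y - q.y)
            cost[i, j] = d / len(shared)
    rows, cols = linear_sum_assignment(cost)
    return {est[r].track_id: gt[c].agent_id for r, c in zip(rows, cols) if cost[r, c] < BIG}


def read_ground_truth(path: str | Path) -> list[GroundTruthTrack]:
    """Read a delimited ground-truth file.

    Format: ``frame, agent_id, x, y[, x_min, y_min, x_max, y_max]``, comma-
    delimited, header optional.
    """
    tracks: dict[int, GroundTruthTrack] = {}
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = [f.strip() for f in line.split(",")]
            if lineno == 1:
                try:
                    float(fields[0])
                except ValueError:
                    continue  # header
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected at least 4 columns")
            frame = int(fields[0])
            agent = int(fields[1])
            x, y = float(fields[2]), float(fields[3])
            trk = tracks.setdefault(agent, GroundTruthTrack(agent_id=agent))
            trk.points[frame] = Point2D(x, y)
            if len(fields) >= 8:
                trk.boxes[frame] = BoundingBox(*(float(v) for v in fields[4:8]))
    return [tracks[k] for k in sorted(tracks)]
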