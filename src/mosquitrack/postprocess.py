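"""Trajectory post-processing: short-track filtration and gap interpolation.

Filtration removes identities observed in fewer than a set percentage of
the video's frames — these are typically spurious, short-lived objects such
as specular reflections. Interpolation then fills frames missing from the
interior of each surviving trajectory with a cubic spline (not-a-knot
boundary conditions), fitted independently to x(frame) and y(frame) over
the observed points. The interpolant passes through every observed point;
leading and trailing gaps are never extrapolated.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.interpolate import BarycentricInterpolator, CubicSpline

from .geometry import BoundingBox, Point2D, centroid

__all__ = [
    "PointSource",
    "Trajectory",
    "FiltrationConfig",
    "filter_short_tracks",
    "interpolate_gaps",
    "interpolation_percentage",
    "trajectory_from_history",
    "round_pct",
]


class PointSource(Enum):
    OBSERVED = "observed"
    INTERPOLATED = "interpolated"


@dataclass
class Trajectory:
    """Per-frame centroid series for one identity, with provenance flags."""

    track_id: int
    points: dict[int, tuple[Point2D, PointSource]] = field(default_factory=dict)

    def frames(self) -> list[int]:
        return sorted(self.points)

    def observed_frames(self) -> list[int]:
        return sorted(f for f, (_, src) in self.points.items() if src is PointSource.OBSERVED)

    def interpolated_frames(self) -> list[int]:
        return sorted(f for f, (_, src) in self.points.items() if src is PointSource.INTERPOLATED)

    def point(self, frame: int) -> Point2D:
        return self.points[frame][0]


def trajectory_from_history(track_id: int, history: dict[int, BoundingBox]) -> Trajectory:
    """Build an observed-only trajectory from a track's box history."""
    pts = {f: (centroid(b), PointSource.OBSERVED) for f, b in history.items()}
    return Trajectory(track_id=track_id, points=pts)


@dataclass(frozen=True)
class FiltrationConfig:
    """min_presence_pct: identities observed in strictly fewer than this
    percentage of the video's total frames are removed (default 5%)."""

    min_presence_pct: float = 5.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_presence_pct <= 100.0:
            raise ValueError("min_presence_pct must lie in [0, 100]")


def filter_short_tracks(
    tracks: list[Trajectory], total_frames: int, config: FiltrationConfig = FiltrationConfig()
) -> list[Trajectory]:
    """Drop trajectories observed for less than min_presence_pct of the video.

    Only observed (not interpolated) frames count toward presence; the rule
    is strict, so a track at exactly the threshold is kept.
    """
    if total_frames < 1:
        raise ValueError("total_frames must be >= 1")
    cutoff = config.min_presence_pct / 100.0 * total_frames
    return [t for t in tracks if len(t.observed_frames()) >= cutoff]


def _interpolant(frames: np.ndarray, values: np.ndarray):
    # Cubic needs >= 4 knots for not-a-knot; degrade gracefully below that.
    if len(frames) >= 4:
        return CubicSpline(frames, values, bc_type="not-a-knot")
    return BarycentricInterpolator(frames, values)  # linear / quadratic


def interpolate_gaps(traj: Trajectory, max_gap: int | None = None) -> Trajectory:
    """Fill interior missing frames of a trajectory by spline interpolation.

    Every absent frame strictly between the first and last observed frames
    is filled (x and y independently) and flagged interpolated; observed
    points are untouched. With fewer than 4 observed points the interpolant
    degrades to quadratic/linear; with fewer than 2, nothing is filled.
    ``max_gap`` optionally caps the length of a run of consecutive missing
    frames that will be filled; longer runs are left absent.
    """
    obs = traj.observed_frames()
    out = Trajectory(track_id=traj.track_id, points=dict(traj.points))
    if len(obs) < 2:
        return out
    frames = np.array(obs, dtype=float)
    xs = np.array([traj.point(f).x for f in obs])
    ys = np.array([traj.point(f).y for f in obs])
    fx = _interpolant(frames, xs)
    fy = _interpolant(frames, ys)

    missing = [f for f in range(obs[0] + 1, obs[-1]) if f not in traj.points]
    runs = _consecutive_runs(missing)
    for run in runs:
        if max_gap is not None and len(run) > max_gap:
            continue
        for f in run:
            p = Point2D(float(fx(f)), float(fy(f)))
            out.points[f] = (p, PointSource.INTERPOLATED)
    return out


def _consecutive_runs(frames: list[int]) -> list[list[int]]:
    runs: list[list[int]] = []
    for f in frames:
        if runs and f == runs[-1][-1] + 1:
            runs[-1].append(f)
        else:
            runs.append([f])
    return runs


def interpolation_percentage(traj: Trajectory, total_frames: int) -> float:
    """Interpolated frames as a percentage of the video's total frames."""
    if total_frames < 1:
        raise ValueError("total_frames must be >= 1")
    return 100.0 * len(traj.interpolated_frames()) / total_frames


def round_pct(value: float, ndigits: int = 2) -> float:
    """Round half away from zero, as percentages are conventionally printed."""
    d = decimal.Decimal(repr(value)).quantize(
        decimal.Decimal(1).scaleb(-ndigits), rounding=decimal.ROUND_HALF_UP
    )
    return float(d)
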