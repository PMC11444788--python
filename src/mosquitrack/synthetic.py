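"""Synthetic flight-video generator with exact ground truth.

Emulates the recording regime of an infrared laboratory cage: ~1040x1024 px
grayscale frames at 60 frames/s, up to five small dark agents (ellipses a
dozen pixels long) on a light background, flying smooth stochastic paths
with occasional forced crossings (occlusions), brief per-frame detection
dropouts, and optional short-lived specular "reflection" blobs. Every
pixel and every ground-truth coordinate is reproducible from a single seed.

Kinematics are a mean-reverting (Ornstein-Uhlenbeck-style) velocity random
walk with reflective arena boundaries: smooth, bounded, and tunable, which
is all that a tracker benchmark needs; no attempt is made to model real
mosquito flight dynamics.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import imageio.v3 as iio
import numpy as np

from .detection import Frame
from .evaluation import GroundTruthTrack
from .geometry import BoundingBox, Point2D

__all__ = [
    "SynthConfig",
    "AgentTrajectory",
    "simulate_trajectories",
    "render_frames",
    "iter_rendered_frames",
    "dropout_mask",
    "write_dataset",
    "ground_truth_tracks",
]


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings.

    Defaults follow the target recording regime: 1040x1024 px, 60 frames/s,
    5 agents, 12 px mean body length (so the half-body-length accuracy
    tolerance recipe yields 6 px). ``speed`` is the RMS flight speed in
    px/frame (3 px/frame = 180 px/s, a plausible cage-flight speed at
    roughly millimetre-per-pixel scale); ``smoothness`` in [0, 1) is the
    one-frame velocity autocorrelation of the mean-reverting walk.
    ``dropout_rate`` is the per-agent-per-frame probability that the agent
    is not rendered (emulating a missed detection); ``min_separation`` > 0
    confines agents to disjoint arena cells so their paths never come
    closer than that many pixels. Forced crossings are transversal flybys:
    the pair's relative speed at the meeting frame must be at least
    ``crossing_min_speed_frac`` of the RMS speed and the resulting approach
    event may last at most ``crossing_max_duration`` frames, so the two
    agents cross with disjoint entry and exit paths rather than travelling
    together.
    """

    width: int = 1040
    height: int = 1024
    fps: float = 60.0
    n_agents: int = 5
    duration: float = 2.0
    speed: float = 3.0
    smoothness: float = 0.95
    body_length: float = 12.0
    body_width: float = 4.0
    background: float = 230.0
    contrast: float = 190.0
    dropout_rate: float = 0.0
    n_forced_crossings: int = 0
    crossing_min_speed_frac: float = 0.8
    crossing_max_duration: int = 12
    noise_std: float = 2.0
    min_separation: float = 0.0
    n_reflections: int = 0
    reflection_duration: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_agents < 1:
            raise ValueError("n_agents must be >= 1")
        if not 0.0 <= self.smoothness < 1.0:
            raise ValueError("smoothness must lie in [0, 1)")
        if self.min_separation > 0 and self.n_forced_crossings > 0:
            raise ValueError("min_separation and forced crossings are mutually exclusive")

    @property
    def n_frames(self) -> int:
        return int(self.fps * self.duration)


@dataclass
class AgentTrajectory:
    """Ground-truth path of one agent: per-frame center, heading, body axes."""

    agent_id: int
    centers: np.ndarray  # (n_frames, 2) float, (x, y)
    orientations: np.ndarray  # (n_frames,) radians
    semi_axes: tuple[float, float]  # (along-body, across-body) px

    def box(self, frame: int) -> BoundingBox:
        """Axis-aligned bounding box of the oriented body ellipse."""
        a, b = self.semi_axes
        th = self.orientations[frame]
        hx = float(np.hypot(a * np.cos(th), b * np.sin(th)))
        hy = float(np.hypot(a * np.sin(th), b * np.cos(th)))
        cx, cy = self.centers[frame]
        return BoundingBox(cx - hx, cy - hy, cx + hx, cy + hy)


def _streams(config: SynthConfig) -> dict[str, np.random.Generator]:
    """Named independent RNG streams, all derived from the single seed."""
    root = np.random.SeedSequence(config.seed)
    names = ["motion", "noise", "dropout", "reflections", "crossings"]
    return {n: np.random.default_rng(s) for n, s in zip(names, root.spawn(len(names)))}


def _cell_bounds(config: SynthConfig) -> list[tuple[float, float, float, float]]:
    """Disjoint per-agent arena cells guaranteeing min_separation."""
    n = config.n_agents
    ncols = int(np.ceil(np.sqrt(n)))
    nrows = int(np.ceil(n / ncols))
    pad = config.min_separation / 2.0 + config.body_length
    cw, ch = config.width / ncols, config.height / nrows
    cells = []
    for k in range(n):
        r, c = divmod(k, ncols)
        x0, y0 = c * cw + pad, r * ch + pad
        x1, y1 = (c + 1) * cw - pad, (r + 1) * ch - pad
        if x1 <= x0 or y1 <= y0:
            raise ValueError("arena too small for the requested separation")
        cells.append((x0, y0, x1, y1))
    return cells


def _reflect(pos: float, vel: float, lo: float, hi: float) -> tuple[float, float]:
    if pos < lo:
        return 2 * lo - pos, -vel
    if pos > hi:
        return 2 * hi - pos, -vel
    return pos, vel


def simulate_trajectories(config: SynthConfig) -> list[AgentTrajectory]:
    """Simulate smooth stochastic flight paths with optional forced crossings.

    Velocities follow a mean-reverting random walk whose stationary RMS
    speed equals ``config.speed``, with smooth wall avoidance and a top
    speed of twice the RMS. When ``n_forced_crossings`` > 0, exactly that
    many pairwise approach events (maximal runs of frames where some
    pair's distance falls below one body length) are produced by rigidly
    translating whole paths so scheduled pairs meet; each realized event
    must be a genuine transversal flyby (see :func:`_valid_crossings`),
    and the simulation is deterministically re-drawn until the realized
    events match. Fully reproducible from the seed.
    """
    for attempt in range(300):
        trajs = _simulate_once(config, attempt)
        if trajs is None:
            continue
        if config.n_forced_crossings == 0:
            return trajs
        if _valid_crossings(trajs, config):
            return trajs
    raise ValueError(
        f"could not realize exactly {config.n_forced_crossings} crossings "
        f"with {config.n_agents} agents in {config.n_frames} frames"
    )


def _simulate_once(config: SynthConfig, attempt: int) -> list[AgentTrajectory] | None:
    root = np.random.SeedSequence(entropy=(config.seed, 7919 * attempt))
    rng = np.random.default_rng(root)
    n_frames = config.n_frames
    n = config.n_agents
    a = config.smoothness
    sigma_axis = config.speed / np.sqrt(2.0)  # per-axis stationary std
    kick = sigma_axis * np.sqrt(1.0 - a * a)

    if config.min_separation > 0:
        cells = _cell_bounds(config)
    else:
        m = config.body_length
        cells = [(m, m, config.width - 1 - m, config.height - 1 - m)] * n

    pos = np.empty((n, 2))
    for k, (x0, y0, x1, y1) in enumerate(cells):
        pos[k] = [rng.uniform(x0, x1), rng.uniform(y0, y1)]
    vel = rng.normal(0.0, sigma_axis, size=(n, 2))

    # Smooth wall avoidance: inside a margin band the agent is steered back
    # toward the interior (mosquitoes turn near walls, they do not bounce);
    # reflection remains as a backstop so positions never leave the arena.
    margin = 3.0 * config.body_length
    steer = 0.6 * config.speed
    vmax = 2.0 * config.speed  # top flight speed, px/frame

    centers = np.empty((n_frames, n, 2))
    for f in range(n_frames):
        centers[f] = pos
        vel = a * vel + kick * rng.normal(0.0, 1.0, size=(n, 2))
        speed_now = np.linalg.norm(vel, axis=1, keepdims=True)
        np.clip(speed_now, 1e-9, None, out=speed_now)
        vel *= np.minimum(1.0, vmax / speed_now)
        for k, (x0, y0, x1, y1) in enumerate(cells):
            for axis, (lo, hi) in enumerate(((x0, x1), (y0, y1))):
                m = min(margin, (hi - lo) / 3.0)
                if pos[k, axis] < lo + m:
                    vel[k, axis] += steer * (lo + m - pos[k, axis]) / m
                elif pos[k, axis] > hi - m:
                    vel[k, axis] -= steer * (pos[k, axis] - (hi - m)) / m
        pos = pos + vel
        for k, (x0, y0, x1, y1) in enumerate(cells):
            pos[k, 0], vel[k, 0] = _reflect(pos[k, 0], vel[k, 0], x0, x1)
            pos[k, 1], vel[k, 1] = _reflect(pos[k, 1], vel[k, 1], y0, y1)

    if config.n_forced_crossings > 0:
        if not _apply_crossings(centers, config, rng):
            return None

    trajs = []
    semi = (config.body_length / 2.0, config.body_width / 2.0)
    for k in range(n):
        c = centers[:, k, :]
        d = np.gradient(c, axis=0)
        orient = np.arctan2(d[:, 1], d[:, 0])
        trajs.append(AgentTrajectory(agent_id=k + 1, centers=c, orientations=orient, semi_axes=semi))
    return trajs


def _apply_crossings(centers: np.ndarray, config: SynthConfig, rng: np.random.Generator) -> bool:
    """Translate whole paths so scheduled pairs meet below one body length.

    Each crossing rigidly shifts one not-yet-shifted agent's entire path so
    that it passes within a fraction of a body length of its partner at the
    scheduled frame. A rigid translation leaves the path's own kinematics
    untouched, so the encounter is a natural transversal crossing rather
    than an artificial swerve. At most n_agents - 1 crossings are feasible
    this way (each needs a fresh agent to shift). Returns False when a
    shifted path would leave the arena, signalling the caller to redraw.
    """
    n_frames, n, _ = centers.shape
    if n < 2:
        raise ValueError("forced crossings require at least 2 agents")
    k = config.n_forced_crossings
    if k > n - 1:
        raise ValueError(
            f"at most {n - 1} forced crossings are feasible with {n} agents; requested {k}"
        )
    lo, hi = int(0.15 * n_frames), int(0.85 * n_frames)
    if hi - lo < k:
        raise ValueError("video too short for the requested crossings")
    times = np.linspace(lo, hi, k, dtype=int) if k > 1 else np.array([(lo + hi) // 2])
    margin = 1.0 + config.body_length
    for i, t_k in enumerate(times):
        ia, ib = i, i + 1  # ia already placed (possibly shifted), ib fresh
        v_a = (centers[t_k + 1, ia] - centers[t_k - 1, ia]) / 2.0
        v_b = (centers[t_k + 1, ib] - centers[t_k - 1, ib]) / 2.0
        if np.linalg.norm(v_a - v_b) < config.crossing_min_speed_frac * config.speed:
            return False  # not a transversal flyby; redraw
        angle = rng.uniform(0.0, 2.0 * np.pi)
        miss = 0.25 * config.body_length
        target = centers[t_k, ia] + miss * np.array([np.cos(angle), np.sin(angle)])
        delta = target - centers[t_k, ib]
        shifted = centers[:, ib, :] + delta
        if (
            shifted[:, 0].min() < margin
            or shifted[:, 0].max() > config.width - margin
            or shifted[:, 1].min() < margin
            or shifted[:, 1].max() > config.height - margin
        ):
            return False
        centers[:, ib, :] = shifted
    return True


def _valid_crossings(trajs: list[AgentTrajectory], config: SynthConfig) -> bool:
    """Verify the realized approach events are clean transversal flybys.

    Exactly ``n_forced_crossings`` maximal runs of inter-agent distance
    below one body length must exist, each a genuine pass-through with
    disjoint entry and exit paths: short (at most ``crossing_max_duration``
    frames), with the pair's relative speed at least
    ``crossing_min_speed_frac`` of the RMS flight speed throughout, with
    neither agent reversing its heading across the encounter, and with the
    two agents swapping sides (the relative-position vector flips).
    Encounters that are rebounds, hairpin turns or joint travel fail one of
    these and force a redraw.
    """
    n = len(trajs)
    n_runs = 0
    vmin = config.crossing_min_speed_frac * config.speed
    for i in range(n):
        for j in range(i + 1, n):
            rel = trajs[j].centers - trajs[i].centers
            d = np.linalg.norm(rel, axis=1)
            vrel = np.linalg.norm(np.gradient(rel, axis=0), axis=1)
            close = np.concatenate([[False], d < config.body_length, [False]])
            starts = np.flatnonzero(close[1:] & ~close[:-1])
            ends = np.flatnonzero(~close[1:] & close[:-1])
            for s, e in zip(starts, ends):
                n_runs += 1
                if e - s > config.crossing_max_duration:
                    return False
                w0 = max(s - 4, 0)
                w1 = min(e + 4, len(d))
                if w0 >= s or w1 <= e or vrel[w0:w1].min() < vmin:
                    return False
                if float(rel[w0] @ rel[w1 - 1]) >= 0.0:
                    return False  # sides did not swap: no true crossing
                for traj in (trajs[i], trajs[j]):
                    v_in = traj.centers[s] - traj.centers[w0]
                    v_out = traj.centers[w1 - 1] - traj.centers[e - 1]
                    if float(v_in @ v_out) <= 0.0:
                        return False  # hairpin: entry and exit not disjoint
    return n_runs == config.n_forced_crossings


def dropout_mask(config: SynthConfig) -> np.ndarray:
    """(n_frames, n_agents) boolean mask of agent-frames rendered invisible.

    Recomputable by callers (it depends only on the config), so tests and
    evaluations know exactly which frames were dropped.
    """
    rng = _streams(config)["dropout"]
    return rng.random((config.n_frames, config.n_agents)) < config.dropout_rate


def _reflection_schedule(
    config: SynthConfig, trajs: list[AgentTrajectory] | None = None
) -> list[tuple[int, int, float, float, float]]:
    """(start, duration, x, y, radius) for each synthetic reflection blob.

    Reflections emulate static specular spots on the cage wall: spatially
    distinct from the flying agents (a spot coincident with a body would
    never register as a separate identity). When trajectories are given,
    candidate positions keep a clear margin from every agent position
    during the reflection's active window plus the tracker-relevant
    aftermath; the farthest candidate wins if no draw satisfies the margin.
    """
    if config.n_reflections == 0:
        return []
    rng = _streams(config)["reflections"]
    out = []
    clearance = 4.0 * config.body_length
    for _ in range(config.n_reflections):
        dur = config.reflection_duration or max(1, config.n_frames // 50)
        start = int(rng.integers(0, max(1, config.n_frames - dur)))
        best = None
        best_d = -1.0
        for _try in range(60):
            x = float(rng.uniform(10, config.width - 10))
            y = float(rng.uniform(10, config.height - 10))
            if trajs is None:
                best = (x, y)
                break
            w1 = min(start + dur + 45, config.n_frames)
            d_min = min(
                float(np.min(np.linalg.norm(tr.centers[start:w1] - [x, y], axis=1)))
                for tr in trajs
            )
            if d_min > best_d:
                best_d, best = d_min, (x, y)
            if d_min >= clearance:
                break
        out.append((start, dur, best[0], best[1], 2.5))
    return out


def _paint_ellipse(img: np.ndarray, cx: float, cy: float, a: float, b: float, theta: float, depth: float) -> None:
    """Darken an anti-aliased oriented ellipse in place."""
    H, W = img.shape
    r = int(np.ceil(max(a, b))) + 2
    x0, x1 = max(int(cx) - r, 0), min(int(cx) + r + 1, W)
    y0, y1 = max(int(cy) - r, 0), min(int(cy) + r + 1, H)
    if x0 >= x1 or y0 >= y1:
        return
    ys, xs = np.mgrid[y0:y1, x0:x1]
    dx = xs + 0.0 - cx
    dy = ys + 0.0 - cy
    ct, st = np.cos(theta), np.sin(theta)
    u = (dx * ct + dy * st) / a
    v = (-dx * st + dy * ct) / b
    q = np.sqrt(u * u + v * v)
    alpha = np.clip((1.0 - q) * min(a, b) + 0.5, 0.0, 1.0)  # ~1 px soft edge
    img[y0:y1, x0:x1] -= depth * alpha


def iter_rendered_frames(trajs: list[AgentTrajectory], config: SynthConfig) -> Iterator[Frame]:
    """Lazily render frames: light background, dark agent ellipses, noise.

    Agents masked by the dropout stream are skipped for that frame (the
    ground truth still records their position). Optional reflection blobs
    are static dark disks of sub-filtration duration.
    """
    noise_rng = _streams(config)["noise"]
    drop = dropout_mask(config)
    reflections = _reflection_schedule(config, trajs)
    for f in range(config.n_frames):
        img = np.full((config.height, config.width), config.background, dtype=float)
        for k, tr in enumerate(trajs):
            if drop[f, k]:
                continue
            cx, cy = tr.centers[f]
            a, b = tr.semi_axes
            _paint_ellipse(img, cx, cy, a, b, tr.orientations[f], config.contrast)
        for start, dur, x, y, rad in reflections:
            if start <= f < start + dur:
                _paint_ellipse(img, x, y, rad, rad, 0.0, config.contrast)
        if config.noise_std > 0:
            img += noise_rng.normal(0.0, config.noise_std, size=img.shape)
        np.clip(img, 0.0, 255.0, out=img)
        yield Frame(index=f, pixels=np.round(img).astype(np.uint8))


def render_frames(trajs: list[AgentTrajectory], config: SynthConfig) -> list[Frame]:
    """Render all frames into memory (see :func:`iter_rendered_frames`)."""
    return list(iter_rendered_frames(trajs, config))


def ground_truth_tracks(trajs: list[AgentTrajectory]) -> list[GroundTruthTrack]:
    """Convert simulated agent paths to evaluation ground-truth tracks."""
    out = []
    for tr in trajs:
        g = GroundTruthTrack(agent_id=tr.agent_id)
        for f in range(tr.centers.shape[0]):
            g.points[f] = Point2D(float(tr.centers[f, 0]), float(tr.centers[f, 1]))
            g.boxes[f] = tr.box(f)
        out.append(g)
    return out


def write_dataset(trajs: list[AgentTrajectory], frames: Iterator[Frame] | list[Frame], path: str | Path, config: SynthConfig) -> Path:
    """Write a dataset directory: frames/NNNNNN.png, gt.csv, manifest.json."""
    path = Path(path)
    frame_dir = path / "frames"
    frame_dir.mkdir(parents=True, exist_ok=True)
    n_written = 0
    for frame in frames:
        iio.imwrite(frame_dir / f"{frame.index:06d}.png", frame.pixels)
        n_written += 1
    with (path / "gt.csv").open("w", encoding="utf-8") as fh:
        fh.write("frame,agent_id,x,y,x_min,y_min,x_max,y_max\n")
        for tr in trajs:
            for f in range(tr.centers.shape[0]):
                box = tr.box(f)
                cx, cy = tr.centers[f]
                fh.write(
                    f"{f},{tr.agent_id},{cx:.4f},{cy:.4f},"
                    f"{box.x_min:.4f},{box.y_min:.4f},{box.x_max:.4f},{box.y_max:.4f}\n"
                )
    manifest = {"config": dataclasses.asdict(config), "n_frames_written": n_written}
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    return path
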