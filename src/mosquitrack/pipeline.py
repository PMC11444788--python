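"""Batch orchestration: frames in, positions/plots/report out.

A video (a directory of grayscale frames, or any container imageio can
decode) runs through detection → confidence filter → NMS → tracking →
short-track filtration → gap interpolation, and the results land in
``Results/<video name>/`` next to the input: a positions table (CSV and
optionally a spreadsheet), trajectory plots before and after interpolation,
optional annotated overlay frames, and a run log echoing the effective
configuration. A whole folder of videos is processed unsupervised; one
failing video never aborts the batch, and partial results are flushed if a
run is interrupted.
"""

from __future__ import annotations

import dataclasses
import traceback
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import imageio.v3 as iio
import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import detection as det_mod
from .detection import AdaptiveBlobDetector, DetectorConfig, Frame, adjust_image_size
from .evaluation import (
    EvalReport,
    GroundTruthTrack,
    accuracy_percentage,
    detect_occlusions,
    frame_is_accurate,
    mae,
    match_trajectories_to_ground_truth,
    read_ground_truth,
    score_identity_preservation,
)
from .geometry import Detection
from .postprocess import (
    FiltrationConfig,
    PointSource,
    Trajectory,
    filter_short_tracks,
    interpolate_gaps,
    interpolation_percentage,
    trajectory_from_history,
)
from .tracking import MultiObjectTracker, TrackerConfig

__all__ = [
    "PipelineConfig",
    "process_video",
    "process_frames",
    "process_folder",
    "evaluate_run",
    "load_frames",
    "write_positions",
    "read_positions",
]

IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".bmp", ".jpg", ".jpeg"}


@dataclass(frozen=True)
class PipelineConfig:
    """The five user-facing tracking parameters plus plumbing knobs.

    image_size — maximum input dimension, snapped up to a multiple of 32;
    confidence — minimum detection score kept (default 0.05, lenient for
    small targets); nms_iou — NMS overlap threshold (default 0.05);
    max_age — frames a track survives undetected (default 30); and
    filtration_pct — minimum identity presence as a percentage of total
    frames (default 5).
    """

    image_size: int = 1040
    confidence: float = 0.05
    nms_iou: float = 0.05
    max_age: int = 30
    filtration_pct: float = 5.0
    detector: str = "blob"  # "blob" | "external"
    detections_path: str | None = None
    occlusion_iou: float = 0.25
    intensity_threshold: float = 128.0
    min_area: float = 4.0
    max_area: float = 2000.0
    split_factor: float | None = 1.6
    write_overlays: bool = False
    write_xlsx: bool = False

    @property
    def effective_image_size(self) -> int:
        return adjust_image_size(self.image_size, 32)

    def detector_config(self) -> DetectorConfig:
        return DetectorConfig(
            confidence_threshold=self.confidence,
            nms_iou=self.nms_iou,
            image_size=self.image_size,
            intensity_threshold=self.intensity_threshold,
            min_area=self.min_area,
            max_area=self.max_area,
        )

    def tracker_config(self) -> TrackerConfig:
        return TrackerConfig(max_age=self.max_age)


def load_frames(video_path: str | Path) -> Iterator[Frame]:
    """Yield grayscale frames from a frame directory or a video container."""
    video_path = Path(video_path)
    if video_path.is_dir():
        if (video_path / "frames").is_dir():  # generated dataset layout
            video_path = video_path / "frames"
        files = sorted(p for p in video_path.iterdir() if p.suffix.lower() in IMAGE_SUFFIXES)
        if not files:
            raise FileNotFoundError(f"no image frames found in {video_path}")
        for idx, p in enumerate(files):
            img = np.asarray(iio.imread(p))
            yield Frame(index=idx, pixels=_to_gray(img))
    elif video_path.is_file():
        for idx, img in enumerate(iio.imiter(video_path)):
            yield Frame(index=idx, pixels=_to_gray(np.asarray(img)))
    else:
        raise FileNotFoundError(f"{video_path} does not exist")


def _to_gray(img: np.ndarray) -> np.ndarray:
    if img.ndim == 3:
        img = img[..., :3].mean(axis=2)
    return img.astype(np.uint8) if img.dtype != np.uint8 else img


def process_frames(
    frames: Iterable[Frame],
    config: PipelineConfig = PipelineConfig(),
    external: dict[int, list[Detection]] | None = None,
) -> tuple[list[Trajectory], list[Trajectory], int]:
    """Run the tracking pipeline over an in-memory frame stream.

    Returns (trajectories before interpolation but after filtration,
    trajectories after interpolation, total frame count).
    """
    detector = AdaptiveBlobDetector(config.detector_config(), config.split_factor)
    tracker = MultiObjectTracker(config.tracker_config())
    n_frames = 0
    for frame in frames:
        n_frames += 1
        if config.detector == "external":
            dets = list((external or {}).get(frame.index, []))
        else:
            dets = detector(frame)
        dets = det_mod.filter_by_confidence(dets, config.confidence)
        dets = _nms(dets, config.nms_iou)
        tracker.step(frame, dets)
    raw = [trajectory_from_history(t.id, t.history) for t in tracker.confirmed_tracks()]
    if n_frames == 0:
        return [], [], 0
    kept = filter_short_tracks(raw, n_frames, FiltrationConfig(config.filtration_pct))
    filled = [interpolate_gaps(t) for t in kept]
    return kept, filled, n_frames


def _nms(dets: list[Detection], thr: float) -> list[Detection]:
    from .geometry import non_max_suppression

    return non_max_suppression(dets, thr) if dets else []


def process_video(
    video_path: str | Path,
    config: PipelineConfig = PipelineConfig(),
    out_root: str | Path | None = None,
) -> Path:
    """Process one video end to end and write its results directory.

    Results go to ``<out_root or parent of input>/Results/<video name>/``:
    positions.csv (frame, id, x, y, interpolated), trajectory_before.png,
    trajectory_after.png, optional overlay frames and spreadsheet, and
    run.log echoing the effective configuration. If the run is interrupted,
    whatever has been processed so far is flushed before the exception
    propagates.
    """
    video_path = Path(video_path)
    name = video_path.stem if video_path.is_file() else video_path.name
    root = Path(out_root) if out_root is not None else video_path.parent
    out_dir = root / "Results" / name
    out_dir.mkdir(parents=True, exist_ok=True)

    external = None
    if config.detector == "external":
        if not config.detections_path:
            raise ValueError("external detector selected but no detections_path given")
        external = det_mod.read_external_detections(config.detections_path)

    detector = AdaptiveBlobDetector(config.detector_config(), config.split_factor)
    tracker = MultiObjectTracker(config.tracker_config())
    n_frames = 0
    overlay_dir = out_dir / "overlay"
    if config.write_overlays:
        overlay_dir.mkdir(exist_ok=True)

    try:
        for frame in load_frames(video_path):
            n_frames += 1
            if external is not None:
                dets = list(external.get(frame.index, []))
            else:
                dets = detector(frame)
            dets = det_mod.filter_by_confidence(dets, config.confidence)
            dets = _nms(dets, config.nms_iou)
            live = tracker.step(frame, dets)
            if config.write_overlays:
                _write_overlay(overlay_dir, frame, live)
    finally:
        # Flush whatever exists, even on interruption.
        raw = [trajectory_from_history(t.id, t.history) for t in tracker.confirmed_tracks()]
        if n_frames > 0:
            kept = filter_short_tracks(raw, n_frames, FiltrationConfig(config.filtration_pct))
        else:
            kept = []
        filled = [interpolate_gaps(t) for t in kept]
        write_positions(out_dir / "positions.csv", filled)
        if config.write_xlsx:
            _write_xlsx(out_dir / "positions.xlsx", filled)
        _plot_trajectories(out_dir / "trajectory_before.png", kept, "Trajectories before interpolation")
        _plot_trajectories(out_dir / "trajectory_after.png", filled, "Trajectories after interpolation")
        _write_log(out_dir / "run.log", config, n_frames, filled)

    if not filled:
        (out_dir / "run.log").open("a", encoding="utf-8").write("warning: no trajectories produced\n")
    return out_dir


def _write_overlay(overlay_dir: Path, frame: Frame, tracks) -> None:
    img = np.stack([frame.pixels] * 3, axis=-1).astype(np.uint8)
    for t in tracks:
        if frame.index not in t.history or not t.is_confirmed:
            continue
        b = t.history[frame.index]
        x0, y0 = int(max(b.x_min, 0)), int(max(b.y_min, 0))
        x1 = int(min(b.x_max, img.shape[1] - 1))
        y1 = int(min(b.y_max, img.shape[0] - 1))
        img[y0, x0 : x1 + 1] = (255, 0, 0)
        img[y1, x0 : x1 + 1] = (255, 0, 0)
        img[y0 : y1 + 1, x0] = (255, 0, 0)
        img[y0 : y1 + 1, x1] = (255, 0, 0)
    iio.imwrite(overlay_dir / f"{frame.index:06d}.png", img)


def write_positions(path: Path, trajs: list[Trajectory]) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("frame,id,x,y,interpolated\n")
        for t in sorted(trajs, key=lambda t: t.track_id):
            for f in t.frames():
                p, src = t.points[f]
                flag = 1 if src is PointSource.INTERPOLATED else 0
                fh.write(f"{f},{t.track_id},{p.x:.4f},{p.y:.4f},{flag}\n")


def read_positions(path: str | Path) -> list[Trajectory]:
    from .geometry import Point2D

    trajs: dict[int, Trajectory] = {}
    with Path(path).open("r", encoding="utf-8") as fh:
        header = fh.readline()
        if header and not header.startswith("frame"):
            raise ValueError(f"{path}: unexpected header {header!r}")
        for line in fh:
            line = line.strip()
            if not line:
                continue
            f_s, id_s, x_s, y_s, i_s = line.split(",")
            tid = int(id_s)
            t = trajs.setdefault(tid, Trajectory(track_id=tid))
            src = PointSource.INTERPOLATED if int(i_s) else PointSource.OBSERVED
            t.points[int(f_s)] = (Point2D(float(x_s), float(y_s)), src)
    return [trajs[k] for k in sorted(trajs)]


def _write_xlsx(path: Path, trajs: list[Trajectory]) -> None:
    import pandas as pd

    rows = []
    for t in sorted(trajs, key=lambda t: t.track_id):
        for f in t.frames():
            p, src = t.points[f]
            rows.append(
                {"frame": f, "id": t.track_id, "x": p.x, "y": p.y,
                 "interpolated": 1 if src is PointSource.INTERPOLATED else 0}
            )
    pd.DataFrame(rows).to_excel(path, index=False)


def _plot_trajectories(path: Path, trajs: list[Trajectory], title: str) -> None:
    try:
        fig, ax = plt.subplots(figsize=(6, 6))
        for t in trajs:
            frames = t.frames()
            xs = [t.point(f).x for f in frames]
            ys = [t.point(f).y for f in frames]
            ax.plot(xs, ys, lw=0.8, label=f"id {t.track_id}")
        ax.invert_yaxis()
        ax.set_xlabel("x (px)")
        ax.set_ylabel("y (px)")
        ax.set_title(title)
        if trajs:
            ax.legend(fontsize=7)
        fig.savefig(path, dpi=100)
        plt.close(fig)
    except Exception:  # plotting failures are non-fatal
        traceback.print_exc()


def _write_log(path: Path, config: PipelineConfig, n_frames: int, trajs: list[Trajectory]) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("effective configuration:\n")
        for k, v in dataclasses.asdict(config).items():
            fh.write(f"  {k} = {v}\n")
        fh.write(f"  image_size_adjusted = {config.effective_image_size}\n")
        fh.write(f"frames processed: {n_frames}\n")
        fh.write(f"trajectories: {len(trajs)}\n")
        for t in trajs:
            interp = len(t.interpolated_frames())
            pct = interpolation_percentage(t, n_frames) if n_frames else 0.0
            fh.write(f"  id {t.track_id}: {len(t.observed_frames())} observed, {interp} interpolated ({pct:.2f}%)\n")


def process_folder(folder: str | Path, config: PipelineConfig = PipelineConfig()) -> list[dict]:
    """Process every video in a folder unsupervised; return the batch summary.

    A video is a subdirectory of frames or a video file; the generated
    Results directory itself is skipped. One failure does not abort the
    batch: the summary marks it and processing continues. The summary is
    also written to ``<folder>/Results/summary.csv``.
    """
    folder = Path(folder)
    if not folder.is_dir():
        raise FileNotFoundError(f"{folder} is not a directory")
    videos = sorted(
        p
        for p in folder.iterdir()
        if (p.is_dir() and p.name != "Results") or (p.is_file() and p.suffix.lower() not in {".csv", ".json", ".log", ".txt"})
    )
    summary: list[dict] = []
    for vid in videos:
        row: dict = {"video": vid.name, "status": "ok", "interpolation_pct": ""}
        try:
            out_dir = process_video(vid, config, out_root=folder)
            trajs = read_positions(out_dir / "positions.csv")
            n_frames = sum(1 for _ in load_frames(vid))
            interp = sum(len(t.interpolated_frames()) for t in trajs)
            row["interpolation_pct"] = round(100.0 * interp / n_frames, 2) if n_frames else 0.0
        except Exception as exc:
            row["status"] = f"failed: {exc}"
        summary.append(row)
    if not summary:
        import warnings

        warnings.warn(f"no videos found in {folder}")
    results_dir = folder / "Results"
    results_dir.mkdir(exist_ok=True)
    with (results_dir / "summary.csv").open("w", encoding="utf-8") as fh:
        fh.write("video,status,interpolation_pct\n")
        for row in summary:
            status = str(row["status"]).replace(",", ";")
            fh.write(f"{row['video']},{status},{row['interpolation_pct']}\n")
    return summary


def evaluate_run(
    results_dir: str | Path,
    gt_path: str | Path,
    tolerance: float = 6.0,
    occlusion_iou: float = 0.25,
) -> EvalReport:
    """Score a results directory against a ground-truth table.

    Estimated trajectories are matched one-to-one to ground-truth agents by
    minimal mean centroid distance; MAE and tolerance accuracy are computed
    over the frames shared by each matched pair and pooled across pairs.
    When the ground truth carries boxes, occlusion events are extracted
    from them and identity preservation through each event is scored.
    """
    results_dir = Path(results_dir)
    est = read_positions(results_dir / "positions.csv")
    gts = read_ground_truth(gt_path)
    gt_by_id = {g.agent_id: g for g in gts}
    mapping = match_trajectories_to_ground_truth(est, gts)

    total_frames = 0
    total_err = 0.0
    n_bad = 0
    for t in est:
        if t.track_id not in mapping:
            continue
        g = gt_by_id[mapping[t.track_id]]
        shared = sorted(set(t.points) & set(g.points))
        sub_t = Trajectory(track_id=t.track_id, points={f: t.points[f] for f in shared})
        sub_g = GroundTruthTrack(agent_id=g.agent_id, points={f: g.points[f] for f in shared})
        if not shared:
            continue
        total_err += mae(sub_t, sub_g) * len(shared)
        n_bad += sum(
            1 for f in shared if not frame_is_accurate(sub_t.point(f), sub_g.points[f], tolerance)
        )
        total_frames += len(shared)

    if total_frames == 0:
        raise ValueError("no overlapping frames between estimates and ground truth")

    boxes_by_id = {g.agent_id: g.boxes for g in gts if g.boxes}
    events = detect_occlusions(boxes_by_id, occlusion_iou) if boxes_by_id else []
    correct, total = score_identity_preservation(events, est, gts)

    return EvalReport(
        n_frames=total_frames,
        mae=total_err / total_frames,
        accuracy_pct=100.0 * (total_frames - n_bad) / total_frames,
        n_inaccurate=n_bad,
        tolerance=tolerance,
        occlusions_total=total,
        occlusions_correct=correct,
    )
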