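"""Two-phase orchestration: detect everything first, then track.

Detection (background model -> LoG blob filter -> posture) runs over all
frames and persists a per-frame detections table; tracking then folds the
Kalman/Hungarian/heading-gate step over that table alone, never touching
pixels.  Persisting the intermediate lets the tracking phase re-run with
different parameters without re-detecting.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

from . import background as bg
from . import detect as det
from . import posture as pm
from .synth import FrameStack, GroundTruth
from .tracking import TrackConfig, TrackerState, track_step

__all__ = [
    "DetectConfig",
    "RunConfig",
    "frame_interval",
    "detect_all",
    "track_all",
    "evaluate",
    "render_overlay",
]

DETECTION_COLUMNS = [
    "frame",
    "blob_id",
    "x",
    "y",
    "area",
    "a",
    "b",
    "theta",
    "heading_dx",
    "heading_dy",
    "heading_valid",
]

TRAJECTORY_COLUMNS = ["frame", "id", "x", "y", "vx", "vy", "heading_angle", "matched"]


@dataclass(frozen=True)
class DetectConfig:
    sigma: float = 6.0
    threshold: float = 1.0  # LoG-response units; preview with threshold_preview()
    min_area_frac: float = 0.2
    split_step_frac: float = 0.02
    split_max_iter: int = 60
    n_background_samples: int = 100
    background_seed: int = 0
    adjust_intensity: bool = True


@dataclass(frozen=True)
class RunConfig:
    input_path: str = ""
    output_dir: str = "."
    frame_start: int = 0
    frame_end: int | None = None  # inclusive; None = last
    fps: float = 20.0
    seed: int = 0
    detect: DetectConfig = field(default_factory=DetectConfig)
    track: TrackConfig = field(default_factory=TrackConfig)

    def __post_init__(self) -> None:
        if self.frame_end is not None and self.frame_start > self.frame_end:
            raise ValueError("frame_start must be <= frame_end")


def frame_interval(fps: float) -> float:
    """Inter-frame interval in seconds, reported to 4 decimals (e.g. 19 fps
    -> 0.0526 s)."""
    if fps <= 0:
        raise ValueError("fps must be positive")
    return round(1.0 / fps, 4)


def _expected_area(spec_sigma: float) -> float:
    # rough single-fly area prior from the LoG scale; refined per frame
    return np.pi * (spec_sigma * np.sqrt(2.0)) ** 2


def detect_frame(
    frame: np.ndarray,
    plate: bg.BackgroundPlate,
    kernel: det.LoGKernel,
    cfg: DetectConfig,
) -> list[dict]:
    """Run the full detection chain on one frame; returns record dicts."""
    adjusted = bg.adjust_intensity(frame, plate) if cfg.adjust_intensity else np.asarray(
        frame, dtype=float
    )
    fg = bg.subtract_background(adjusted, plate)
    resp = det.blob_filter(fg, kernel)
    kept = det.threshold_blobs(resp, cfg.threshold)
    blobs = det.label_blobs(kept, min_area=4)
    if blobs:
        expected = float(np.mean([b.area for b in blobs]))
        blobs = [b for b in blobs if b.area >= cfg.min_area_frac * expected]
    if blobs:
        blobs = det.split_merged(
            blobs,
            det.SplitConfig(
                base_threshold=cfg.threshold,
                step_frac=cfg.split_step_frac,
                max_iter=cfg.split_max_iter,
                min_area_frac=cfg.min_area_frac,
            ),
        )
    records = []
    for i, b in enumerate(blobs):
        fit = pm.ellipse_fit(pm.second_moments(b), pm.centroid(b))
        hd = pm.heading_direction(b, fit, adjusted)
        records.append(
            {
                "blob_id": i,
                "x": fit.centroid[0],
                "y": fit.centroid[1],
                "area": b.area,
                "a": fit.major,
                "b": fit.minor,
                "theta": fit.theta,
                "heading_dx": float(hd.direction[0]) if hd.valid else 0.0,
                "heading_dy": float(hd.direction[1]) if hd.valid else 0.0,
                "heading_valid": int(hd.valid),
            }
        )
    return records


def detect_all(
    frames: FrameStack,
    cfg: RunConfig,
    out_csv: str | Path | None = None,
) -> pd.DataFrame:
    """Phase 1: detect every frame in range; optionally persist CSV + manifest."""
    end = len(frames) - 1 if cfg.frame_end is None else min(cfg.frame_end, len(frames) - 1)
    plate = bg.extract_background(
        frames.frames[cfg.frame_start : end + 1],
        n_samples=cfg.detect.n_background_samples,
        seed=cfg.detect.background_seed,
    )
    kernel = det.log_kernel(cfg.detect.sigma)
    rows = []
    for f in range(cfg.frame_start, end + 1):
        for rec in detect_frame(frames[f], plate, kernel, cfg.detect):
            rows.append({"frame": f, **rec})
    df = pd.DataFrame(rows, columns=DETECTION_COLUMNS)
    if out_csv is not None:
        out_csv = Path(out_csv)
        out_csv.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(out_csv, index=False, float_format="%.6f")
        _write_manifest(out_csv.with_suffix(".manifest.json"), cfg)
    return df


def _write_manifest(path: Path, cfg: RunConfig) -> None:
    payload = asdict(cfg)
    digest = hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()
    payload["config_sha256"] = digest
    path.write_text(json.dumps(payload, indent=2, default=str) + "\n")


def track_all(
    detections: pd.DataFrame,
    cfg: RunConfig,
    out_csv: str | Path | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Phase 2: fold the tracking step over the detections table.

    Returns the trajectory table (one row per live tracker per frame) and
    a run summary.  Never reads pixel data.
    """
    if detections.empty:
        return pd.DataFrame(columns=TRAJECTORY_COLUMNS), {"n_identities": 0}
    f0, f1 = int(detections["frame"].min()), int(detections["frame"].max())
    trackers: list[TrackerState] = []
    next_id = 1
    rows = []
    by_frame = dict(tuple(detections.groupby("frame")))
    for f in range(f0, f1 + 1):
        sub = by_frame.get(f)
        dets: list[tuple[np.ndarray, np.ndarray | None]] = []
        if sub is not None:
            for _, r in sub.iterrows():
                head = (
                    np.array([r["heading_dx"], r["heading_dy"]])
                    if r["heading_valid"]
                    else None
                )
                dets.append((np.array([r["x"], r["y"]]), head))
        trackers = track_step(trackers, dets, cfg.track, next_id=next_id)
        next_id = max((t.id for t in trackers), default=next_id - 1) + 1
        for t in sorted(trackers, key=lambda t: t.id):
            ang = (
                float(np.arctan2(t.heading[1], t.heading[0]))
                if t.heading is not None
                else np.nan
            )
            rows.append(
                {
                    "frame": f,
                    "id": t.id,
                    "x": t.state[0],
                    "y": t.state[1],
                    "vx": t.state[2],
                    "vy": t.state[3],
                    "heading_angle": ang,
                    "matched": int(t.matched),
                }
            )
    traj = pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS).sort_values(
        ["frame", "id"], kind="stable"
    ).reset_index(drop=True)
    summary = {
        "n_identities": int(traj["id"].nunique()),
        "n_frames": int(f1 - f0 + 1),
        "matched_fraction": float(traj["matched"].mean()),
    }
    if out_csv is not None:
        out_csv = Path(out_csv)
        out_csv.parent.mkdir(parents=True, exist_ok=True)
        traj.to_csv(out_csv, index=False, float_format="%.6f")
    return traj, summary


def evaluate(
    trajectories: pd.DataFrame,
    truth: GroundTruth,
    match_radius: float,
) -> dict:
    """Score a trajectory table against ground truth.

    A track row is associated with the nearest true fly within
    ``match_radius``, but only when the association is unambiguous (the
    second-nearest fly is outside the radius): frames where two flies are
    both within reach of one track — the interior of a crossing — carry no
    association, so only identity exchanges that persist past the contact
    are counted.  ``swaps`` counts events where a track id's associated
    fly changes between two valid flies; ``losses`` counts events where a
    true fly's covering id changes to a newly born id;
    ``false_positives`` counts track ids never associated with any fly.
    """
    frames = sorted(trajectories["frame"].unique())
    id_assoc: dict[int, list[int | None]] = {}
    fly_assoc: dict[int, list[int | None]] = {}
    birth_frame: dict[int, int] = {}
    for f in frames:
        sub = trajectories[trajectories["frame"] == f]
        tp = truth.positions(int(f))
        for _, r in sub.iterrows():
            tid = int(r["id"])
            birth_frame.setdefault(tid, int(f))
            if tp.shape[0]:
                d = np.hypot(tp[:, 0] - r["x"], tp[:, 1] - r["y"])
                order = np.argsort(d)
                fly = None
                if float(d[order[0]]) <= match_radius and (
                    len(d) < 2 or float(d[order[1]]) > match_radius
                ):
                    fly = int(order[0])
            else:
                fly = None
            id_assoc.setdefault(tid, []).append(fly)
        if tp.shape[0] and len(sub):
            txy = sub[["x", "y"]].to_numpy()
            ids = sub["id"].to_numpy().astype(int)
            for fly in range(tp.shape[0]):
                d = np.hypot(txy[:, 0] - tp[fly, 0], txy[:, 1] - tp[fly, 1])
                order = np.argsort(d)
                cover = None
                if float(d[order[0]]) <= match_radius and (
                    len(d) < 2 or float(d[order[1]]) > match_radius
                ):
                    cover = int(ids[order[0]])
                fly_assoc.setdefault(fly, []).append(cover)

    swaps = 0
    for tid, seq in id_assoc.items():
        seen = [s for s in seq if s is not None]
        swaps += sum(1 for a_, b_ in zip(seen, seen[1:]) if a_ != b_)
    losses = 0
    first = min(frames) if frames else 0
    for fly, seq in fly_assoc.items():
        seen = [s for s in seq if s is not None]
        for a_, b_ in zip(seen, seen[1:]):
            if a_ != b_ and birth_frame.get(b_, first) > first:
                losses += 1
    fp = sum(
        1 for tid, seq in id_assoc.items() if all(s is None for s in seq)
    )
    return {"swaps": int(swaps), "losses": int(losses), "false_positives": int(fp)}


_COLORS = [
    (230, 60, 60), (60, 160, 230), (70, 200, 110), (235, 180, 50),
    (180, 100, 230), (240, 130, 40), (90, 220, 220), (240, 110, 170),
]


def render_overlay(
    frames: FrameStack,
    trajectories: pd.DataFrame,
    out_dir: str | Path,
    trail: int = 6,
    arrow_len: float = 14.0,
) -> list[Path]:
    """Annotate frames with id labels, heading arrows and 6-frame trails."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    by_id = dict(tuple(trajectories.groupby("id"))) if len(trajectories) else {}
    paths = []
    for f in range(len(frames)):
        img = Image.fromarray(frames[f]).convert("RGB")
        draw = ImageDraw.Draw(img)
        for tid, sub in by_id.items():
            past = sub[(sub["frame"] <= f) & (sub["frame"] >= f - trail)]
            if past.empty or past["frame"].max() != f:
                continue
            color = _COLORS[int(tid) % len(_COLORS)]
            pts = list(zip(past["x"], past["y"]))
            if len(pts) > 1:
                draw.line(pts, fill=color, width=1)
            row = past.iloc[-1]
            x, y = float(row["x"]), float(row["y"])
            ang = row["heading_angle"]
            if np.isfinite(ang):
                draw.line(
                    [
                        (x, y),
                        (x + arrow_len * np.cos(ang), y + arrow_len * np.sin(ang)),
                    ],
                    fill=(255, 0, 0),
                    width=1,
                )
            draw.text((x + 3, y + 3), str(int(tid)), fill=color)
        p = out / f"overlay_{f:06d}.png"
        img.save(p)
        paths.append(p)
    return paths
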