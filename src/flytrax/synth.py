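"""Synthetic arena scenes with ground truth.

Renders grayscale videos of dark elliptical fly bodies (with
intermediate-intensity wing patches trailing the head) walking inside a
bright circular arena, together with per-frame ground-truth positions,
heading angles and motion-event tags.  Every stochastic element is driven
by a single seed, so a given :class:`SceneSpec` always renders the same
byte-identical frame stack.

Conventions
-----------
Coordinates are ``(x, y)`` pixel centers, 0-based, x rightward, y downward
(image convention).  Heading angles are radians, measured from the +x axis,
counter-clockwise positive *in that y-down frame* (so a heading of +pi/2
points down the image).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "SceneSpec",
    "GroundTruth",
    "FrameStack",
    "background_plate",
    "render_fly",
    "simulate_motion",
    "render_video",
    "render_snapshot",
    "write_frames",
    "read_frames",
]


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a synthetic arena scene.

    Intensity ordering ``body_level < wing_level < background_level`` is
    required: wings are rendered at an intermediate intensity between the
    fly's body and the arena floor, which is what the wing-scoring heading
    detector exploits.
    """

    image_size: tuple[int, int] = (256, 256)  # (H, W)
    arena_center: tuple[float, float] = (128.0, 128.0)  # (x, y)
    arena_radius: float = 112.0
    background_level: float = 200.0
    body_level: float = 40.0
    wing_level: float = 120.0
    n_flies: int = 1
    body_axes: tuple[float, float] = (12.0, 6.0)  # (semi-major, semi-minor) px
    fps: float = 20.0
    n_frames: int = 1
    illumination_drift: float = 0.0  # intensity offset per frame
    noise_sd: float = 0.0
    rng_seed: int = 0
    # motion model ------------------------------------------------------
    walk_step: float = 2.0        # mean per-frame displacement, px/frame
    turn_sd: float = 0.35         # heading increment SD, rad/frame
    jump_prob: float = 0.0        # per-fly per-frame jump probability
    # scripted near-contact events: (frame, fly_i, fly_j)
    crossings: tuple[tuple[int, int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (self.body_level < self.wing_level < self.background_level):
            raise ValueError(
                "intensity ordering body_level < wing_level < background_level required"
            )
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")

    @property
    def body_length(self) -> float:
        return 2.0 * self.body_axes[0]


@dataclass
class GroundTruth:
    """Per-(frame, fly) true state: position, heading angle, event tag."""

    table: pd.DataFrame  # columns: frame, fly, x, y, heading, event

    def positions(self, frame: int) -> np.ndarray:
        sub = self.table[self.table["frame"] == frame].sort_values("fly")
        return sub[["x", "y"]].to_numpy(dtype=float)

    def headings(self, frame: int) -> np.ndarray:
        sub = self.table[self.table["frame"] == frame].sort_values("fly")
        return sub["heading"].to_numpy(dtype=float)

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "GroundTruth":
        return cls(pd.read_csv(path))


@dataclass
class FrameStack:
    """An ordered stack of 8-bit grayscale frames plus the frame rate."""

    frames: np.ndarray  # (n_frames, H, W) uint8
    fps: float

    def __len__(self) -> int:
        return self.frames.shape[0]

    def __getitem__(self, i: int) -> np.ndarray:
        return self.frames[i]


def background_plate(spec: SceneSpec) -> np.ndarray:
    """Fly-free arena image: bright floor disc on a darker surround."""
    h, w = spec.image_size
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = spec.arena_center
    inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= spec.arena_radius**2
    plate = np.full((h, w), 0.5 * spec.background_level)
    plate[inside] = spec.background_level
    return plate


def _ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    semi_axes: tuple[float, float],
    angle: float,
) -> np.ndarray:
    h, w = shape
    cx, cy = center
    a, b = semi_axes
    y0 = max(int(np.floor(cy - a - 2)), 0)
    y1 = min(int(np.ceil(cy + a + 3)), h)
    x0 = max(int(np.floor(cx - a - 2)), 0)
    x1 = min(int(np.ceil(cx + a + 3)), w)
    mask = np.zeros(shape, dtype=bool)
    if y0 >= y1 or x0 >= x1:
        return mask
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx = xx - cx
    dy = yy - cy
    c, s = np.cos(angle), np.sin(angle)
    u = dx * c + dy * s
    v = -dx * s + dy * c
    mask[y0:y1, x0:x1] = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return mask


def render_fly(
    canvas: np.ndarray,
    center: tuple[float, float],
    heading: float,
    spec: SceneSpec,
) -> np.ndarray:
    """Draw one fly onto ``canvas`` (modified in place and returned).

    The body is a filled ellipse at ``body_level`` whose major axis points
    along ``heading``; the wings are a single elongated patch at
    ``wing_level`` centered behind the centroid (anti-heading side), so the
    darkest pixels mark the body and intermediate pixels trail the tail.
    Compositing is ``min`` (darkest wins), so overlapping flies merge into
    one dark region.
    """
    cx, cy = center
    h, w = canvas.shape
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValueError(f"fly center {center} outside canvas {canvas.shape}")
    a, b = spec.body_axes
    body = _ellipse_mask(canvas.shape, (cx, cy), (a, b), heading)
    # wing patch: trailing ellipse centered 0.9*a behind the centroid
    wx = cx - 0.9 * a * np.cos(heading)
    wy = cy - 0.9 * a * np.sin(heading)
    wings = _ellipse_mask(canvas.shape, (wx, wy), (1.0 * a, 1.1 * b), heading)
    np.minimum(canvas, np.where(wings, spec.wing_level, np.inf), out=canvas)
    np.minimum(canvas, np.where(body, spec.body_level, np.inf), out=canvas)
    return canvas


def _reflect_into_arena(
    pos: np.ndarray, spec: SceneSpec, margin: float
) -> np.ndarray:
    """Reflect a position across the arena wall if it escaped."""
    cx, cy = spec.arena_center
    r_max = spec.arena_radius - margin
    d = pos - np.array([cx, cy])
    r = float(np.hypot(*d))
    if r > r_max and r > 0:
        pos = np.array([cx, cy]) + d * ((2 * r_max - r) / r)
        # may still be outside for extreme jumps; clamp radially
        d2 = pos - np.array([cx, cy])
        r2 = float(np.hypot(*d2))
        if r2 > r_max:
            pos = np.array([cx, cy]) + d2 * (r_max / r2)
    return pos


def simulate_motion(spec: SceneSpec) -> GroundTruth:
    """Correlated-random-walk trajectories with jumps and scripted crossings.

    Each fly performs a correlated random walk: the heading angle receives
    Gaussian increments (``turn_sd``) and the per-frame step length is
    uniform in ``[0.5, 1.5] * walk_step``.  With probability ``jump_prob``
    per frame a fly jumps: a displacement of 5-15 walk steps in a uniform
    random direction, after which the heading follows the jump.  The arena
    wall reflects.  Unscripted flies avoid one another (a step that would
    bring two flies within 1.5 body lengths is re-drawn or skipped), so
    near-contact happens only where a crossing is scripted: those steer a
    fly pair onto straight tracks that pass within 0.8 body lengths at the
    scripted frame.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n, t = spec.n_flies, spec.n_frames
    margin = spec.body_axes[0] + 2.0
    cx, cy = spec.arena_center

    # initial placement: rejection-sample for >= 2 body-length separation
    pos = np.zeros((n, 2))
    placed = 0
    while placed < n:
        rr = (spec.arena_radius - margin) * np.sqrt(rng.uniform())
        th = rng.uniform(0, 2 * np.pi)
        cand = np.array([cx + rr * np.cos(th), cy + rr * np.sin(th)])
        if placed == 0 or np.min(
            np.linalg.norm(pos[:placed] - cand, axis=1)
        ) > 2 * spec.body_length:
            pos[placed] = cand
            placed += 1
    ang = rng.uniform(0, 2 * np.pi, size=n)

    # precompute scripted-crossing schedules: fly -> {frame: (x, y)}
    approach = 20  # frames spent converging / departing
    scripted: dict[int, dict[int, np.ndarray]] = {}
    partner: dict[int, int] = {}
    cross_tag: dict[tuple[int, int], bool] = {}
    xyz = np.zeros((t, n, 2))
    event = np.full((t, n), "walk", dtype=object)

    cross_plan = []
    for k, i, j in spec.crossings:
        if not (approach <= k < t):
            raise ValueError(f"crossing frame {k} out of range for approach {approach}")
        cross_plan.append((int(k), int(i), int(j)))

    def plan_crossing(k: int, i: int, j: int, pos_now: np.ndarray) -> None:
        a_pt, b_pt = pos_now[i].copy(), pos_now[j].copy()
        m = 0.5 * (a_pt + b_pt)
        m = _reflect_into_arena(m, spec, margin + spec.body_length)
        u = b_pt - a_pt
        nu = np.linalg.norm(u)
        u = u / nu if nu > 0 else np.array([1.0, 0.0])
        perp = np.array([-u[1], u[0]])
        off = 0.4 * spec.body_length
        mi, mj = m + off * perp, m - off * perp
        vi = (mi - a_pt) / approach
        vj = (mj - b_pt) / approach
        partner[i], partner[j] = j, i
        for f in range(k - approach + 1, min(k + approach, t)):
            di = f - (k - approach)
            scripted.setdefault(i, {})[f] = a_pt + vi * di
            scripted.setdefault(j, {})[f] = b_pt + vj * di
            if abs(f - k) <= 2:
                cross_tag[(f, i)] = True
                cross_tag[(f, j)] = True

    min_sep = 1.5 * spec.body_length

    def clear_of_others(
        p: np.ndarray, fl: int, f: int, skip: int = -1, sep: float | None = None
    ) -> bool:
        sep = min_sep if sep is None else sep
        for other in range(n):
            if other == fl or other == skip:
                continue
            ref = xyz[f, other] if other < fl else xyz[f - 1, other]
            if np.linalg.norm(p - ref) < sep:
                return False
        return True

    xyz[0] = pos
    for f in range(1, t):
        for k, i, j in cross_plan:
            if f == k - approach + 1:
                plan_crossing(k, i, j, xyz[f - 1])
        for fl in range(n):
            if fl in scripted and f in scripted[fl]:
                new = _reflect_into_arena(scripted[fl][f], spec, margin)
                # the scripted pair may approach each other but must not
                # plow through a third fly; if an actual merge with a
                # bystander is imminent the script ends early and the fly
                # resumes its avoiding walk
                if clear_of_others(
                    new, fl, f, skip=partner.get(fl, -1), sep=spec.body_length
                ):
                    step = new - xyz[f - 1, fl]
                    if np.linalg.norm(step) > 1e-9:
                        ang[fl] = float(np.arctan2(step[1], step[0]))
                    xyz[f, fl] = new
                    if cross_tag.get((f, fl)):
                        event[f, fl] = "crossing"
                    continue
                scripted[fl] = {}  # abandon remaining schedule
            scripted_now = any(
                fl in (i, j) and abs(f - k) <= approach for k, i, j in cross_plan
            )
            placed_ok = False
            for attempt in range(8):
                if spec.jump_prob > 0 and attempt == 0 and rng.uniform() < spec.jump_prob:
                    jdir = rng.uniform(0, 2 * np.pi)
                    jmag = rng.uniform(5.0, 15.0) * spec.walk_step
                    new = xyz[f - 1, fl] + jmag * np.array(
                        [np.cos(jdir), np.sin(jdir)]
                    )
                    cand_ang = jdir
                    tag = "jump"
                else:
                    cand_ang = ang[fl] + rng.normal(0.0, spec.turn_sd * (1 + attempt))
                    step = spec.walk_step * rng.uniform(0.5, 1.5)
                    new = xyz[f - 1, fl] + step * np.array(
                        [np.cos(cand_ang), np.sin(cand_ang)]
                    )
                    tag = "walk"
                reflected = _reflect_into_arena(new, spec, margin)
                skip = partner.get(fl, -1) if scripted_now else -1
                if clear_of_others(reflected, fl, f, skip=skip):
                    if not np.allclose(reflected, new):
                        d = reflected - xyz[f - 1, fl]
                        if np.linalg.norm(d) > 1e-9:
                            cand_ang = float(np.arctan2(d[1], d[0]))
                    ang[fl] = cand_ang
                    event[f, fl] = tag
                    xyz[f, fl] = reflected
                    placed_ok = True
                    break
            if not placed_ok:
                # crowded: step directly away from the nearest neighbor so
                # close pairs disperse instead of freezing in place
                others = np.array(
                    [xyz[f, o] if o < fl else xyz[f - 1, o] for o in range(n) if o != fl]
                )
                if len(others):
                    d = others - xyz[f - 1, fl]
                    nearest = d[np.argmin(np.hypot(d[:, 0], d[:, 1]))]
                    nrm = float(np.hypot(*nearest))
                    away = (
                        -nearest / nrm
                        if nrm > 1e-9
                        else np.array([np.cos(ang[fl]), np.sin(ang[fl])])
                    )
                    new = xyz[f - 1, fl] + spec.walk_step * away
                    xyz[f, fl] = _reflect_into_arena(new, spec, margin)
                    ang[fl] = float(np.arctan2(away[1], away[0]))
                else:
                    xyz[f, fl] = xyz[f - 1, fl]

    rows = []
    headings = np.zeros((t, n))
    # heading of record = angle used to take the step into this frame
    headings[0] = ang  # frame 0 has no step; use final-consistent init below
    # recompute headings deterministically: direction of arrival, falling
    # back to the next departure for frame 0
    for fl in range(n):
        for f in range(t):
            if f == 0:
                d = xyz[1, fl] - xyz[0, fl] if t > 1 else np.array([1.0, 0.0])
            else:
                d = xyz[f, fl] - xyz[f - 1, fl]
            if np.linalg.norm(d) > 1e-9:
                headings[f, fl] = float(np.arctan2(d[1], d[0]))
            elif f > 0:
                headings[f, fl] = headings[f - 1, fl]
    for f in range(t):
        for fl in range(n):
            rows.append(
                (f, fl, xyz[f, fl, 0], xyz[f, fl, 1], headings[f, fl], event[f, fl])
            )
    table = pd.DataFrame(rows, columns=["frame", "fly", "x", "y", "heading", "event"])
    return GroundTruth(table)


def render_video(spec: SceneSpec, truth: GroundTruth) -> FrameStack:
    """Render every frame: plate + drift + flies + Gaussian noise, uint8."""
    plate = background_plate(spec)
    noise_rng = np.random.default_rng(np.random.SeedSequence([spec.rng_seed, 0xF17]))
    frames = np.empty((spec.n_frames, *spec.image_size), dtype=np.uint8)
    for f in range(spec.n_frames):
        canvas = plate.copy()
        sub = truth.table[truth.table["frame"] == f]
        for _, row in sub.iterrows():
            render_fly(canvas, (row["x"], row["y"]), row["heading"], spec)
        canvas = canvas + spec.illumination_drift * f
        if spec.noise_sd > 0:
            canvas = canvas + noise_rng.normal(0.0, spec.noise_sd, canvas.shape)
        frames[f] = np.clip(np.round(canvas), 0, 255).astype(np.uint8)
    return FrameStack(frames=frames, fps=spec.fps)


def render_snapshot(
    spec: SceneSpec,
    centers: list[tuple[float, float]],
    headings: list[float],
    noise_seed: int = 0,
) -> np.ndarray:
    """Render one quantized frame with flies at explicit poses."""
    canvas = background_plate(spec)
    for c, h in zip(centers, headings):
        render_fly(canvas, c, h, spec)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(noise_seed)
        canvas = canvas + rng.normal(0.0, spec.noise_sd, canvas.shape)
    return np.clip(np.round(canvas), 0, 255).astype(np.uint8)


def write_frames(stack: FrameStack, out_dir: str | Path) -> list[Path]:
    """Write the stack as numbered 8-bit grayscale PNGs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i in range(len(stack)):
        p = out / f"frame_{i:06d}.png"
        iio.imwrite(p, stack[i])
        paths.append(p)
    return paths


def read_frames(in_dir: str | Path, fps: float = 20.0) -> FrameStack:
    """Read a directory of numbered grayscale PNG/TIFF frames."""
    files = sorted(
        p for p in Path(in_dir).iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")
    )
    if not files:
        raise FileNotFoundError(f"no PNG/TIFF frames in {in_dir}")
    frames = np.stack([np.asarray(iio.imread(p)) for p in files])
    if frames.ndim == 4:  # RGB(A) -> gray
        frames = frames[..., :3].mean(axis=-1).round().astype(np.uint8)
    return FrameStack(frames=frames.astype(np.uint8), fps=fps)
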