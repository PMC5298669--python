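"""Posture modeling: centroid, best-fit ellipse, signed heading direction.

The body orientation comes from the normalized second central moments of
the blob's pixel set (with the +1/12 single-pixel correction on the
diagonal terms), giving the classic region-ellipse axes

    Delta = sqrt((uxx - uyy)^2 + 4 uxy^2)
    a     = 2 sqrt(2) sqrt(uxx + uyy + Delta)   (major axis length)
    b     = 2 sqrt(2) sqrt(uxx + uyy - Delta)   (minor axis length)

and the orientation theta from the principal-axis arctangent.  The
orientation is unsigned; the *heading* (which of the two major-axis ends
is the head) is resolved by wing evidence: wings have an intermediate
intensity between the dark body and the bright background and always trail
the head, so band-pass "wing pixels" accumulate around the tail-end search
point.  Two search discs at the major-axis ends are scored over a sweep of
(floor, ceiling) threshold couples; a couple whose marked pixels are mostly
outside both discs ("environment pixels") is noise and contributes nothing.
The head is the end with the *lower* wing score.

Angles are radians in the image frame (x right, y down, counter-clockwise
positive in that frame); theta lies in (-pi/2, pi/2].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detect import Blob

__all__ = [
    "EllipseFit",
    "HeadingResult",
    "WingSearchConfig",
    "centroid",
    "second_moments",
    "ellipse_fit",
    "heading_direction",
]

PIXEL_MOMENT = 1.0 / 12.0  # normalized second central moment of a unit pixel


@dataclass(frozen=True)
class EllipseFit:
    centroid: tuple[float, float]
    uxx: float
    uyy: float
    uxy: float
    delta: float
    major: float  # a, full major-axis length in px
    minor: float  # b
    theta: float  # radians in (-pi/2, pi/2]


@dataclass
class HeadingResult:
    direction: np.ndarray | None  # unit vector centroid -> head, or None
    head_point: tuple[float, float]
    tail_point: tuple[float, float]
    score_head_end: int
    score_tail_end: int
    valid: bool


@dataclass(frozen=True)
class WingSearchConfig:
    """Wing-scoring parameters.

    ``threshold_couples`` (floor, ceiling) bands may be given explicitly;
    by default ``n_couples`` windows are spread evenly over the intensity
    band strictly between the body's 90th-percentile value and the local
    background level.  A winning search point must collect more than
    ``min_score`` marked pixels; a couple is discarded when marked pixels
    outside both search discs exceed ``env_reject_ratio`` of the total.
    """

    threshold_couples: tuple[tuple[float, float], ...] | None = None
    n_couples: int = 6
    couple_width: float = 10.0
    search_radius: float | None = None  # default: 0.35 * major axis
    min_score: int = 3
    env_reject_ratio: float = 0.5

    def __post_init__(self) -> None:
        if self.threshold_couples is not None:
            for lo, hi in self.threshold_couples:
                if not lo < hi:
                    raise ValueError("each couple needs floor < ceiling")
        if self.search_radius is not None and self.search_radius < 1:
            raise ValueError("search_radius must be >= 1")


def centroid(blob: Blob) -> tuple[float, float]:
    """Arithmetic mean of member pixel coordinates."""
    if blob.area < 1:
        raise ValueError("empty blob")
    return (float(blob.xs.mean()), float(blob.ys.mean()))


def second_moments(blob: Blob) -> tuple[float, float, float]:
    """Normalized second central moments (uxx, uyy, uxy).

    The diagonal terms carry the +1/12 correction for the extent of a unit
    pixel; the cross term does not (a constant on the cross term would tilt
    every axis-aligned region).
    """
    if blob.area < 1:
        raise ValueError("empty blob")
    xb, yb = centroid(blob)
    dx = blob.xs - xb
    dy = blob.ys - yb
    n = blob.area
    uxx = float((dx**2).sum() / n) + PIXEL_MOMENT
    uyy = float((dy**2).sum() / n) + PIXEL_MOMENT
    uxy = float((dx * dy).sum() / n)
    return uxx, uyy, uxy


def ellipse_fit(
    moments: tuple[float, float, float], center: tuple[float, float]
) -> EllipseFit:
    """Axes and orientation of the moment-equivalent ellipse."""
    uxx, uyy, uxy = moments
    delta = float(np.sqrt((uxx - uyy) ** 2 + 4.0 * uxy**2))
    major = 2.0 * np.sqrt(2.0) * np.sqrt(max(uxx + uyy + delta, 0.0))
    minor = 2.0 * np.sqrt(2.0) * np.sqrt(max(uxx + uyy - delta, 0.0))
    if uxy == 0.0 and uxx - uyy + delta == 0.0:
        theta = 0.0
    elif uyy > uxx:
        theta = float(np.arctan2(uyy - uxx + delta, 2.0 * uxy))
    else:
        theta = float(np.arctan2(2.0 * uxy, uxx - uyy + delta))
    # fold into (-pi/2, pi/2]
    if theta <= -np.pi / 2:
        theta += np.pi
    elif theta > np.pi / 2:
        theta -= np.pi
    return EllipseFit(
        centroid=center,
        uxx=uxx,
        uyy=uyy,
        uxy=uxy,
        delta=delta,
        major=float(major),
        minor=float(minor),
        theta=theta,
    )


def _default_couples(
    blob: Blob, raw: np.ndarray, cfg: WingSearchConfig
) -> list[tuple[float, float]]:
    body_vals = raw[blob.ys, blob.xs]
    lo_band = float(np.percentile(body_vals, 90)) + 1.0
    x0, y0, w, h = blob.bbox
    m = 3
    ys0, ys1 = max(y0 - m, 0), min(y0 + h + m, raw.shape[0])
    xs0, xs1 = max(x0 - m, 0), min(x0 + w + m, raw.shape[1])
    window = raw[ys0:ys1, xs0:xs1]
    bg = float(np.percentile(window, 90))
    hi_band = bg - 1.0
    if hi_band - lo_band < 2.0:
        return []
    width = max(cfg.couple_width, (hi_band - lo_band) / cfg.n_couples)
    if cfg.n_couples == 1:
        starts = [lo_band]
    else:
        last = max(hi_band - width, lo_band)
        starts = list(np.linspace(lo_band, last, cfg.n_couples))
    return [(s, min(s + width, hi_band)) for s in starts if s < hi_band]


def heading_direction(
    blob: Blob,
    fit: EllipseFit,
    raw: np.ndarray,
    cfg: WingSearchConfig | None = None,
) -> HeadingResult:
    """Resolve which major-axis end is the head by scoring wing pixels.

    ``raw`` is the original (or drift-adjusted) grayscale frame — not the
    LoG response — because wing evidence lives in the intermediate
    intensity band that the response destroys.
    """
    cfg = cfg or WingSearchConfig()
    cx, cy = fit.centroid
    axis = np.array([np.cos(fit.theta), np.sin(fit.theta)])
    p_plus = (cx + 0.5 * fit.major * axis[0], cy + 0.5 * fit.major * axis[1])
    p_minus = (cx - 0.5 * fit.major * axis[0], cy - 0.5 * fit.major * axis[1])

    invalid = HeadingResult(
        direction=None,
        head_point=p_plus,
        tail_point=p_minus,
        score_head_end=0,
        score_tail_end=0,
        valid=False,
    )
    if fit.major <= 0 or fit.minor / max(fit.major, 1e-12) > 0.9:
        return invalid  # near-circular: axis direction unreliable

    couples = (
        list(cfg.threshold_couples)
        if cfg.threshold_couples is not None
        else _default_couples(blob, raw, cfg)
    )
    if not couples:
        return invalid

    radius = cfg.search_radius if cfg.search_radius is not None else max(
        3.0, 0.35 * fit.major
    )
    x0, y0, w, h = blob.bbox
    m = int(np.ceil(radius)) + 1
    ys0, ys1 = max(y0 - m, 0), min(y0 + h + m, raw.shape[0])
    xs0, xs1 = max(x0 - m, 0), min(x0 + w + m, raw.shape[1])
    window = np.asarray(raw, dtype=float)[ys0:ys1, xs0:xs1]
    yy, xx = np.mgrid[ys0:ys1, xs0:xs1]
    in_plus = (xx - p_plus[0]) ** 2 + (yy - p_plus[1]) ** 2 <= radius**2
    in_minus = (xx - p_minus[0]) ** 2 + (yy - p_minus[1]) ** 2 <= radius**2
    in_bbox = (xx >= x0) & (xx < x0 + w) & (yy >= y0) & (yy < y0 + h)

    score_plus = 0
    score_minus = 0
    for lo, hi in couples:
        marked = (window >= lo) & (window < hi)
        total = int(marked.sum())
        if total == 0:
            continue
        env = int((marked & in_bbox & ~in_plus & ~in_minus).sum())
        if env > cfg.env_reject_ratio * total:
            continue  # mostly environment: this band is not wing evidence
        score_plus += int((marked & in_plus).sum())
        score_minus += int((marked & in_minus).sum())

    if score_plus == score_minus:
        return HeadingResult(
            direction=None,
            head_point=p_plus,
            tail_point=p_minus,
            score_head_end=score_plus,
            score_tail_end=score_minus,
            valid=False,
        )
    wing_is_plus = score_plus > score_minus
    win = max(score_plus, score_minus)
    if win <= cfg.min_score:
        valid = False
        direction = None
    else:
        valid = True
        direction = -axis if wing_is_plus else axis
    head = p_minus if wing_is_plus else p_plus
    tail = p_plus if wing_is_plus else p_minus
    return HeadingResult(
        direction=direction,
        head_point=head,
        tail_point=tail,
        score_head_end=min(score_plus, score_minus),
        score_tail_end=win,
        valid=valid,
    )
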