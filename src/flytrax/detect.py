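"""Laplacian-of-Gaussian blob detection and merged-blob splitting.

The reversed foreground image (dark flies on a light field) is convolved
with a LoG kernel, which turns each dark body into a bright, smooth blob in
the response.  A non-binary threshold zeroes weak response while keeping
the surviving pixels' values, so each blob retains an intensity profile;
connected components are then measured, and any component whose area is a
multiple of the typical single-fly area is re-thresholded at escalating
levels until it separates into the expected number of flies (or gives up
and stays one blob).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

__all__ = [
    "LoGKernel",
    "Blob",
    "SplitConfig",
    "log_kernel",
    "blob_filter",
    "threshold_blobs",
    "label_blobs",
    "split_merged",
]

_EIGHT = np.ones((3, 3), dtype=int)  # 8-connectivity structure


@dataclass(frozen=True)
class LoGKernel:
    sigma: float
    half_width: int
    values: np.ndarray


@dataclass
class Blob:
    """A connected foreground region.

    ``xs``/``ys`` are the member pixel coordinates (x = column, y = row);
    ``bbox`` is ``(x_min, y_min, width, height)``; ``intensity_patch`` is
    the response image inside the bbox, zeroed outside the member pixels.
    """

    xs: np.ndarray
    ys: np.ndarray
    intensity_patch: np.ndarray
    bbox: tuple[int, int, int, int]
    area: int = field(init=False)
    centroid: tuple[float, float] = field(init=False)

    def __post_init__(self) -> None:
        if self.xs.size == 0:
            raise ValueError("blob must contain at least one pixel")
        self.area = int(self.xs.size)
        self.centroid = (float(self.xs.mean()), float(self.ys.mean()))

    @property
    def pixels(self) -> np.ndarray:
        """(N, 2) array of (x, y) member coordinates."""
        return np.column_stack([self.xs, self.ys])


@dataclass(frozen=True)
class SplitConfig:
    """Threshold-escalation parameters for splitting merged blobs.

    ``step`` is an absolute response increment per iteration; if None it is
    derived per blob as ``step_frac`` of the blob's intensity span above
    the base threshold, so ``max_iter`` iterations sweep the whole span.
    """

    base_threshold: float
    step: float | None = None
    step_frac: float = 0.02
    max_iter: int = 60
    min_area_frac: float = 0.2

    def __post_init__(self) -> None:
        if self.step is not None and self.step <= 0:
            raise ValueError("step must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


def log_kernel(sigma: float, half_width: int | None = None) -> LoGKernel:
    """Laplacian-of-Gaussian kernel on the integer grid.

    ``LoG(x, y) = -(1 / (pi sigma^4)) (1 - r^2 / (2 sigma^2)) exp(-r^2 / (2 sigma^2))``

    Negative at the origin with a positive annulus crossing zero at
    ``r = sigma * sqrt(2)``; convolving with a dark spot of comparable
    radius on a bright field yields a positive peak at the spot center.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if half_width is None:
        half_width = int(np.ceil(3 * sigma))
    g = np.arange(-half_width, half_width + 1)
    xx, yy = np.meshgrid(g, g)
    r2 = xx**2 + yy**2
    values = (
        -1.0
        / (np.pi * sigma**4)
        * (1.0 - r2 / (2.0 * sigma**2))
        * np.exp(-r2 / (2.0 * sigma**2))
    )
    return LoGKernel(sigma=float(sigma), half_width=int(half_width), values=values)


def blob_filter(image: np.ndarray, kernel: LoGKernel) -> np.ndarray:
    """Convolve with the LoG kernel (reflected border), FFT-accelerated.

    The continuous LoG integrates to zero but its truncated discrete
    sampling does not; the kernel mean is subtracted during convolution so
    flat regions map to exactly zero response (pure DC rejection).
    """
    image = np.asarray(image, dtype=float)
    hw = kernel.half_width
    if min(image.shape) <= 2 * hw:
        raise ValueError("kernel does not fit inside the image")
    k = kernel.values - kernel.values.mean()
    padded = np.pad(image, hw, mode="reflect")
    resp = signal.fftconvolve(padded, k, mode="same")
    return resp[hw:-hw, hw:-hw]


def threshold_blobs(filtered: np.ndarray, threshold: float) -> np.ndarray:
    """Zero sub-threshold response; keep surviving values (non-binary)."""
    out = np.where(filtered >= threshold, filtered, 0.0)
    return np.maximum(out, 0.0)


def _measure(
    mask: np.ndarray, values: np.ndarray, min_area: int
) -> list[Blob]:
    labels, n = ndimage.label(mask, structure=_EIGHT)
    blobs: list[Blob] = []
    for sl, lab in zip(ndimage.find_objects(labels), range(1, n + 1)):
        comp = labels[sl] == lab
        if int(comp.sum()) < min_area:
            continue
        ys_loc, xs_loc = np.nonzero(comp)
        y0, x0 = sl[0].start, sl[1].start
        patch = np.where(comp, values[sl], 0.0)
        blobs.append(
            Blob(
                xs=xs_loc + x0,
                ys=ys_loc + y0,
                intensity_patch=patch,
                bbox=(x0, y0, sl[1].stop - x0, sl[0].stop - y0),
            )
        )
    return blobs


def label_blobs(blob_image: np.ndarray, min_area: int = 1) -> list[Blob]:
    """8-connected components of the thresholded response, measured.

    Components smaller than ``min_area`` pixels are discarded as noise.
    """
    blob_image = np.asarray(blob_image, dtype=float)
    if (blob_image < 0).any():
        raise ValueError("blob image must be nonnegative")
    return _measure(blob_image > 0, blob_image, max(min_area, 1))


def split_merged(
    blobs: list[Blob], cfg: SplitConfig, expected_area: float | None = None
) -> list[Blob]:
    """Split blobs whose area is a multiple of the typical fly area.

    The expected single-fly area defaults to the mean area over all blobs
    in the frame (pass ``expected_area`` to supply a prior instead, e.g.
    when a frame holds few blobs).  Each blob with
    ``round(area / expected) = m > 1`` is
    re-thresholded inside its own bbox at levels rising from
    ``base_threshold``; escalation stops as soon as at least ``m``
    sufficiently large components emerge (keeping the ``m`` largest) or
    after ``max_iter`` steps, in which case the original blob is kept —
    heavily overlapping flies legitimately stay one detection.
    """
    if not blobs:
        raise ValueError("split_merged needs at least one blob")
    expected = (
        float(np.mean([b.area for b in blobs]))
        if expected_area is None
        else float(expected_area)
    )
    min_area = max(1, int(round(cfg.min_area_frac * expected)))
    out: list[Blob] = []
    for b in blobs:
        m = max(1, int(round(b.area / expected)))
        if m == 1:
            out.append(b)
            continue
        span = float(b.intensity_patch.max()) - cfg.base_threshold
        step = cfg.step if cfg.step is not None else max(
            cfg.step_frac * span, 1e-9
        )
        x0, y0 = b.bbox[0], b.bbox[1]
        split: list[Blob] | None = None
        for it in range(1, cfg.max_iter + 1):
            thr = cfg.base_threshold + it * step
            mask = b.intensity_patch >= thr
            if not mask.any():
                break
            subs = _measure(mask, b.intensity_patch, min_area)
            if len(subs) >= m:
                subs.sort(key=lambda s: s.area, reverse=True)
                split = subs[:m]
                break
        if split is None:
            out.append(b)
        else:
            for s in split:
                out.append(
                    Blob(
                        xs=s.xs + x0,
                        ys=s.ys + y0,
                        intensity_patch=s.intensity_patch,
                        bbox=(s.bbox[0] + x0, s.bbox[1] + y0, s.bbox[2], s.bbox[3]),
                    )
                )
    return out
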