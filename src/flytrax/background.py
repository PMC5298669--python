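"""Static background extraction and foreground isolation.

The arena background is recovered as the per-pixel *mode* over a random
sample of frames: a pixel's most frequent intensity is its background value
provided moving flies occupy it a minority of the time.  Frames are then
mean-shifted against the plate to cancel slow illumination drift, and the
absolute difference from the plate is intensity-reversed so that flies are
dark objects on a light field for the downstream blob filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .synth import FrameStack

__all__ = [
    "BackgroundPlate",
    "extract_background",
    "adjust_intensity",
    "subtract_background",
]

DEFAULT_N_SAMPLES = 100


@dataclass
class BackgroundPlate:
    image: np.ndarray  # float, same shape as frames
    mean_intensity: float
    n_samples: int


def extract_background(
    frames: FrameStack | np.ndarray,
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
) -> BackgroundPlate:
    """Per-pixel mode over ``n_samples`` frames sampled without replacement.

    Ties take the smallest tied value.  With ``n_samples`` equal to the
    stack length every frame is used and no sampling randomness remains.
    """
    arr = frames.frames if isinstance(frames, FrameStack) else np.asarray(frames)
    if arr.ndim != 3 or arr.shape[0] == 0:
        raise ValueError("need a non-empty (n, H, W) frame stack")
    n_total = arr.shape[0]
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    n_samples = min(n_samples, n_total)
    if n_samples == n_total:
        sample = arr
    else:
        rng = np.random.default_rng(seed)
        idx = rng.choice(n_total, size=n_samples, replace=False)
        sample = arr[np.sort(idx)]
    mode = stats.mode(sample, axis=0, keepdims=False).mode
    image = mode.astype(float)
    return BackgroundPlate(
        image=image, mean_intensity=float(image.mean()), n_samples=n_samples
    )


def adjust_intensity(frame: np.ndarray, plate: BackgroundPlate) -> np.ndarray:
    """Shift a frame's mean intensity to the plate's (drift correction).

    Adds the constant ``plate.mean_intensity - mean(frame)`` to every pixel
    and clips to [0, 255]; absent clipping the output mean equals the
    plate mean exactly.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.shape != plate.image.shape:
        raise ValueError(
            f"frame shape {frame.shape} != plate shape {plate.image.shape}"
        )
    shift = plate.mean_intensity - frame.mean()
    return np.clip(frame + shift, 0.0, 255.0)


def subtract_background(frame: np.ndarray, plate: BackgroundPlate) -> np.ndarray:
    """Reversed-intensity difference image: flies dark on a light field.

    Static pixels map to 255 (no difference from the plate); pixels that
    depart from the plate — fly bodies and wings — map toward 0 in
    proportion to the departure.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.shape != plate.image.shape:
        raise ValueError(
            f"frame shape {frame.shape} != plate shape {plate.image.shape}"
        )
    return 255.0 - np.abs(frame - plate.image)
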