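import numpy as np
import pytest

import flytrax as ft
from flytrax import background as bg
from flytrax import detect as det


@pytest.fixture
def small_spec():
    """A compact single-fly arena used across detection/posture tests."""
    return ft.SceneSpec(
        image_size=(96, 96),
        arena_center=(48.0, 48.0),
        arena_radius=40.0,
        n_flies=1,
        noise_sd=2.0,
    )


def plate_of(spec):
    img = ft.background_plate(spec)
    return bg.BackgroundPlate(img, float(img.mean()), 1)


def detect_single(frame, spec, threshold=1.0, sigma=6.0):
    """Run subtract -> LoG -> threshold -> label on a known-plate frame."""
    fg = bg.subtract_background(np.asarray(frame, dtype=float), plate_of(spec))
    resp = det.blob_filter(fg, det.log_kernel(sigma))
    return det.label_blobs(det.threshold_blobs(resp, threshold), min_area=4)


def random_blob(rng, n_pixels=50):
    """A random connected-ish pixel set as a Blob (grown from a seed pixel)."""
    pts = {(30, 30)}
    while len(pts) < n_pixels:
        x, y = list(pts)[rng.integers(len(pts))]
        dx, dy = rng.integers(-1, 2), rng.integers(-1, 2)
        pts.add((x + dx, y + dy))
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    x0, y0 = xs.min(), ys.min()
    w, h = xs.max() - x0 + 1, ys.max() - y0 + 1
    patch = np.zeros((h, w))
    patch[ys - y0, xs - x0] = 1.0
    return det.Blob(xs=xs, ys=ys, intensity_patch=patch, bbox=(x0, y0, w, h))
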