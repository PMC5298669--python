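"""Detect one fly and recover its posture (ellipse + heading).

Renders a single fly at a known pose, runs background subtraction, the
LoG blob filter and the moment-ellipse fit, then scores wing pixels to
decide which end of the body is the head.
"""

import numpy as np

import flytrax as ft
from flytrax import background as bg
from flytrax import detect as det
from flytrax import posture as pm

TRUE_HEADING = 0.8  # radians, y-down image frame

spec = ft.SceneSpec(image_size=(96, 96), arena_center=(48.0, 48.0),
                    arena_radius=40.0, n_flies=1, noise_sd=2.0)
frame = ft.render_snapshot(spec, [(48.0, 48.0)], [TRUE_HEADING], noise_seed=3)

img = ft.background_plate(spec)
plate = bg.BackgroundPlate(img, float(img.mean()), 1)
fg = bg.subtract_background(frame.astype(float), plate)
resp = det.blob_filter(fg, det.log_kernel(sigma=6.0))
blobs = det.label_blobs(det.threshold_blobs(resp, 1.0), min_area=4)

b = blobs[0]
fit = pm.ellipse_fit(pm.second_moments(b), pm.centroid(b))
res = pm.heading_direction(b, fit, frame.astype(float))
est = np.arctan2(res.direction[1], res.direction[0])

print(f"blob: area {b.area} px, centroid ({fit.centroid[0]:.1f}, {fit.centroid[1]:.1f})")
print(f"ellipse: major {fit.major:.1f} px, minor {fit.minor:.1f} px, "
      f"orientation {np.degrees(fit.theta):.1f} deg")
print(f"wing scores: head end {res.score_head_end}, tail end {res.score_tail_end} "
      "(wings trail the head, so the low-score end is the head)")
print(f"heading: true {np.degrees(TRUE_HEADING):.1f} deg, "
      f"estimated {np.degrees(est):.1f} deg")
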