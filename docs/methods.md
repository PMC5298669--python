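# Methods

This note documents the models, the parameters that matter, the synthetic
scenes the tests run on, and the places where the design was genuinely
open and a choice had to be made.

## Background model

The arena background is the per-pixel mode over `n_samples` frames drawn
without replacement (default 100; with fewer frames than that, all are
used and no sampling randomness remains). The mode argument requires each
pixel to be fly-free in a strict majority of sampled frames; a fly that
never moves is therefore *part of the background* and invisible to
detection — this is inherent to the model, not a defect, and the test
suite covers it explicitly. Mode ties take the smallest tied value (any
deterministic rule would do). Illumination drift is cancelled by shifting
each frame's mean intensity onto the plate's mean before subtraction;
foreground isolation is the reversed absolute difference
`255 − |frame − plate|`, chosen so that downstream code can always assume
dark-fly-on-light-field regardless of input polarity. All intensity
arithmetic is floating point; quantization happens only at I/O boundaries.

## Blob detection

* **LoG kernel.** Sampled on the integer grid `[-h, h]²` with
  `h = ceil(3σ)`; σ defaults to 6 px, matched to the rendered fly scale
  (the response zero-crossing at `σ√2 ≈ 8.5 px` sits near the body
  half-width). The truncated discrete kernel does not sum to zero, so the
  kernel mean is subtracted during convolution; flat regions then map to
  exactly zero and the filter is purely band-pass. Convolution is
  FFT-based with reflected borders.
* **Threshold.** Non-binary: sub-threshold response is zeroed, surviving
  pixels keep their values, so each blob carries an intensity profile that
  the splitting step needs. The default (1.0 in response units, against a
  single-fly peak of ≈ 2.5–3) is a starting point; the CLI's
  `--threshold-preview` prints blob counts across candidate values.
* **Merged-blob splitting.** The expected single-fly area is the mean blob
  area in the frame (an `expected_area` prior can be supplied when a frame
  holds too few blobs for the mean to be meaningful). For a blob with
  `round(area / expected) = m > 1`, the threshold inside its bbox is
  raised step by step; the step defaults to 2% of the blob's response span
  so that `max_iter = 60` iterations sweep the whole span. Escalation
  stops as soon as ≥ m sufficiently large components emerge (the m largest
  are kept — escalation can jump past exactly m) or the iteration budget
  is exhausted, in which case the original blob stands: flies overlapping
  more than ~70% of their body area genuinely cannot be separated by
  thresholding and remain one detection for the tracker to carry.
  Components below 20% of the expected area are discarded as noise
  throughout.

## Posture

Moments use the standard +1/12 correction on `u_xx` and `u_yy` (the
normalized second central moment of a unit pixel). The cross term `u_xy`
carries **no** such constant — adding one would tilt every axis-aligned
region, and the fit would no longer agree with the eigendecomposition of
the central second-moment matrix, which the tests use as an independent
oracle. Axis lengths are `a = 2√2·√(u_xx+u_yy+Δ)` and
`b = 2√2·√(u_xx+u_yy−Δ)` (equivalently `4√λ` on the covariance
eigenvalues), the convention in which a/b are the full major/minor axis
lengths of the moment-equivalent ellipse.

Heading disambiguation places two search points at the ellipse vertices
(`centroid ± (a/2)(cosθ, sinθ)`) and sweeps (floor, ceiling) intensity
couples over the band strictly between the body's 90th-percentile
intensity and the local background level. The couples are spread evenly
across that band (6 windows, each at least 10 gray levels wide) rather
than stepped at a fixed 5-level stride from the bottom — a fixed stride
cannot reach wing intensities when the body–background band is wide. Per
couple, marked pixels are counted inside each search disc (radius
0.35 × a by default); a couple whose marked pixels fall mostly *outside*
both discs (more than `env_reject_ratio = 0.5` of the total) is treated as
environment noise and contributes nothing. The winning (wing) end must
score more than `min_score = 3`; ties and sub-threshold scores yield
`valid = false`, and the tracker then treats the detection's heading as
unavailable rather than guessing. Near-circular fits (b/a > 0.9) are
invalid by construction since the axis direction is undefined. Known
failure modes — wings extended sideways, a blurred flying fly — are
reproduced in the tests only as "may be invalid or wrong-ended".

Angle convention everywhere: radians, zero along +x, counter-clockwise
positive *in the y-down image frame* (so +π/2 points down the image);
ellipse orientation θ lives in (−π/2, π/2].

## Tracking

State `(x, y, vx, vy)` with the constant-velocity transition; Δt is one
frame internally (velocities convert to px/s at the I/O layer). Process
noise comes from a white-acceleration model (`q_accel_sd`, default
10 px/frame², sized for walks with occasional jumps); measurement noise is
isotropic (`r_sd = 2 px`, the centroid jitter observed on rendered
fixtures). Neither covariance is a measured constant of the method — both
are exposed configuration. New trackers start with zero velocity.

Per frame: predict → Hungarian on predicted-position distances →
heading gate → greedy repair → update/birth/retire. The cost matrix is
padded to `(n+m) × (m+n)` with dummy rows/columns at
`dummy_cost = 1.5 × gate` (gate default 50 px/frame), so any tracker or
detection can go unmatched rather than take an implausible pair;
dummy–dummy entries cost zero. The heading gate accepts a pair when the
angle between the tracker's stored heading and the detection's heading is
within `heading_tolerance` (default π/2); pairs with a missing heading are
accepted — heading is confirmatory evidence, not a requirement — and
dummy pairs are always rejected into the repair pool. The repair stage
re-matches the pooled trackers and detections greedily (globally smallest
cost first, ties broken by lowest row then column index) on the trackers'
*pre-prediction* positions: a fly that stopped and reversed is closest to
where its tracker *was*, not where the prediction went. The stored
tracker heading compared in the gate is the last detection heading (not
the displacement direction), since body orientation is stable through
stops and reversals while velocity direction is not. Trackers missing
longer than `max_missed = 10` frames retire; unmatched detections spawn
new identities in birth order.

Hungarian assignment itself is delegated to
`scipy.optimize.linear_sum_assignment`; the tests verify it against an
exhaustive-permutation oracle, and the greedy stage against a literal
list-based re-trace.

## Two-phase pipeline

Detection (background → LoG → posture) runs over all frames first and
persists a CSV plus a JSON manifest (config hash, seed); tracking is a
fold over that table and never touches pixels. This makes tracking
re-runnable with different parameters at zero detection cost, and makes
the determinism guarantee concrete: identical input, config and seed give
byte-identical detections and trajectory files. The reported frame
interval is `round(1/fps, 4)` seconds (19 fps → 0.0526 s).

Input is a directory of numbered grayscale PNG/TIFF frames; compressed
video containers are out of scope for I/O (no ffmpeg backend is assumed).

## Evaluation

A trajectory row is associated with the nearest true fly within one body
length, but only when unambiguous (second-nearest fly outside the
radius): inside a crossing both flies are within reach of one detection
and no association is scored, so only identity exchanges that *persist
past* the contact count. `swaps` counts per-track association changes
between two valid flies (a mutual exchange counts once per track);
`losses` counts a fly's covering id changing to a newly born id; false
positives are tracks never associated with any fly.

## Synthetic scenes

The generator renders what the detection model assumes and nothing more:
uniform elliptical bodies (semi-axes 12 × 6 px) at intensity 40, a single
trailing wing patch at 120 centered 0.9 semi-major-axes behind the
centroid, arena floor at 200 (surround at half that), min-compositing so
overlapping bodies merge into one dark region, optional per-frame
illumination drift and Gaussian pixel noise (default SD 2), quantized to
8-bit. Motion is a correlated random walk (turn SD 0.35 rad/frame, step
uniform in 0.5–1.5 × 2 px/frame ⇒ ≈ 40 px/s at 20 fps, inside the
13–94 px/s range typical of walking groups) with reflective arena walls,
optional jumps of 5–15 walk steps in a random direction, and active
avoidance: a step that would bring two flies within 1.5 body lengths is
re-drawn, and a crowded fly steps directly away from its nearest
neighbor, so near-contact occurs only where a crossing is *scripted*.
Scripted crossings steer a pair onto straight tracks passing within 0.8
body lengths at a chosen frame, aborting early if the path would plow
through a bystander. Everything derives from one seed; identical specs
render bit-identical stacks.

What the scenes deliberately lack: body texture, leg/wing articulation,
perspective, shadows, occlusion by arena walls, and size variation
between individuals. Passing tests therefore demonstrate the algorithmic
chain under its own stated assumptions — clean dark-on-light bodies with
intermediate-intensity wings — not robustness to real-video nuisances
such as reflections or flies climbing the wall.

## Problem sizes in the tests and acceptance script

Assignment oracles run on 500–1000 random matrices up to 6×6 (exhaustive
permutation is exact there); the ellipse oracle on 500 random connected
blobs; heading accuracy on 200 single-fly images; background recovery on
a 200-frame noise-free stack (the per-pixel mode can only equal the
stored plate *exactly* when quantization noise is absent — noisy and
drifting stacks are covered separately with tolerances); end-to-end
identity preservation on 10 flies × 300 frames at 256×256 px plus a
3-fly scripted-crossing scene. These sizes keep any single check under a
few tens of seconds while leaving the statistics stable across seeds.
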