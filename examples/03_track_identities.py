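"""Track a group of flies end to end and score against ground truth.

Renders an 8-fly scene with one scripted near-contact event, runs the
two-phase pipeline (detect all frames, then track), and reports identity
swaps / losses / false positives against the known trajectories.
"""

import flytrax as ft

spec = ft.SceneSpec(n_flies=8, n_frames=150, noise_sd=2.0, rng_seed=13,
                    crossings=((75, 0, 1),))
truth = ft.simulate_motion(spec)
stack = ft.render_video(spec, truth)

cfg = ft.RunConfig(fps=spec.fps)
detections = ft.detect_all(stack, cfg)
trajectories, summary = ft.track_all(detections, cfg)
score = ft.evaluate(trajectories, truth, match_radius=spec.body_length)

print(f"frame interval: {ft.frame_interval(spec.fps)} s")
print(f"{len(detections)} detections over {summary['n_frames']} frames; "
      f"{summary['n_identities']} identities "
      f"({spec.n_flies} flies rendered)")
print(f"matched fraction: {summary['matched_fraction']:.3f}")
print(f"vs ground truth: {score['swaps']} swaps, {score['losses']} losses, "
      f"{score['false_positives']} false positives "
      "(0/0/0 means every identity stayed on its fly, including through "
      "the scripted near-contact)")
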