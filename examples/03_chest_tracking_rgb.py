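"""Extract a respiratory signal from a synthetic RGB chest video.

Renders a 64x64 px video whose textured chest patch translates vertically
with a 12 breaths/min signal, selects minimum-eigenvalue corner points on
the chest, tracks them with the Lucas-Kanade tracker, projects each 2-D
trajectory onto its primary motion direction, and fuses the candidate
signals with correlation gating + moving-window PCA.
"""

import numpy as np

from breathsense import RespiratorySignal, VideoScene, extract_chest_observations, fuse_observations, render_video

fs = 10.0
t = np.arange(600) / fs
truth = RespiratorySignal(samples=np.sin(2 * np.pi * 0.2 * t), fs=fs)

scene = VideoScene(gain=2.0)
video = render_video(truth, "rgb", scene)
print(f"rendered {len(video)} frames of {video.shape[0]}x{video.shape[1]} px")

O = extract_chest_observations(video, chest_roi=scene.chest, n_points=20)
amps = (O.values.max(axis=0) - O.values.min(axis=0)) / 2
print(f"observation matrix: {O.values.shape[1]} trajectories x {O.values.shape[0]} frames")
print(f"per-trajectory amplitude [px]: {np.round(amps, 2)} (displacement gain was 2.0)")

fused = fuse_observations(O, keep=5, window_length=30)
r = np.corrcoef(fused.samples, truth.samples)[0, 1]
print(f"fused signal vs ground truth: |r| = {abs(r):.4f}")
print("\nTracked amplitudes sit near the 2 px displacement gain and the")
print("fused signal is essentially the planted breathing motion.")
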