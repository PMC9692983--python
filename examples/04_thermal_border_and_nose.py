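"""Thermal-video extraction: border RoIs with a motion gate, and nose RoI.

Renders an IRT scene (warm body on cold background, nose intensity in
antiphase with breathing, one deliberate non-respiratory bump), segments
the silhouette with Otsu's threshold, places RoIs along the border, and
shows how the motion error e_m flags the bump.  The nose signal is the
tracked nose box's mean intensity.
"""

import numpy as np

from breathsense import (
    RespiratorySignal,
    VideoScene,
    extract_border_observations,
    extract_nose_signal,
    fuse_observations,
    otsu_foreground,
    render_video,
    select_feature_points,
)

fs = 10.0
t = np.arange(400) / fs
truth = RespiratorySignal(samples=0.8 * np.sin(2 * np.pi * 0.2 * t), fs=fs)
scene = VideoScene(bump_frame=200)
video = render_video(truth, "irt", scene)

mask = otsu_foreground(video.frames[0])
print(f"Otsu foreground: {mask.sum()} px silhouette")

O = extract_border_observations(video, n_rois=20, roi_size=11, motion_threshold=30.0)
invalid = np.flatnonzero(~O.frame_valid)
print(f"motion gate: frames {invalid.min()}..{invalid.max()} unusable "
      f"(bump at frame {scene.bump_frame}, RoIs re-initialized 2 s later)")

fused = fuse_observations(O, keep=5)
ok = O.frame_valid
print(f"border-RoI fused signal vs truth (usable frames): "
      f"|r| = {abs(np.corrcoef(fused.samples[ok], truth.samples[ok])[0, 1]):.3f}")

pts = select_feature_points(video.frames[0], roi=scene.head, n=6, min_distance=2)
nose = extract_nose_signal(video, pts, nose_roi=scene.nose)
mag = np.abs(np.fft.rfft(nose.samples - nose.samples.mean()))
freqs = np.fft.rfftfreq(len(nose.samples), 1 / fs)
r = np.corrcoef(nose.samples, truth.samples)[0, 1]
print(f"nose signal: dominant frequency {freqs[np.argmax(mag)]:.2f} Hz, r = {r:.3f}")
print("\nThe nose tracks the breathing frequency in antiphase (inspiration")
print("cools the nostrils) but carries no effort information, which is why")
print("the classification pipeline relies on the chest and border signals.")
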