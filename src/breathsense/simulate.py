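"""Synthetic subjects and synthetic RGB / thermal frame sequences.

The dataset this pipeline was designed for consists of camera recordings of
volunteers breathing along the reference protocol.  This module emulates
those recordings so every downstream stage is testable: a *subject* is a
noisy, lagged, rescaled rendition of the reference signal (imperfect
protocol compliance), and a *video* is a small intensity-image stack with a
textured chest patch that translates vertically with the breathing motion.
Thermal (IRT) mode adds a warm body silhouette on a cold background and a
nose region whose mean intensity is modulated in antiphase with the signal
(inspiration cools the nostrils, expiration warms them).

None of this models physiology or radiometry; it reproduces the geometric
and statistical structure the extraction algorithms rely on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .protocol import ReferenceSignal
from .signals import RespiratorySignal

__all__ = [
    "SubjectConfig",
    "FrameSequence",
    "VideoScene",
    "simulate_subject",
    "simulate_cohort",
    "render_video",
]


@dataclass(frozen=True)
class SubjectConfig:
    """Deviations a simulated subject applies to the reference signal.

    Defaults are the study conditions used throughout the tests and the
    synthetic classification experiment: mild sensor/compliance noise
    (sd 0.05 n.u.), 5 % breath-rate jitter, slow baseline wander of
    0.1 n.u. at 0.02 Hz, and a Kussmaul effort deficit (gain 0.6) emulating
    the observed inability of subjects to reach the demanded Kussmaul
    effort.  ``re_gain`` rescales the whole signal (subjects and sensors
    differ in motion amplitude); ``lag`` delays the response relative to the
    on-screen reference.
    """

    noise_sd: float = 0.05
    rr_jitter_frac: float = 0.05
    re_gain: float = 1.0
    baseline_amp: float = 0.1
    baseline_freq: float = 0.02
    lag: float = 0.0
    kussmaul_gain: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.rr_jitter_frac < 0.5:
            raise ValueError("rr_jitter_frac must be in [0, 0.5)")
        if self.re_gain <= 0:
            raise ValueError("re_gain must be positive")


@dataclass
class FrameSequence:
    """Stack of H x W intensity frames with timestamps."""

    frames: np.ndarray  # (m, H, W) float
    fps: float
    modality: str = "rgb"  # rgb | irt
    timestamps: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (m, H, W) stack")
        if self.timestamps is None:
            self.timestamps = np.arange(self.frames.shape[0]) / self.fps
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


def _smooth_unit_noise(n: int, fs: float, rng: np.random.Generator, corr_s: float = 2.0) -> np.ndarray:
    """Zero-mean smooth noise with max |value| = 1."""
    u = rng.standard_normal(n)
    u = ndimage.gaussian_filter1d(u, sigma=max(corr_s * fs, 1.0), mode="reflect")
    u -= u.mean()
    peak = np.max(np.abs(u))
    return u / peak if peak > 0 else u


def _warp_segment(x: np.ndarray, jitter_frac: float, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth time-warp of one segment, endpoints fixed.

    The local playback rate varies smoothly within +-jitter_frac, so breath
    intervals jitter while segment boundaries (and hence labels) stay put.
    """
    n = len(x)
    if n < 4 or jitter_frac <= 0:
        return x.copy()
    rate = 1.0 + jitter_frac * _smooth_unit_noise(n, fs, rng)
    pos = np.concatenate([[0.0], np.cumsum(rate)[:-1]])
    pos *= (n - 1) / pos[-1]  # pin the endpoint: same duration
    return np.interp(pos, np.arange(n), x)


def simulate_subject(
    ref: ReferenceSignal,
    cfg: SubjectConfig = SubjectConfig(),
    modality: str = "synthetic",
) -> RespiratorySignal:
    """One subject's rendition of the reference protocol.

    Applies, in order: per-segment smooth rate jitter, a Kussmaul-only
    effort deficit, a global effort gain, a response lag, sinusoidal
    baseline wander and additive white Gaussian noise.  With all corruption
    parameters zero and unit gains this is the identity on the reference.
    Reproducible under ``cfg.seed``.
    """
    if len(ref.samples) == 0:
        raise ValueError("reference signal is empty")
    if cfg.lag >= ref.duration:
        raise ValueError("lag longer than the signal")

    rng = np.random.default_rng(cfg.seed)
    fs = ref.fs
    x = ref.samples.astype(float).copy()

    if cfg.rr_jitter_frac > 0:
        for seg in ref.annotation or []:
            sl = slice(int(round(seg.start * fs)), int(round(seg.end * fs)))
            x[sl] = _warp_segment(x[sl], cfg.rr_jitter_frac, fs, rng)

    if cfg.kussmaul_gain != 1.0 and ref.annotation is not None:
        for seg in ref.annotation:
            if seg.label == "kussmaul":
                sl = slice(int(round(seg.start * fs)), int(round(seg.end * fs)))
                x[sl] *= cfg.kussmaul_gain

    x *= cfg.re_gain

    ann = ref.annotation
    if cfg.lag != 0.0:
        t = np.arange(len(x)) / fs
        x = np.interp(t - cfg.lag, t, x, left=0.0, right=0.0)
        if ann is not None:
            ann = ann.shifted(cfg.lag).clipped(len(x) / fs)

    if cfg.baseline_amp > 0:
        t = np.arange(len(x)) / fs
        phase = rng.uniform(0, 2 * math.pi)
        x = x + cfg.baseline_amp * np.sin(2 * math.pi * cfg.baseline_freq * t + phase)

    if cfg.noise_sd > 0:
        x = x + cfg.noise_sd * rng.standard_normal(len(x))

    return RespiratorySignal(samples=x, fs=fs, modality=modality, annotation=ann)


def simulate_cohort(
    ref: ReferenceSignal,
    n_subjects: int = 10,
    seed: int = 0,
    modality: str = "synthetic",
) -> tuple[list[RespiratorySignal], list[SubjectConfig]]:
    """Simulate a cohort with per-subject randomized compliance.

    Per-subject draws (study conditions): effort gain log-uniform in
    [0.7, 1.5], response lag uniform in [0, 1] s, Kussmaul deficit uniform
    in [0.5, 0.8]; noise, jitter and baseline wander at their defaults.
    """
    rng = np.random.default_rng(seed)
    signals, configs = [], []
    for i in range(n_subjects):
        cfg = SubjectConfig(
            re_gain=float(np.exp(rng.uniform(math.log(0.7), math.log(1.5)))),
            lag=float(rng.uniform(0.0, 1.0)),
            kussmaul_gain=float(rng.uniform(0.5, 0.8)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        signals.append(simulate_subject(ref, cfg, modality=modality))
        configs.append(cfg)
    return signals, configs


@dataclass(frozen=True)
class VideoScene:
    """Geometry of the rendered scene (pixels; origin top-left).

    ``gain`` converts signal units to vertical displacement in px.  In IRT
    mode, ``fg_level``/``bg_level`` set the warm-body / cold-background
    intensities, and the nose box mean is ``fg_level - nose_gain * sig``.
    ``bump_frame`` optionally injects a non-respiratory event (a global
    horizontal shift of ``bump_px``) for motion-gate testing.
    """

    height: int = 64
    width: int = 64
    gain: float = 2.0
    chest: tuple[int, int, int, int] = (20, 34, 24, 16)  # x, y, w, h
    body: tuple[int, int, int, int] = (16, 28, 32, 36)
    head: tuple[int, int, int, int] = (24, 4, 16, 24)  # neck touches the torso
    nose: tuple[int, int, int, int] = (29, 18, 6, 4)
    bg_level: float = 50.0
    fg_level: float = 200.0
    nose_gain: float = 20.0
    texture_sd: float = 25.0
    bump_frame: int | None = None
    bump_px: float = 4.0
    seed: int = 0


def _put_rect(canvas: np.ndarray, rect: tuple[int, int, int, int], value: np.ndarray | float) -> None:
    x, y, w, h = rect
    canvas[y : y + h, x : x + w] = value


def render_video(
    sig: RespiratorySignal,
    mode: str = "rgb",
    scene: VideoScene = VideoScene(),
    fps: float | None = None,
) -> FrameSequence:
    """Render a frame sequence whose chest region moves with ``sig``.

    The moving layer (chest patch in RGB mode; the whole warm silhouette in
    IRT mode) is translated vertically by ``scene.gain * sig[k]`` px with
    bilinear subpixel interpolation, so rendered displacement is linear in
    the signal.  A constant signal yields identical frames.
    """
    if mode not in ("rgb", "irt"):
        raise ValueError("mode must be 'rgb' or 'irt'")
    fps = sig.fs if fps is None else fps
    if fps > sig.fs:
        raise ValueError("fps must not exceed the signal sampling rate")
    step = int(round(sig.fs / fps))
    samples = sig.samples[::step]

    H, W = scene.height, scene.width
    rng = np.random.default_rng(scene.seed)
    disp = scene.gain * samples
    max_d = float(np.max(np.abs(disp))) if len(disp) else 0.0

    if mode == "rgb":
        bg = 100.0 + 10.0 * ndimage.gaussian_filter(rng.standard_normal((H, W)), 3)
        layer0 = np.zeros((H, W))
        alpha0 = np.zeros((H, W))
        cx, cy, cw, ch = scene.chest
        if cy - max_d < 1 or cy + ch + max_d > H - 1:
            raise ValueError("chest displacement exceeds frame bounds")
        _put_rect(layer0, scene.chest, 120.0 + scene.texture_sd * rng.standard_normal((ch, cw)))
        _put_rect(alpha0, scene.chest, 1.0)
        nose_mask = None
    else:
        bg = scene.bg_level + 2.0 * ndimage.gaussian_filter(rng.standard_normal((H, W)), 2)
        layer0 = np.zeros((H, W))
        alpha0 = np.zeros((H, W))
        for rect in (scene.body, scene.head):
            x, y, w, h = rect
            _put_rect(layer0, rect, scene.fg_level + 0.15 * scene.texture_sd * rng.standard_normal((h, w)))
            _put_rect(alpha0, rect, 1.0)
        # cloth wrinkles: strong thermal texture on the chest region
        cx, cy, cw, ch = scene.chest
        _put_rect(layer0, scene.chest, scene.fg_level - 30.0 + scene.texture_sd * rng.standard_normal((ch, cw)))
        # the torso may extend past the frame bottom; only the head/top must stay inside
        if scene.head[1] - max_d < 1:
            raise ValueError("body displacement exceeds frame bounds")
        nose_mask = np.zeros((H, W))
        _put_rect(nose_mask, scene.nose, 1.0)
        layer0 = np.where(nose_mask > 0, scene.fg_level, layer0)

    frames = np.empty((len(samples), H, W))
    for k, d in enumerate(disp):
        layer = layer0
        if mode == "irt":
            # nostril temperature in antiphase with inspiration
            layer = layer0 - nose_mask * (scene.nose_gain * samples[k])
        if d != 0.0:
            lay = ndimage.shift(layer, (d, 0), order=1, mode="constant", cval=0.0)
            alp = ndimage.shift(alpha0, (d, 0), order=1, mode="constant", cval=0.0)
        else:
            lay, alp = layer, alpha0
        frame = bg * (1.0 - alp) + lay * alp
        if scene.bump_frame is not None and k == scene.bump_frame:
            frame = ndimage.shift(frame, (0, scene.bump_px), order=1, mode="nearest")
        frames[k] = frame

    return FrameSequence(frames=frames, fps=fps, modality=mode)
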