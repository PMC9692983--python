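"""Raw respiratory signal extraction from frame sequences.

Three families of candidate signals are produced:

* **Chest tracking** (RGB and IRT): minimum-eigenvalue corner points are
  selected on the chest, tracked over time with a pyramidal Lucas-Kanade
  (KLT) tracker, and each 2-D trajectory is projected onto its primary
  direction of motion via an SVD of the mean-centered point cloud.  The
  projected 1-D signals form the columns of an observation matrix ``O``.
* **Border RoIs** (IRT): the warm subject is segmented from the cold
  background with Otsu's threshold, square regions of interest are placed
  at equal arc-length spacing along the subject/background contour, and
  their per-frame mean intensities form ``O``.  A motion gate marks frames
  where the row-to-row change ``e_m = ||O_k - O_{k-1}||_2`` exceeds a
  threshold; the RoIs are re-initialized shortly after.
* **Nose RoI** (IRT): the mean intensity of a tracked box below the
  nostrils, used directly as a respiratory signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import corner_shi_tomasi, peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import find_contours, label as cc_label

from .signals import RespiratorySignal
from .simulate import FrameSequence

__all__ = [
    "Trajectory",
    "ObservationMatrix",
    "RoISet",
    "select_feature_points",
    "track_klt",
    "project_trajectories",
    "extract_nose_signal",
    "otsu_foreground",
    "init_border_rois",
    "extract_border_observations",
    "extract_chest_observations",
]


@dataclass
class Trajectory:
    """(x, y) pixel positions of one tracked point over m frames."""

    positions: np.ndarray  # (m, 2)
    id: int = 0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be (m, 2)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")

    def __len__(self) -> int:
        return self.positions.shape[0]


@dataclass
class ObservationMatrix:
    """m x n matrix whose columns are candidate 1-D respiratory signals."""

    values: np.ndarray  # (m, n)
    fs: float
    source_kind: str = "trajectory"  # trajectory | border_roi
    frame_valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.frame_valid is None:
            self.frame_valid = np.ones(self.values.shape[0], dtype=bool)
        self.frame_valid = np.asarray(self.frame_valid, dtype=bool)

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_signals(self) -> int:
        return self.values.shape[1]


@dataclass
class RoISet:
    """Square regions of interest, (x, y, w, h) in pixels."""

    boxes: np.ndarray  # (n, 4) int

    def __post_init__(self) -> None:
        self.boxes = np.atleast_2d(np.asarray(self.boxes, dtype=int))

    def __len__(self) -> int:
        return self.boxes.shape[0]


# ---------------------------------------------------------------------------
# feature point selection and KLT tracking


def select_feature_points(
    frame: np.ndarray,
    roi: tuple[int, int, int, int] | None = None,
    n: int = 50,
    min_distance: int = 3,
    response_floor: float = 1e-8,
) -> np.ndarray:
    """Select up to ``n`` minimum-eigenvalue (Shi-Tomasi) corner points inside ``roi``.

    Points are ranked by the smaller eigenvalue of the local structure
    tensor (good features to track) and spatially spread by a minimum
    peak distance.  Returns an (k, 2) array of (x, y) coordinates.
    Raises ``ValueError`` on a textureless region; warns if fewer than
    ``n`` corners are available.
    """
    frame = np.asarray(frame, dtype=float)
    if roi is None:
        roi = (0, 0, frame.shape[1], frame.shape[0])
    x0, y0, w, h = roi
    if x0 < 0 or y0 < 0 or x0 + w > frame.shape[1] or y0 + h > frame.shape[0]:
        raise ValueError("roi outside frame bounds")
    if n < 1:
        raise ValueError("n must be >= 1")

    response = corner_shi_tomasi(frame)
    sub = response[y0 : y0 + h, x0 : x0 + w]
    floor = response_floor * max(1.0, float(np.ptp(frame)) ** 2)
    peaks = peak_local_max(sub, min_distance=min_distance, threshold_abs=floor, exclude_border=2)
    if peaks.shape[0] == 0:
        raise ValueError("textureless roi: no corner response above floor")
    strengths = sub[peaks[:, 0], peaks[:, 1]]
    order = np.argsort(strengths)[::-1]
    peaks = peaks[order[:n]]
    if peaks.shape[0] < n:
        warnings.warn(f"only {peaks.shape[0]} corners available (requested {n})")
    # (row, col) -> (x, y), back to full-frame coordinates
    return np.stack([peaks[:, 1] + x0, peaks[:, 0] + y0], axis=1).astype(float)


def _sample(img: np.ndarray, ys: np.ndarray, xs: np.ndarray) -> np.ndarray:
    return ndimage.map_coordinates(img, [ys, xs], order=1, mode="nearest")


def _track_point_pair(
    I: np.ndarray,
    gx: np.ndarray,
    gy: np.ndarray,
    J: np.ndarray,
    p: np.ndarray,
    d0: np.ndarray,
    win: int,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, float, bool]:
    """Inverse-compositional Lucas-Kanade step for one point, one frame pair.

    Returns (displacement, residual, ok)."""
    r = win // 2
    oy, ox = np.mgrid[-r : r + 1, -r : r + 1]
    ys, xs = p[1] + oy.ravel(), p[0] + ox.ravel()
    T = _sample(I, ys, xs)
    Gx = _sample(gx, ys, xs)
    Gy = _sample(gy, ys, xs)
    G = np.array([[np.sum(Gx * Gx), np.sum(Gx * Gy)], [np.sum(Gx * Gy), np.sum(Gy * Gy)]])
    if np.linalg.det(G) < 1e-6:
        return d0, np.inf, False
    Ginv = np.linalg.inv(G)
    d = d0.astype(float).copy()
    for _ in range(max_iter):
        Jw = _sample(J, ys + d[1], xs + d[0])
        err = T - Jw
        b = np.array([np.sum(Gx * err), np.sum(Gy * err)])
        delta = Ginv @ b
        d += delta
        if np.hypot(*delta) < tol:
            break
    Jw = _sample(J, ys + d[1], xs + d[0])
    residual = float(np.mean(np.abs(T - Jw)))
    return d, residual, True


def _pyr_down(img: np.ndarray) -> np.ndarray:
    return ndimage.zoom(ndimage.gaussian_filter(img, 1.0), 0.5, order=1)


def track_klt(
    frames: FrameSequence,
    points: np.ndarray,
    win: int = 15,
    levels: int = 2,
    max_iter: int = 30,
    tol: float = 1e-3,
    err_thresh: float = 25.0,
) -> list[Trajectory]:
    """Track ``points`` through all frames with pyramidal Lucas-Kanade.

    Each point's local window is registered from frame to frame by
    iterative gradient descent on the intensity difference, coarse-to-fine
    over ``levels`` pyramid levels.  A point is *lost* (and its trajectory
    dropped entirely) when its window leaves the frame, the local structure
    tensor is degenerate, or the post-registration residual exceeds
    ``err_thresh`` intensity units.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] == 0:
        raise ValueError("empty point list")
    m = len(frames)
    H, W = frames.shape
    r = win // 2
    stack = frames.frames

    def in_bounds(p: np.ndarray) -> bool:
        return r <= p[0] <= W - 1 - r and r <= p[1] <= H - 1 - r

    for p in points:
        if not (0 <= p[0] <= W - 1 and 0 <= p[1] <= H - 1):
            raise ValueError("point outside first frame")

    n = points.shape[0]
    pos = np.full((m, n, 2), np.nan)
    pos[0] = points
    alive = np.array([in_bounds(p) for p in points])

    # pyramids are built lazily per frame
    def build_pyr(img: np.ndarray) -> list[np.ndarray]:
        pyr = [img]
        for _ in range(levels - 1):
            pyr.append(_pyr_down(pyr[-1]))
        return pyr

    pyrI = build_pyr(stack[0])
    for t in range(m - 1):
        pyrJ = build_pyr(stack[t + 1])
        grads = [np.gradient(lv) for lv in pyrI]  # (gy, gx) per level
        for i in range(n):
            if not alive[i]:
                continue
            p = pos[t, i]
            d = np.zeros(2)
            ok = True
            for lv in range(levels - 1, -1, -1):
                scale = 2.0**lv
                gyl, gxl = grads[lv]
                d, res, ok = _track_point_pair(
                    pyrI[lv], gxl, gyl, pyrJ[lv], p / scale, d / scale, win, max_iter, tol
                )
                d = d * scale
                if not ok:
                    break
            newp = p + d
            if not ok or not in_bounds(newp) or res > err_thresh:
                alive[i] = False
                continue
            pos[t + 1, i] = newp
        pyrI = pyrJ

    trajs = [Trajectory(pos[:, i], id=i) for i in range(n) if alive[i]]
    return trajs


def project_trajectories(
    trajs: list[Trajectory],
    fs: float = 10.0,
) -> ObservationMatrix:
    """Project each 2-D trajectory onto its primary direction of motion.

    Each trajectory is mean-centered and decomposed with an SVD; the
    positions are projected onto the first right singular vector (the
    principal axis of the 2-D point cloud).  The SVD's arbitrary sign is
    normalized so every column correlates positively with the ensemble
    mean signal.  A zero-variance trajectory yields an all-zero column
    (with a warning).
    """
    if not trajs:
        raise ValueError("no trajectories to project")
    m = len(trajs[0])
    if m < 2:
        raise ValueError("trajectories must have length >= 2")
    if any(len(t) != m for t in trajs):
        raise ValueError("all trajectories must share the same length")

    cols = []
    for t in trajs:
        X = t.positions - t.positions.mean(axis=0)
        U, S, Vt = np.linalg.svd(X, full_matrices=False)
        if S[0] <= 1e-12:
            warnings.warn(f"trajectory {t.id} has zero variance; emitting zero column")
            cols.append(np.zeros(m))
        else:
            cols.append(X @ Vt[0])
    O = np.stack(cols, axis=1)

    # sign normalization: align to the strongest column, then to the mean
    norms = np.linalg.norm(O, axis=0)
    if np.any(norms > 0):
        seed = int(np.argmax(norms))
        for _ in range(2):
            ref = O[:, seed] if _ == 0 else O.mean(axis=1)
            if np.linalg.norm(ref) == 0:
                break
            for j in range(O.shape[1]):
                c = float(O[:, j] @ ref)
                if c < 0:
                    O[:, j] = -O[:, j]
    return ObservationMatrix(values=O, fs=fs, source_kind="trajectory")


def extract_chest_observations(
    frames: FrameSequence,
    chest_roi: tuple[int, int, int, int],
    n_points: int = 50,
    **klt_kwargs,
) -> ObservationMatrix:
    """Chest-tracking pipeline: corners -> KLT -> SVD projection."""
    pts = select_feature_points(frames.frames[0], chest_roi, n=n_points)
    trajs = track_klt(frames, pts, **klt_kwargs)
    if not trajs:
        raise ValueError("all feature points were lost by the tracker")
    return project_trajectories(trajs, fs=frames.fps)


# ---------------------------------------------------------------------------
# thermal: nose RoI, Otsu foreground, border RoIs


def _roi_mean(frame: np.ndarray, box: np.ndarray | tuple, dy: float = 0.0, dx: float = 0.0) -> float:
    x, y, w, h = box
    oy, ox = np.mgrid[0:h, 0:w]
    ys = y + dy + oy.ravel()
    xs = x + dx + ox.ravel()
    return float(np.mean(_sample(frame, ys, xs)))


def extract_nose_signal(
    frames: FrameSequence,
    face_points: np.ndarray,
    nose_roi: tuple[int, int, int, int],
    **klt_kwargs,
) -> RespiratorySignal:
    """Mean intensity of the (tracked) nose box, used directly as signal.

    Facial feature points are tracked with the KLT tracker and their median
    displacement moves the nose box from frame to frame, so the box follows
    small head motion.
    """
    x, y, w, h = nose_roi
    H, W = frames.shape
    if x < 0 or y < 0 or x + w > W or y + h > H:
        raise ValueError("nose roi outside frame bounds")
    trajs = track_klt(frames, face_points, **klt_kwargs)
    if not trajs:
        raise ValueError("nose roi tracking lost (no surviving facial points)")
    disp = np.median(
        np.stack([t.positions - t.positions[0] for t in trajs], axis=0), axis=0
    )  # (m, 2) median (dx, dy)
    samples = np.array(
        [_roi_mean(frames.frames[k], nose_roi, dy=disp[k, 1], dx=disp[k, 0]) for k in range(len(frames))]
    )
    return RespiratorySignal(samples=samples, fs=frames.fps, modality="irt")


def otsu_foreground(frame: np.ndarray) -> np.ndarray:
    """Binary foreground mask by Otsu's threshold, largest component only.

    Raises ``ValueError`` on a (near-)uniform frame, where no threshold
    separates two classes.
    """
    frame = np.asarray(frame, dtype=float)
    if np.ptp(frame) == 0:
        raise ValueError("uniform frame: Otsu threshold undefined")
    if np.all(frame == np.round(frame)):
        # integer-valued (8/16-bit) frames: integer-aligned histogram makes
        # the threshold exact rather than bin-center approximate
        lo = int(frame.min())
        counts = np.bincount((frame - lo).astype(int).ravel())
        thr = threshold_otsu(hist=(counts, np.arange(lo, lo + len(counts), dtype=float)))
    else:
        thr = threshold_otsu(frame)
    mask = frame > thr
    if not mask.any() or mask.all():
        raise ValueError("degenerate Otsu segmentation")
    labels = cc_label(mask, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0  # background
    return labels == int(np.argmax(counts))


def init_border_rois(
    mask: np.ndarray,
    n: int = 30,
    size: int = 25,
) -> RoISet:
    """Place ``n`` size x size boxes along the foreground/background border.

    Box centers are sampled at equal arc-length spacing along the longest
    contour of the mask and clamped to the frame bounds.  Fewer boxes are
    returned (with a warning) if the contour is shorter than ``n`` pixels.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask: no boundary")
    contours = find_contours(mask.astype(float), 0.5)
    contour = max(contours, key=lambda c: c.shape[0])  # (row, col) points
    seglen = np.hypot(*np.diff(contour, axis=0).T)
    arclen = np.concatenate([[0.0], np.cumsum(seglen)])
    total = arclen[-1]
    n_eff = min(n, contour.shape[0])
    if n_eff < n:
        warnings.warn(f"contour supports only {n_eff} rois (requested {n})")
    targets = np.linspace(0.0, total, n_eff, endpoint=False)
    idx = np.searchsorted(arclen, targets)
    centers = contour[np.clip(idx, 0, contour.shape[0] - 1)]

    H, W = mask.shape
    boxes = []
    for row, col in centers:
        x = int(round(col)) - size // 2
        y = int(round(row)) - size // 2
        x = min(max(x, 0), W - size)
        y = min(max(y, 0), H - size)
        boxes.append((x, y, size, size))
    return RoISet(boxes=np.array(boxes))


def extract_border_observations(
    frames: FrameSequence,
    rois: RoISet | None = None,
    n_rois: int = 30,
    roi_size: int = 25,
    motion_threshold: float = 5.0,
    reinit_delay: float = 2.0,
) -> ObservationMatrix:
    """Per-frame mean intensities of the border RoIs, with a motion gate.

    The motion error ``e_m[k] = ||O_k - O_{k-1}||_2`` (two-norm of the
    difference of consecutive observation rows) flags non-respiratory
    movements: frames with ``e_m > motion_threshold`` are marked unusable.
    ``reinit_delay`` seconds after the latest marked frame the foreground is
    re-segmented, the RoIs re-initialized and extraction continues.  The
    threshold applies to raw intensity units and is configurable.
    """
    H, W = frames.shape
    size = roi_size if rois is None else int(rois.boxes[0, 2])
    size = min(size, H, W)
    if rois is None:
        rois = init_border_rois(otsu_foreground(frames.frames[0]), n=n_rois, size=size)
    n = len(rois)
    m = len(frames)
    O = np.zeros((m, n))
    valid = np.ones(m, dtype=bool)
    boxes = rois.boxes
    reinit_at: int | None = None
    prev_row: np.ndarray | None = None

    for k in range(m):
        frame = frames.frames[k]
        if reinit_at is not None and k >= reinit_at:
            try:
                new = init_border_rois(otsu_foreground(frame), n=n, size=size)
                boxes = new.boxes
            except ValueError:
                pass  # keep previous rois if segmentation fails
            reinit_at = None
            prev_row = None
        row = np.array([_roi_mean(frame, b) for b in boxes])[:n]
        if row.shape[0] < n:  # fewer rois after re-init: repeat the mean
            row = np.concatenate([row, np.full(n - row.shape[0], row.mean())])
        O[k] = row
        if prev_row is not None:
            e_m = float(np.linalg.norm(row - prev_row))
            if e_m > motion_threshold:
                # marked unusable; extraction resumes reinit_delay s later
                reinit_at = k + int(round(reinit_delay * frames.fps))
        if reinit_at is not None:
            valid[k] = False
        prev_row = row

    return ObservationMatrix(values=O, fs=frames.fps, source_kind="border_roi", frame_valid=valid)
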