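"""Video signal extraction: corners, KLT tracking, projection, RoIs."""

import numpy as np
import pytest
from scipy import ndimage

from breathsense.signals import RespiratorySignal
from breathsense.simulate import FrameSequence, VideoScene, render_video
from breathsense.video_extract import (
    Trajectory,
    extract_border_observations,
    extract_nose_signal,
    init_border_rois,
    otsu_foreground,
    project_trajectories,
    select_feature_points,
    track_klt,
)


def checkerboard(n=64, cell=8):
    row = (np.arange(n) // cell) % 2
    return 200.0 * np.logical_xor.outer(row, row)


class TestSelectFeaturePoints:
    def test_checkerboard_corners_at_cell_crossings(self):
        """The strongest minimum-eigenvalue responses on a checkerboard sit
        at the interior cell crossings (known geometry oracle)."""
        img = checkerboard()
        pts = select_feature_points(img, roi=(10, 10, 44, 44), n=4, min_distance=4)
        assert pts.shape[0] == 4
        for x, y in pts:
            assert min(x % 8, 8 - x % 8) <= 2
            assert min(y % 8, 8 - y % 8) <= 2

    def test_uniform_region_fails(self):
        with pytest.raises(ValueError):
            select_feature_points(np.full((64, 64), 7.0), n=5)

    def test_more_points_than_corners_warns(self):
        img = checkerboard(32, 16)  # few interior crossings
        with pytest.warns(UserWarning):
            pts = select_feature_points(img, n=50, min_distance=4)
        assert pts.shape[0] < 50


def textured_image(rng, n=64):
    return 100 + 40 * ndimage.gaussian_filter(rng.standard_normal((n, n)), 1.5)


class TestTrackKLT:
    def test_static_scene_constant_trajectories(self, rng):
        img = textured_image(rng)
        frames = FrameSequence(np.stack([img] * 5), fps=10)
        pts = select_feature_points(img, roi=(12, 12, 40, 40), n=6, min_distance=4)
        trajs = track_klt(frames, pts)
        assert len(trajs) == 6
        for t in trajs:
            assert np.allclose(t.positions, t.positions[0], atol=0.05)

    def test_pure_vertical_translation_slope(self, rng):
        """A 1 px/frame vertical shift must be recovered within 0.1 px/frame."""
        img = textured_image(rng)
        stack = np.stack([ndimage.shift(img, (k, 0), order=1, mode="nearest") for k in range(8)])
        frames = FrameSequence(stack, fps=10)
        pts = select_feature_points(img, roi=(16, 16, 32, 32), n=8, min_distance=3)
        trajs = track_klt(frames, pts)
        assert len(trajs) >= 6
        for t in trajs:
            slope = np.polyfit(np.arange(8), t.positions[:, 1], 1)[0]
            assert slope == pytest.approx(1.0, abs=0.1)
            # x stays put
            assert np.ptp(t.positions[:, 0]) < 0.3

    def test_point_leaving_frame_is_dropped(self, rng):
        img = textured_image(rng)
        stack = np.stack([ndimage.shift(img, (0, 6 * k), order=1, mode="nearest") for k in range(10)])
        frames = FrameSequence(stack, fps=10)
        pts = np.array([[60.0, 32.0]])  # near the right edge, pushed out
        trajs = track_klt(frames, pts)
        assert trajs == []

    def test_empty_point_list_rejected(self, rng):
        frames = FrameSequence(np.stack([textured_image(rng)] * 2), fps=10)
        with pytest.raises(ValueError):
            track_klt(frames, np.zeros((0, 2)))


def principal_axis_oracle(X):
    """Brute-force principal axis of a 2-D point cloud: eigenvector of the
    covariance matrix with the largest eigenvalue."""
    Xc = X - X.mean(axis=0)
    C = Xc.T @ Xc
    w, V = np.linalg.eigh(C)
    return V[:, np.argmax(w)]


class TestProjectTrajectories:
    def test_line_cloud_matches_closed_form(self):
        """Points (k, 2k) project to sqrt(5)*(k-2) along the principal axis."""
        k = np.arange(5.0)
        O = project_trajectories([Trajectory(np.stack([k, 2 * k], axis=1))], fs=10)
        expected = np.sqrt(5) * (k - 2)
        col = O.values[:, 0]
        assert np.allclose(col, expected, atol=1e-9) or np.allclose(col, -expected, atol=1e-9)

    def test_matches_bruteforce_principal_axis(self, rng):
        """Projection direction agrees with the covariance eigen-oracle
        (|cos angle| > 0.999) on 100 random anisotropic trajectories."""
        for _ in range(100):
            m = int(rng.integers(10, 60))
            direction = rng.standard_normal(2)
            direction /= np.linalg.norm(direction)
            t = rng.standard_normal(m) * 5
            X = np.outer(t, direction) + 0.1 * rng.standard_normal((m, 2))
            O = project_trajectories([Trajectory(X)], fs=10)
            axis = principal_axis_oracle(X)
            proj_oracle = (X - X.mean(0)) @ axis
            col = O.values[:, 0]
            cos = abs(col @ proj_oracle) / (np.linalg.norm(col) * np.linalg.norm(proj_oracle))
            assert cos > 0.999

    def test_rotation_invariance_up_to_sign(self, rng):
        X = np.stack([np.arange(20.0), 0.3 * np.arange(20.0) ** 1.2], axis=1)
        base = project_trajectories([Trajectory(X)], fs=10).values[:, 0]
        for theta in (0.3, 1.2, 2.9):
            R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
            rot = project_trajectories([Trajectory(X @ R.T)], fs=10).values[:, 0]
            assert min(np.max(np.abs(rot - base)), np.max(np.abs(rot + base))) < 1e-8

    def test_vertical_motion_equals_centered_y(self):
        y = np.array([0.0, 1, 2, 3, 4, 3, 2, 1])
        X = np.stack([np.full_like(y, 5.0), y], axis=1)
        col = project_trajectories([Trajectory(X)], fs=10).values[:, 0]
        cy = y - y.mean()
        assert np.allclose(col, cy, atol=1e-9) or np.allclose(col, -cy, atol=1e-9)

    def test_constant_trajectory_zero_column_with_warning(self):
        X = np.stack([np.full(6, 3.0), np.full(6, 4.0)], axis=1)
        with pytest.warns(UserWarning):
            O = project_trajectories([Trajectory(X)], fs=10)
        assert np.all(O.values[:, 0] == 0)


def between_class_variance(img, t):
    x = img.ravel()
    lo, hi = x[x <= t], x[x > t]
    if len(lo) == 0 or len(hi) == 0:
        return -1.0
    w0, w1 = len(lo) / len(x), len(hi) / len(x)
    return w0 * w1 * (lo.mean() - hi.mean()) ** 2


def exhaustive_otsu_oracle(img):
    """Exhaustive search over all 8-bit thresholds maximizing the
    between-class variance."""
    ts = range(int(img.min()), int(img.max()) + 1)
    vs = [between_class_variance(img, t) for t in ts]
    return list(ts)[int(np.argmax(vs))], max(vs)


class TestOtsuForeground:
    def test_two_level_image_recovers_blob(self):
        img = np.full((40, 40), 50.0)
        img[10:20, 5:25] = 200.0
        mask = otsu_foreground(img)
        truth = img > 125
        assert np.array_equal(mask, truth)

    def test_matches_exhaustive_threshold_oracle(self, rng):
        """On 50 random bimodal 8-bit images the implementation's mask equals
        the exhaustive between-class-variance maximizer's mask (largest
        connected component of it)."""
        from skimage.measure import label as cc_label

        for _ in range(50):
            img = np.where(
                rng.random((32, 32)) < 0.4,
                rng.normal(190, 12, (32, 32)),
                rng.normal(60, 12, (32, 32)),
            )
            img = np.clip(np.round(img), 0, 255)
            t_best, v_best = exhaustive_otsu_oracle(img)
            mask = otsu_foreground(img)
            truth = img > t_best
            lab = cc_label(truth, connectivity=2)
            counts = np.bincount(lab.ravel())
            counts[0] = 0
            truth_big = lab == np.argmax(counts)
            assert np.array_equal(mask, truth_big)

    def test_largest_component_kept(self):
        img = np.full((40, 40), 50.0)
        img[2:22, 2:22] = 200.0  # 400 px
        img[30:35, 30:35] = 200.0  # 25 px
        mask = otsu_foreground(img)
        assert mask[10, 10] and not mask[32, 32]

    def test_uniform_frame_rejected(self):
        with pytest.raises(ValueError):
            otsu_foreground(np.full((10, 10), 9.0))


class TestBorderRois:
    def test_default_count_and_size(self):
        mask = np.zeros((120, 120), dtype=bool)
        mask[20:100, 30:90] = True
        rois = init_border_rois(mask)
        assert len(rois) == 30
        assert np.all(rois.boxes[:, 2:] == 25)

    def test_centers_on_contour_at_equal_spacing(self):
        mask = np.zeros((60, 60), dtype=bool)
        mask[10:50, 10:50] = True  # 40x40 square
        rois = init_border_rois(mask, n=4, size=5)
        centers = rois.boxes[:, :2] + 2
        for cx, cy in centers:
            on_x = min(abs(cx - 10), abs(cx - 49)) <= 1
            on_y = min(abs(cy - 10), abs(cy - 49)) <= 1
            assert on_x or on_y  # every center lies on the square's border

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            init_border_rois(np.zeros((20, 20), dtype=bool))


class TestBorderObservations:
    @pytest.fixture()
    def breathing_irt(self):
        fs = 10
        t = np.arange(300) / fs
        sig = RespiratorySignal(samples=0.8 * np.sin(2 * np.pi * 0.2 * t), fs=fs)
        return sig, render_video(sig, "irt", VideoScene(bump_frame=150))

    def test_static_scene_no_frames_discarded(self):
        sig = RespiratorySignal(samples=np.zeros(30), fs=10)
        vid = render_video(sig, "irt")
        O = extract_border_observations(vid, n_rois=10, roi_size=9, motion_threshold=5.0)
        assert O.frame_valid.all()
        assert np.allclose(np.diff(O.values, axis=0), 0, atol=1e-9)

    def test_bump_marks_frame_and_reinitializes(self, breathing_irt):
        """A non-respiratory bump raises e_m above threshold; the affected
        frames up to re-initialization (2 s later) are unusable."""
        sig, vid = breathing_irt
        O = extract_border_observations(vid, n_rois=20, roi_size=11, motion_threshold=30.0)
        invalid = np.flatnonzero(~O.frame_valid)
        assert 150 in invalid
        assert invalid.min() >= 149
        assert invalid.max() <= 150 + 21
        # respiration survives the gate: valid-frame signals correlate with truth
        from breathsense.fuse import fuse_observations

        fused = fuse_observations(O, keep=5)
        ok = O.frame_valid
        r = np.corrcoef(fused.samples[ok], sig.samples[ok])[0, 1]
        assert abs(r) > 0.9

    def test_identical_rows_give_zero_motion_error(self):
        # two rois with identical consecutive means -> e_m = 0, nothing marked
        frames = FrameSequence(np.stack([np.full((30, 30), 10.0)] * 4), fps=10)
        from breathsense.video_extract import RoISet

        rois = RoISet(np.array([[2, 2, 5, 5], [20, 20, 5, 5]]))
        O = extract_border_observations(frames, rois=rois, motion_threshold=5.0)
        assert O.frame_valid.all()


class TestNoseSignal:
    def test_constant_frames_constant_signal(self):
        frames = FrameSequence(np.stack([checkerboard()] * 6), fps=10)
        pts = select_feature_points(frames.frames[0], n=5, min_distance=4)
        sig = extract_nose_signal(frames, pts, nose_roi=(28, 28, 4, 4))
        assert np.allclose(sig.samples, sig.samples[0], atol=1e-6)

    def test_roi_mean_is_arithmetic_mean(self):
        img = np.zeros((32, 32))
        img[0:2, 0:2] = [[1, 2], [3, 4]]
        img[14:18, 14:18] = 99.0  # texture so tracking has gradients
        frames = FrameSequence(np.stack([img] * 3), fps=10)
        pts = np.array([[15.0, 15.0]])
        sig = extract_nose_signal(frames, pts, nose_roi=(0, 0, 2, 2), win=9)
        assert sig.samples[0] == pytest.approx(2.5)

    def test_modulated_nose_dominant_frequency(self):
        fs = 10
        t = np.arange(300) / fs
        breath = RespiratorySignal(samples=0.5 * np.sin(2 * np.pi * 0.2 * t), fs=fs)
        vid = render_video(breath, "irt")
        pts = select_feature_points(vid.frames[0], roi=(24, 4, 16, 22), n=6, min_distance=2)
        nose = extract_nose_signal(vid, pts, nose_roi=(29, 18, 6, 4))
        mag = np.abs(np.fft.rfft(nose.samples - nose.samples.mean()))
        freqs = np.fft.rfftfreq(len(nose.samples), 1 / fs)
        assert freqs[np.argmax(mag)] == pytest.approx(0.2, abs=freqs[1])
        # antiphase: inspiration cools the nostrils
        assert np.corrcoef(nose.samples, breath.samples)[0, 1] < -0.9
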