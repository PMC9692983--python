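"""Feature extraction, artifact rules and feature fusion."""

import numpy as np
import pytest

from breathsense.features import (
    FeatureTrack,
    artifact_correct,
    cwt_ridge_features,
    fuse_features,
    peak_features,
    smooth,
)
from breathsense.signals import RespiratorySignal

FS = 10.0


def sig(samples):
    return RespiratorySignal(samples=np.asarray(samples, dtype=float), fs=FS)


def sine(rr_bpm, re=1.0, n=600):
    t = np.arange(n) / FS
    return sig(re * np.sin(2 * np.pi * rr_bpm / 60.0 * t))


class TestSmooth:
    def test_polynomial_reproduced_in_interior(self):
        t = np.linspace(0, 1, 200)
        x = 3 * t**3 - t**2 + 0.5
        out = smooth(sig(x), window=15, order=3)
        assert np.allclose(out.samples[10:-10], x[10:-10], atol=1e-9)

    def test_white_noise_variance_reduced(self, rng):
        x = rng.standard_normal(1000)
        out = smooth(sig(x))
        assert out.samples.var() < 0.6 * x.var()

    def test_window_one_is_identity(self):
        x = np.sin(np.arange(100) * 0.3)
        out = smooth(sig(x), window=1)
        assert np.array_equal(out.samples, x)

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValueError):
            smooth(sig(np.zeros(5)), window=11)


class TestPeakFeatures:
    def test_clean_eupnea_rate_everywhere(self):
        F = peak_features(sine(12))
        assert np.all(np.abs(F.rr[F.valid] - 12) < 0.2)
        # valid only from the second peak onward
        first_two = np.flatnonzero(F.valid)[0]
        assert first_two >= int(0.8 * (60 / 12) * FS)

    def test_amplitude_is_half_prominence(self):
        F = peak_features(sine(12, re=1.0))
        # unit sine: prominence 2, amplitude 1
        assert np.median(F.amp[F.valid]) == pytest.approx(1.0, abs=0.02)

    def test_flat_signal_fully_invalid(self):
        F = peak_features(sig(np.zeros(300)))
        assert not F.valid.any()
        assert np.all(F.rr == 0)

    def test_single_peak_invalid(self):
        x = np.zeros(300)
        x[100:110] = np.hanning(10)
        F = peak_features(sig(x))
        assert not F.valid.any()


class TestCwtRidge:
    def test_unit_sine_rate_and_amplitude(self):
        F = cwt_ridge_features(sine(15))
        mid = slice(100, 500)
        assert np.median(F.rr[mid]) == pytest.approx(15, abs=0.5)
        assert np.median(F.amp[mid]) == pytest.approx(1.0, abs=0.05)

    def test_chirp_rate_monotonically_increasing(self):
        """A 10 -> 30 breaths/min linear chirp yields a (noisily) increasing
        ridge: Spearman correlation with time > 0.95."""
        from scipy.stats import spearmanr

        n = 1200
        t = np.arange(n) / FS
        f0, f1 = 10 / 60, 30 / 60
        phase = 2 * np.pi * (f0 * t + (f1 - f0) / (2 * t[-1]) * t**2)
        F = cwt_ridge_features(sig(np.sin(phase)))
        mid = slice(100, n - 100)
        rho = spearmanr(np.arange(n)[mid], F.rr[mid]).statistic
        assert rho > 0.95

    def test_zero_signal_zero_amplitude_invalid(self):
        F = cwt_ridge_features(sig(np.zeros(400)))
        assert np.all(F.amp == 0)
        assert not F.valid.any()


def clean_track(n=900, rr=12.0, amp=1.0):
    return FeatureTrack(
        rr=np.full(n, rr), amp=np.full(n, amp), valid=np.ones(n, dtype=bool), fs=FS
    )


class TestArtifactCorrect:
    def test_clean_track_unchanged(self):
        F = clean_track()
        out = artifact_correct(F)
        assert np.array_equal(out.rr, F.rr)
        assert out.valid.all()

    def test_double_jump_within_ten_seconds_invalidated(self):
        """Steps of +6 and -6 breaths/min five seconds apart mark the
        enclosed section as unusable (then the short gap is filled)."""
        F = clean_track()
        F.rr[500:550] = 18.0  # +6 at 50.0 s, -6 at 55.0 s
        out = artifact_correct(F)
        assert out.filled[510:545].all()
        assert np.all(out.rr[510:545] == 12.0)  # filled from the last valid values

    def test_isolated_jump_survives(self):
        F = clean_track()
        F.rr[500:] = 18.0  # one step only
        out = artifact_correct(F)
        assert out.valid.all()
        assert not out.filled.any()

    def test_low_amplitude_kept_only_if_stable(self):
        """A 70 s amp=0.03 span with rates 9-11 around median 10 satisfies
        the keep conditions (>= 5 periods, median > 5, spread 0.2 < 0.45);
        an erratic span of the same length is invalidated."""
        F = clean_track(n=2000, rr=10.0)
        F.amp[600:1300] = 0.03
        F.rr[600:1300] = np.linspace(9, 11, 700)
        out = artifact_correct(F)
        assert out.valid[600:1300].all()
        assert not out.filled[600:1300].any()

        G = clean_track(n=2000, rr=10.0)
        G.amp[600:1300] = 0.03
        G.rr[600:1300] = 10.0 + 3.0 * np.sin(np.arange(700) / 25.0)  # spread 6/10 = 0.6
        out2 = artifact_correct(G)
        assert not out2.valid[600:1300].any()
        assert np.all(out2.rr[600:1300] == 0)

    def test_short_valid_islands_removed(self):
        n = 600
        F = FeatureTrack(
            rr=np.full(n, 12.0), amp=np.ones(n), valid=np.zeros(n, dtype=bool), fs=FS
        )
        F.valid[100:150] = True  # 5 s island
        F.valid[300:500] = True  # 20 s island
        out = artifact_correct(F)
        assert not out.valid[100:150].any() or out.filled[100:150].all()
        assert out.valid[300:500].all()

    def test_long_gap_zeroed_short_gap_filled(self):
        F = clean_track(n=1200)
        F.valid[400:450] = False  # 5 s gap -> filled
        F.valid[700:900] = False  # 20 s gap -> zeroed
        out = artifact_correct(F)
        assert out.valid[400:450].all() and out.filled[400:450].all()
        assert np.all(out.rr[400:450] == 12.0)
        assert not out.valid[700:900].any()
        assert np.all(out.rr[700:900] == 0)

    def test_idempotent_on_random_tracks(self):
        """Applying the correction twice equals applying it once, across 50
        randomized rate/amplitude tracks with jumps, dropouts and
        low-amplitude spans."""
        for trial in range(50):
            r = np.random.default_rng(7000 + trial)
            n = 800
            rr = 12 + np.cumsum(r.normal(0, 0.8, n))
            rr = np.clip(np.abs(rr), 0, 60)
            amp = np.abs(1 + np.cumsum(r.normal(0, 0.02, n)))
            amp[r.random(n) < 0.05] = 0.03
            valid = r.random(n) > 0.1
            F = FeatureTrack(rr=rr, amp=amp, valid=valid, fs=FS)
            once = artifact_correct(F)
            twice = artifact_correct(once)
            assert np.array_equal(once.valid, twice.valid)
            assert np.array_equal(once.filled, twice.filled)
            assert np.allclose(once.rr, twice.rr)
            assert np.allclose(once.amp, twice.amp)


class TestFuseFeatures:
    def test_identical_inputs_reproduced(self):
        Fp = artifact_correct(clean_track())
        Fs = artifact_correct(clean_track())
        M = fuse_features(Fp, Fs)
        assert np.allclose(M.rr[M.valid], 12.0)
        assert np.allclose(M.amp[M.valid], 1.0)
        # constant track: moving variance ~ 0
        assert np.all(M.rr_var < 1e-9)

    def test_stable_higher_rate_source_wins(self):
        """When the medians disagree, the source without recent rate jumps
        and with the higher mean rate supplies the segment."""
        n = 900
        Fp = clean_track(n, rr=12.0)
        # peak track glitches: rate excursion in the middle
        Fp.rr[400:500] = 30.0
        Fs = clean_track(n, rr=20.0)
        M = fuse_features(artifact_correct(Fp), artifact_correct(Fs))
        # inside the glitch window the spectral track (stable, higher mean
        # in its segment) or the fill wins; rate never shows the glitch mean
        assert abs(np.median(M.rr[420:480]) - 30.0) > 5

    def test_both_sources_dead_gap_zeroed(self):
        n = 900
        Fp = clean_track(n)
        Fs = clean_track(n)
        Fp.valid[300:380] = False
        Fs.valid[300:380] = False
        Fp.filled = None
        M = fuse_features(FeatureTrack(rr=Fp.rr, amp=Fp.amp, valid=Fp.valid, fs=FS), Fs)
        # 8 s gap: longer than the 5 s fill limit -> zero and invalid
        assert not M.valid[320:370].any()
        assert np.all(M.rr[320:370] == 0)

    def test_no_nans_and_invalid_is_zero(self, rng):
        n = 900
        Fp = clean_track(n)
        Fp.rr += rng.normal(0, 0.1, n)
        Fp.valid[100:300] = False
        Fs = clean_track(n, rr=12.5)
        M = fuse_features(Fp, Fs)
        for arr in (M.rr, M.amp, M.rr_var, M.amp_var):
            assert np.all(np.isfinite(arr))
            assert np.all(arr[~M.valid] == 0)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fuse_features(clean_track(100), clean_track(101))

    def test_variance_orders_complex_above_constant(self):
        """30 s moving rate variance: a Biot-like intermittent track far
        exceeds a constant eupnea track."""
        from breathsense.protocol import PatternSpec, synth_segment
        from breathsense.pipeline import segment_feature_vector
        from breathsense.dataset import LabelledSegment

        biot = synth_segment(PatternSpec("biot", 15, 1, 80, "biot_intermittent", (12, 25)), FS)
        eup = synth_segment(PatternSpec("eupnea", 12, 1, 80, rr_range=(12, 18)), FS)
        v_biot = segment_feature_vector(LabelledSegment("biot", biot, FS))
        v_eup = segment_feature_vector(LabelledSegment("eupnea", eup, FS))
        assert v_biot.rr_var_med > 10 * max(v_eup.rr_var_med, 1e-6)
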