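import numpy as np
import pytest

from bitescape import (
    StrikeTrack,
    calibrate_track,
    detect_strike_window,
    gape_series,
    jaw_angle_series,
    ms_per_frame,
    protrusion_series,
    smooth_track,
    summarize_strike,
)
from bitescape.errors import DegenerateWindowError, ValidationError
from bitescape.io import DENTARY, PREMAX, PREOPERCLE, PUPIL, QUADRATE


def mm_track(coords, frame_rate=1100.0, **kw):
    coords = np.asarray(coords, dtype=float)
    defaults = dict(
        strike_id="s",
        individual_id="f",
        species="generalist",
        frame_rate=frame_rate,
        coords=coords,
        confidence=np.ones(coords.shape[:2]),
        units="mm",
    )
    defaults.update(kw)
    return StrikeTrack(**defaults)


def test_ms_per_frame_at_1100_fps():
    assert ms_per_frame(1100.0) == pytest.approx(0.909, abs=5e-4)


class TestSeries:
    def test_gape_three_four_five(self):
        coords = np.zeros((2, 5, 2))
        coords[:, PREMAX] = (0, 0)
        coords[:, DENTARY] = (3, 4)
        np.testing.assert_allclose(gape_series(mm_track(coords)), 5.0)

    def test_coincident_landmarks_zero(self):
        coords = np.zeros((2, 5, 2))
        assert gape_series(mm_track(coords))[0] == 0.0
        assert protrusion_series(mm_track(coords))[0] == 0.0

    def test_protrusion_axis_aligned(self):
        coords = np.zeros((2, 5, 2))
        coords[:, PUPIL] = (0, 0)
        coords[:, PREMAX] = (0, 6.5)
        np.testing.assert_allclose(protrusion_series(mm_track(coords)), 6.5)

    def test_jaw_angle_orthogonal_and_collinear(self):
        coords = np.zeros((2, 5, 2))
        coords[:, QUADRATE] = (0, 0)
        coords[0, DENTARY] = (1, 0)
        coords[0, PREOPERCLE] = (0, 1)
        coords[1, DENTARY] = (1, 0)
        coords[1, PREOPERCLE] = (-2, 0)
        ja = jaw_angle_series(mm_track(coords))
        np.testing.assert_allclose(ja, [90.0, 180.0], atol=1e-9)

    def test_zero_length_ray_is_missing(self):
        coords = np.zeros((2, 5, 2))  # dentary coincides with quadrate
        coords[:, PREOPERCLE] = (1, 0)
        assert np.isnan(jaw_angle_series(mm_track(coords))).all()

    def test_series_match_brute_force_oracles(self, rng):
        coords = rng.uniform(-50, 50, size=(40, 5, 2))
        track = mm_track(coords)
        gape = gape_series(track)
        prot = protrusion_series(track)
        ja = jaw_angle_series(track)
        for t in range(40):
            assert gape[t] == pytest.approx(
                float(np.hypot(*(coords[t, PREMAX] - coords[t, DENTARY]))), abs=1e-9
            )
            assert prot[t] == pytest.approx(
                float(np.hypot(*(coords[t, PUPIL] - coords[t, PREMAX]))), abs=1e-9
            )
            u = coords[t, DENTARY] - coords[t, QUADRATE]
            v = coords[t, PREOPERCLE] - coords[t, QUADRATE]
            expected = np.degrees(
                np.arccos(
                    np.clip(
                        u @ v / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1
                    )
                )
            )
            assert ja[t] == pytest.approx(expected, abs=1e-9)

    def test_requires_calibrated_track(self, rng):
        coords = rng.uniform(0, 100, (5, 5, 2))
        track = mm_track(coords)
        track.units = "px"
        with pytest.raises(ValidationError):
            gape_series(track)


class TestRigidMotionInvariance:
    def test_all_variables_invariant(self, noiseless_dataset, scale):
        track = calibrate_track(noiseless_dataset.tracks[0], scale)
        base = summarize_strike(track)
        theta = 0.83
        R = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        moved = track.copy()
        moved.coords = track.coords @ R.T + np.array([12.0, -7.0])
        out = summarize_strike(moved)
        for attr in (
            "peak_gape_mm",
            "peak_protrusion_mm",
            "min_jaw_angle_deg",
            "ttpg_ms",
            "ram_speed_m_s",
        ):
            assert getattr(out, attr) == pytest.approx(getattr(base, attr), abs=1e-9)


class TestStrikeWindow:
    def _approach_track(self, n=60, peak_at=49):
        coords = np.zeros((n, 5, 2))
        x = np.concatenate(
            [np.linspace(0, 10, peak_at + 1), np.linspace(10, 8, n - peak_at - 1)]
        )
        coords[:, PUPIL, 0] = x
        coords[:, PREMAX, 0] = x + 1
        coords[:, DENTARY, 0] = x + 1
        coords[:, DENTARY, 1] = np.linspace(0.2, 2.0, n)
        coords[:, QUADRATE] = np.column_stack([x - 2, np.full(n, 2.0)])
        coords[:, PREOPERCLE] = coords[:, QUADRATE] + (-1.5, 1.5)
        return mm_track(coords)

    def test_impact_at_max_displacement(self):
        w = detect_strike_window(self._approach_track())
        assert (w.start_frame, w.impact_frame) == (0, 49)

    def test_logistic_approach_impact_in_plateau(self):
        n = 100
        t = np.arange(n)
        x = 10 / (1 + np.exp(-0.15 * (t - 55)))
        coords = np.zeros((n, 5, 2))
        coords[:, PUPIL, 0] = x
        track = mm_track(coords)
        w = detect_strike_window(track)
        # strictly increasing logistic: maximum at the last frame
        assert w.impact_frame == n - 1

    def test_stationary_track_degenerate(self):
        coords = np.ones((10, 5, 2))
        with pytest.raises(DegenerateWindowError):
            detect_strike_window(mm_track(coords))

    def test_unobserved_pupil_rejected(self):
        coords = np.ones((10, 5, 2))
        conf = np.ones((10, 5))
        conf[:, PUPIL] = 0.0
        with pytest.raises(DegenerateWindowError):
            detect_strike_window(mm_track(coords, confidence=conf))


class TestSummarize:
    def _gape_profile_track(self, frame_rate=1100.0):
        """Gape crosses 20% of peak at frame 10 and peaks at frame 14."""
        n = 30
        coords = np.zeros((n, 5, 2))
        gape = np.full(n, 0.5)
        gape[10:15] = np.array([1.0, 2.0, 3.5, 4.5, 5.0])
        gape[15:] = 4.0
        coords[:, PUPIL, 0] = np.linspace(0, 10, n)
        coords[:, PREMAX, 0] = coords[:, PUPIL, 0] + 1.0
        coords[:, DENTARY, 0] = coords[:, PREMAX, 0]
        coords[:, DENTARY, 1] = gape
        coords[:, QUADRATE] = coords[:, PUPIL] + (-2, 2)
        coords[:, PREOPERCLE] = coords[:, QUADRATE] + (-1, 1)
        return mm_track(coords, frame_rate=frame_rate)

    def test_ttpg_four_frames_at_1100fps(self):
        s = summarize_strike(self._gape_profile_track())
        assert s.onset_frame == 10 and s.peak_gape_frame == 14
        assert s.ttpg_ms == pytest.approx(4 * 0.909, abs=4e-3)

    def test_ram_speed_is_mm_per_ms(self):
        s = summarize_strike(self._gape_profile_track())
        # pupil moves 10/29 mm per frame; over 4 frames and 4 * (10/11) ms
        expected = (4 * 10 / 29) / (4 * 1000 / 1100)
        assert s.ram_speed_m_s == pytest.approx(expected, rel=1e-9)

    def test_halving_frame_rate_doubles_ttpg_halves_ram(self):
        fast = summarize_strike(self._gape_profile_track(frame_rate=1100.0))
        slow = summarize_strike(self._gape_profile_track(frame_rate=550.0))
        assert slow.ttpg_ms == pytest.approx(2 * fast.ttpg_ms, rel=1e-12)
        assert slow.ram_speed_m_s == pytest.approx(fast.ram_speed_m_s / 2, rel=1e-12)

    def test_onset_gape_between_20pct_and_peak(self, noiseless_dataset, scale):
        for track in noiseless_dataset.tracks[:6]:
            cal = calibrate_track(track, scale)
            s = summarize_strike(cal)
            gape = gape_series(cal)
            assert s.peak_gape_mm >= gape[s.onset_frame] >= 0.2 * s.peak_gape_mm

    def test_degenerate_ttpg_warns_and_rs_missing(self):
        n = 30
        coords = np.zeros((n, 5, 2))
        coords[:, PUPIL, 0] = np.linspace(0, 5, n)
        coords[:, PREMAX, 0] = coords[:, PUPIL, 0] + 1
        coords[:, DENTARY, 0] = coords[:, PREMAX, 0]
        # gape jumps straight to its maximum: onset == peak frame
        coords[:, DENTARY, 1] = np.r_[np.zeros(5), 5.0, np.full(n - 6, 0.4)]
        coords[:, QUADRATE] = coords[:, PUPIL] + (-2, 2)
        coords[:, PREOPERCLE] = coords[:, QUADRATE] + (-1, 1)
        with pytest.warns(UserWarning, match="ram speed"):
            s = summarize_strike(mm_track(coords))
        assert s.ttpg_ms == 0.0 and np.isnan(s.ram_speed_m_s)


class TestSmoothing:
    def test_window_validation(self, noiseless_dataset, scale):
        track = calibrate_track(noiseless_dataset.tracks[0], scale)
        with pytest.raises(ValidationError):
            smooth_track(track, window=4)

    def test_reduces_jitter(self, rng):
        n = 200
        coords = np.zeros((n, 5, 2))
        coords[:, PUPIL, 0] = np.linspace(0, 10, n)
        clean = mm_track(coords.copy())
        noisy = mm_track(coords + rng.normal(0, 0.5, coords.shape))
        sm = smooth_track(noisy, window=21)
        rough_err = np.nanstd(noisy.coords[:, PUPIL, 1])
        smooth_err = np.nanstd(
            sm.coords[20:-20, PUPIL, 1] - clean.coords[20:-20, PUPIL, 1]
        )
        assert smooth_err < 0.4 * rough_err
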