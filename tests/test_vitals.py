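"""ROI construction, temperature readout, cpTD, PPGI and HR estimation."""

import numpy as np
import pytest

from neophantom import (
    HRTrace,
    KeypointSet,
    PPGISignal,
    ROI,
    RGBRenderer,
    compute_cptd,
    detect_peaks,
    estimate_hr,
    extract_ppgi,
    generate_ppg,
    roi_temperature,
    rois_from_keypoints,
)
from neophantom.vitals import hr_quantization_bound


def make_kps(**conf_overrides):
    """Upright-subject skeleton on a 200x300 frame."""
    pts = {
        "nose": (100.0, 40.0, 1.0),
        "neck": (100.0, 70.0, 1.0),
        "left_shoulder": (70.0, 80.0, 1.0),
        "right_shoulder": (130.0, 80.0, 1.0),
        "left_elbow": (55.0, 120.0, 1.0),
        "right_elbow": (145.0, 120.0, 1.0),
        "left_wrist": (45.0, 160.0, 1.0),
        "right_wrist": (155.0, 160.0, 1.0),
        "left_hip": (80.0, 170.0, 1.0),
        "right_hip": (120.0, 170.0, 1.0),
        "left_knee": (75.0, 220.0, 1.0),
        "right_knee": (125.0, 220.0, 1.0),
        "left_ankle": (70.0, 270.0, 1.0),
        "right_ankle": (130.0, 270.0, 1.0),
    }
    for name, conf in conf_overrides.items():
        x, y, _ = pts[name]
        pts[name] = (x, y, conf)
    return KeypointSet(pts)


class TestROIs:
    def test_six_rois_inside_frame(self):
        rois = rois_from_keypoints(make_kps(), frame_size=(200, 300))
        assert set(rois) == {"forehead", "chest", "left_hand", "right_hand",
                             "left_foot", "right_foot"}
        for roi in rois.values():
            assert roi.x >= 0 and roi.y >= 0
            assert roi.x + roi.w <= 200 and roi.y + roi.h <= 300

    def test_roi_side_scales_with_torso(self):
        """Side = scale_fraction * neck-to-mid-hip distance."""
        rois = rois_from_keypoints(make_kps(), frame_size=(200, 300), scale_fraction=0.4)
        # neck (100,70) to mid-hip (100,170) -> 100 px, side 40
        assert rois["chest"].w == 40

    def test_missing_wrist_drops_hand_roi(self):
        rois = rois_from_keypoints(make_kps(left_wrist=0.0), frame_size=(200, 300))
        assert "left_hand" not in rois
        assert len(rois) == 5

    def test_scale_equivariance(self):
        """Doubling all coordinates doubles the ROI rectangles."""
        kps = make_kps()
        doubled = KeypointSet({k: (2 * x, 2 * y, c) for k, (x, y, c) in kps.points.items()})
        r1 = rois_from_keypoints(kps, frame_size=(200, 300))
        r2 = rois_from_keypoints(doubled, frame_size=(400, 600))
        for name in r1:
            assert r2[name].w == pytest.approx(2 * r1[name].w, abs=1)
            assert r2[name].x == pytest.approx(2 * r1[name].x, abs=1)

    def test_missing_torso_rejected(self):
        with pytest.raises(ValueError, match="torso"):
            rois_from_keypoints(make_kps(neck=0.0), frame_size=(200, 300))

    def test_forehead_offset_away_from_body(self):
        rois = rois_from_keypoints(make_kps(), frame_size=(200, 300))
        # neck->nose points up (y decreasing): forehead center above the nose
        assert rois["forehead"].y + rois["forehead"].h / 2 < 40.0


class TestROITemperature:
    def test_uniform_field(self):
        grid = np.full((50, 50), 34.0)
        assert roi_temperature(grid, ROI("chest", 10, 10, 20, 20)) == pytest.approx(34.0)

    def test_half_half_mean(self):
        grid = np.full((40, 40), 30.0)
        grid[:, 20:] = 40.0
        assert roi_temperature(grid, ROI("chest", 10, 0, 20, 40)) == pytest.approx(35.0)

    def test_invalid_region_unavailable(self):
        grid = np.full((30, 30), np.nan)
        assert roi_temperature(grid, ROI("left_hand", 5, 5, 10, 10)) is None

    def test_partial_validity_uses_valid_pixels_only(self):
        grid = np.full((30, 30), 33.0)
        grid[:15, :] = np.nan
        assert roi_temperature(grid, ROI("chest", 0, 0, 30, 30)) == pytest.approx(33.0)


class TestCpTD:
    def test_worked_example(self):
        temps = {"chest": 37.0, "left_hand": 33.0, "right_hand": 33.0,
                 "left_foot": 33.0, "right_foot": 33.0}
        assert compute_cptd(temps) == pytest.approx(4.0)

    def test_zero_when_equal(self):
        temps = {"chest": 36.0, "left_hand": 36.0, "right_foot": 36.0}
        assert compute_cptd(temps) == pytest.approx(0.0)

    def test_partial_peripherals(self):
        temps = {"chest": 36.0, "left_hand": 34.0, "right_hand": 32.0}
        assert compute_cptd(temps) == pytest.approx(3.0)

    def test_missing_chest_unavailable(self):
        assert compute_cptd({"left_hand": 33.0}) is None

    def test_no_peripherals_unavailable(self):
        assert compute_cptd({"chest": 37.0, "forehead": 36.0}) is None

    def test_monotone_sign_convention(self):
        """Warming the chest or cooling a periphery raises cpTD."""
        base = {"chest": 36.0, "left_hand": 34.0, "right_foot": 34.0}
        c0 = compute_cptd(base)
        assert compute_cptd({**base, "chest": 37.0}) > c0
        assert compute_cptd({**base, "left_hand": 33.0}) > c0


class TestPPGI:
    def test_constant_frames_constant_signal(self, small_layout):
        renderer = RGBRenderer(small_layout, baseline=0.5, modulation_depth=0.0)
        rois = rois_from_keypoints(small_layout.keypoints, small_layout.canvas_size)
        sig = extract_ppgi(renderer.frames(np.zeros(10)), rois["forehead"])
        assert np.ptp(sig.values) == 0.0
        assert sig.values.size == 10

    def test_render_extract_round_trip(self, small_layout):
        """Forehead red mean reproduces baseline + depth * ppg exactly."""
        trace = HRTrace(times=np.array([0.0]), values=np.array([120.0]))
        ppg = generate_ppg(trace, duration=5.0, sample_rate=30.0)
        renderer = RGBRenderer(small_layout, baseline=0.6, modulation_depth=0.2)
        rois = rois_from_keypoints(small_layout.keypoints, small_layout.canvas_size)
        sig = extract_ppgi(renderer.frames(ppg.samples), rois["forehead"])
        np.testing.assert_allclose(sig.values, 0.6 + 0.2 * ppg.samples, atol=1e-6)

    def test_single_frame_signal(self, small_layout):
        renderer = RGBRenderer(small_layout)
        rois = rois_from_keypoints(small_layout.keypoints, small_layout.canvas_size)
        sig = extract_ppgi([renderer.render(0.3, 0.0)], rois["forehead"])
        assert sig.values.size == 1

    def test_empty_sequence_rejected(self, small_layout):
        rois = rois_from_keypoints(small_layout.keypoints, small_layout.canvas_size)
        with pytest.raises(ValueError):
            extract_ppgi([], rois["forehead"])


def pulse_signal(rate_bpm, duration=10.0, fs=30.0, secondary=0.3):
    from neophantom import PulseShape

    trace = HRTrace(times=np.array([0.0]), values=np.array([float(rate_bpm)]))
    ppg = generate_ppg(
        trace, duration=duration, sample_rate=fs,
        pulse_shape=PulseShape(secondary_amplitude=secondary),
    )
    return PPGISignal(times=ppg.times, values=ppg.samples), ppg


class TestPeakDetection:
    def test_beat_count_120bpm(self):
        sig, ppg = pulse_signal(120, duration=10.0)
        peaks = detect_peaks(sig)
        assert len(peaks) == 20

    def test_secondary_bumps_rejected(self):
        """30%-amplitude diastolic maxima are dropped by the prominence rule.

        Oracle: brute-force local-maxima scan finds roughly two maxima per
        beat; the detector keeps exactly one."""
        sig, ppg = pulse_signal(90, duration=10.0, fs=60.0, secondary=0.3)
        v = sig.values
        all_maxima = np.sum((v[1:-1] > v[:-2]) & (v[1:-1] >= v[2:]))
        # beats whose systolic peak (0.2 of a period after onset) is rendered
        n_rendered = int(np.sum(ppg.beat_times + 0.2 * 60 / 90 <= sig.times[-1]))
        assert all_maxima >= 2 * n_rendered - 2  # both peaks visible in the raw signal
        peaks = detect_peaks(sig)
        assert len(peaks) == n_rendered

    def test_flat_signal_no_peaks(self):
        sig = PPGISignal(times=np.arange(10) / 30.0, values=np.full(10, 0.5))
        assert detect_peaks(sig).size == 0

    def test_too_short_rejected(self):
        sig = PPGISignal(times=np.array([0.0, 0.1]), values=np.array([0.1, 0.2]))
        with pytest.raises(ValueError):
            detect_peaks(sig)


class TestHREstimate:
    def test_uniform_intervals(self):
        peaks = np.arange(0, 10.0, 0.5)
        hr, n = estimate_hr(peaks, now=10.0)
        assert hr == pytest.approx(120.0)
        assert n == len(peaks) - 1  # every interval ends inside (0, 10]

    def test_spurious_short_interval_filtered(self):
        """A 0.05 s interval implies 1200 bpm > 300 and is discarded."""
        peaks = np.sort(np.concatenate([np.arange(0, 10.0, 0.5), [5.05]]))
        hr, _ = estimate_hr(peaks, now=10.0)
        # remaining intervals: the 0.45 and the 0.5s ones; mean stays near 120
        assert hr == pytest.approx(120.0, abs=3.0)

    def test_no_peaks_undefined(self):
        hr, n = estimate_hr(np.array([]), now=10.0)
        assert hr is None and n == 0

    def test_stale_peaks_outside_window_undefined(self):
        peaks = np.arange(0, 5.0, 0.5)
        hr, n = estimate_hr(peaks, now=20.0)
        assert hr is None

    def test_estimate_always_in_plausible_band(self):
        """Whenever defined, the estimate lies in [36, 300] bpm."""
        rng = np.random.default_rng(4)
        for _ in range(50):
            peaks = np.sort(rng.uniform(0, 12.0, size=rng.integers(2, 40)))
            hr, _ = estimate_hr(peaks, now=12.0)
            if hr is not None:
                assert 36.0 <= hr <= 300.0


class TestEndToEndHR:
    @pytest.mark.parametrize("rate", [80, 140, 180, 240])
    def test_constant_rate_recovered_within_quantization(self, small_layout, rate):
        """Noise-free rendered video at 30 fps yields the set rate to <=0.5 bpm."""
        trace = HRTrace(times=np.array([0.0]), values=np.array([float(rate)]))
        ppg = generate_ppg(trace, duration=30.0, sample_rate=30.0)
        renderer = RGBRenderer(small_layout, baseline=0.6, modulation_depth=0.2)
        rois = rois_from_keypoints(small_layout.keypoints, small_layout.canvas_size)
        sig = extract_ppgi(renderer.frames(ppg.samples), rois["forehead"])
        peaks = detect_peaks(sig)
        estimates = []
        for now in np.arange(15.0, 30.0, 1.0):
            hr, n = estimate_hr(peaks, now=now)
            assert hr is not None
            estimates.append((hr, n))
        for hr, n in estimates:
            assert abs(hr - rate) <= max(hr_quantization_bound(rate, 30.0, n), 0.5)
            assert round(hr) == rate
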