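"""Generator contracts: determinism, declared truth, validity ranges."""

import numpy as np
import pytest

from hypometrics import perfusion, synthio
from hypometrics.types import InvalidArgumentError


class TestSwimVideo:
    def test_zero_activity_is_static(self):
        video, truth = synthio.gen_swim_video(activity_level=0.0, n_frames=8, seed=3)
        assert all(np.array_equal(video.frames[i], video.frames[0]) for i in range(8))
        assert truth.params["activity_level"] == 0.0

    def test_interframe_difference_grows_with_activity(self):
        v_half, _ = synthio.gen_swim_video(activity_level=0.5, n_frames=30, seed=7)
        v_full, _ = synthio.gen_swim_video(activity_level=1.0, n_frames=30, seed=7)
        d_half = np.abs(np.diff(v_half.frames.astype(float), axis=0)).sum()
        d_full = np.abs(np.diff(v_full.frames.astype(float), axis=0)).sum()
        assert d_full > d_half

    def test_deterministic(self):
        a, _ = synthio.gen_swim_video(activity_level=0.4, n_frames=12, seed=42)
        b, _ = synthio.gen_swim_video(activity_level=0.4, n_frames=12, seed=42)
        assert np.array_equal(a.frames, b.frames)

    def test_rejects_bad_dimensions(self):
        with pytest.raises(InvalidArgumentError):
            synthio.gen_swim_video(n_frames=1)
        with pytest.raises(InvalidArgumentError):
            synthio.gen_swim_video(n_organisms=0)

    def test_pixels_within_dynamic_range(self):
        video, _ = synthio.gen_swim_video(activity_level=0.8, n_frames=10, seed=5)
        lo, hi = video.dynamic_range
        assert video.frames.min() >= lo and video.frames.max() <= hi


class TestHeartVideo:
    def test_maxima_count_matches_bpm(self, heart_video_60):
        from scipy.signal import argrelmax

        video, truth = heart_video_60
        roi_cy, roi_cx, roi_r = truth.params["roi"]
        yy, xx = np.mgrid[0 : video.frames.shape[1], 0 : video.frames.shape[2]]
        mask = (yy - roi_cy) ** 2 + (xx - roi_cx) ** 2 <= roi_r**2
        trace = video.frames[:, mask].mean(axis=1)
        assert len(argrelmax(trace)[0]) == 10

    def test_noise_free_trace_periodic(self, heart_video_60):
        video, _ = heart_video_60
        trace = video.frames.mean(axis=(1, 2))
        # period 1 s = 10 frames
        assert np.allclose(trace[:-10], trace[10:], atol=1.0)

    def test_truth_lists_all_onsets(self):
        _, truth = synthio.gen_heart_video(bpm=120.0, duration=60.0, seed=0)
        assert len(truth.params["beat_onsets"]) == 120

    def test_nyquist_violation_rejected(self):
        with pytest.raises(InvalidArgumentError):
            synthio.gen_heart_video(bpm=300.0, frame_interval=0.1)


class TestO2Trace:
    def test_noise_free_is_exactly_linear(self):
        trace, _ = synthio.gen_o2_trace(baseline_rate=2.0, fold_change=1.0, noise_sd=0.0)
        slopes = np.diff(trace.values) / np.diff(trace.times)
        assert np.allclose(slopes, -2.0)

    def test_post_onset_slope(self):
        trace, truth = synthio.gen_o2_trace(
            baseline_rate=2.0, fold_change=1 / 3, onset_time=30.0, noise_sd=0.0
        )
        assert truth.params["post_rate"] == pytest.approx(2 / 3)
        t, v = trace.times, trace.values
        post = t >= 30.0
        slopes = np.diff(v[post]) / np.diff(t[post])
        assert np.allclose(slopes, -2 / 3)

    def test_leak_segment_has_positive_slope(self):
        from scipy.stats import linregress

        trace, truth = synthio.gen_o2_trace(baseline_rate=2.0, inject_leak=True, noise_sd=0.0)
        t0, t1 = truth.params["leak_window"]
        sel = (trace.times >= t0) & (trace.times <= t1)
        assert linregress(trace.times[sel], trace.values[sel]).slope > 0

    def test_duration_validation(self):
        with pytest.raises(InvalidArgumentError):
            synthio.gen_o2_trace(duration=0.0)


class TestPerfusionRecords:
    def test_zero_mvo2_means_identical_samples(self):
        records, _ = synthio.gen_perfusion_records(true_mvo2=0.0, n_timepoints=2)
        rec = records[0]
        assert rec.arterial.po2 == pytest.approx(rec.venous.po2)
        assert rec.arterial.so2 == pytest.approx(rec.venous.so2)

    def test_roundtrip_exact(self):
        records, _ = synthio.gen_perfusion_records(true_mvo2=2.4, n_timepoints=1)
        res = perfusion.compute_mvo2(records[0])
        assert res.value == pytest.approx(2.4, rel=1e-9)

    def test_doubling_flow_halves_content_difference(self):
        _, t1 = synthio.gen_perfusion_records(true_mvo2=2.4, q=300.0, n_timepoints=1)
        _, t2 = synthio.gen_perfusion_records(true_mvo2=2.4, q=600.0, n_timepoints=1)
        d1 = t1.params["content_a"] - t1.params["content_v"]
        d2 = t2.params["content_a"] - t2.params["content_v"]
        assert d2 == pytest.approx(d1 / 2.0, rel=1e-12)

    def test_infeasible_combination_rejected(self):
        with pytest.raises(InvalidArgumentError):
            synthio.gen_perfusion_records(true_mvo2=50.0, q=100.0, weight=500.0)


class TestCellImages:
    def test_unit_ratio_makes_channels_identical(self):
        imgset, truth = synthio.gen_cell_images(
            n_cells=4, true_ratios=[1.0] * 4, noise_sd=0.0, image_size=160, seed=2
        )
        ch = imgset.channels[0]
        assert np.array_equal(ch["YFP"], ch["CFP"])

    def test_connected_component_count(self):
        from skimage.measure import label

        imgset, _ = synthio.gen_cell_images(n_cells=5, noise_sd=0.0, image_size=200, seed=4)
        rfp = imgset.channels[0]["RFP"]
        assert label(rfp > rfp.min()).max() == 5

    def test_deterministic(self):
        a, _ = synthio.gen_cell_images(n_cells=3, image_size=160, seed=9)
        b, _ = synthio.gen_cell_images(n_cells=3, image_size=160, seed=9)
        for ca, cb in zip(a.channels, b.channels):
            for name in ("RFP", "YFP", "CFP"):
                assert np.array_equal(ca[name], cb[name])

    def test_infeasible_density_rejected(self):
        with pytest.raises(InvalidArgumentError):
            synthio.gen_cell_images(n_cells=200, image_size=100)


class TestEcg:
    def test_r_peak_count(self):
        trace, truth = synthio.gen_ecg(bpm=60.0, duration=30.0, seed=0)
        assert len(truth.params["r_times"]) == 30

    def test_zero_st_offset_means_baseline_st(self):
        trace, truth = synthio.gen_ecg(bpm=60.0, st_offset=0.0, duration=10.0)
        # sample mid-ST: 100 ms after each R peak
        idx = [int((r + 0.10) * truth.params["fs"]) for r in truth.params["r_times"][:-1]]
        assert np.allclose(trace.values[idx], 0.0, atol=0.01)

    def test_r_amplitude_is_max(self):
        trace, _ = synthio.gen_ecg(bpm=60.0, r_amplitude=1.0, noise_sd=0.0, duration=10.0)
        assert trace.values.max() == pytest.approx(1.0, abs=0.01)

    def test_feasibility_validation(self):
        with pytest.raises(InvalidArgumentError):
            synthio.gen_ecg(fs=100.0)
        with pytest.raises(InvalidArgumentError):
            synthio.gen_ecg(bpm=120.0, qrs_width=0.6)


def test_all_generators_deterministic_traces():
    for gen, kwargs in (
        (synthio.gen_o2_trace, dict(noise_sd=1.0)),
        (synthio.gen_ecg, dict(noise_sd=0.05, duration=5.0)),
    ):
        a, _ = gen(seed=77, **kwargs)
        b, _ = gen(seed=77, **kwargs)
        assert np.array_equal(a.values, b.values)
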