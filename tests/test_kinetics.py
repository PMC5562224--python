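"""Gas-challenge kinetics: smoothing, metric extraction, response maps."""

import numpy as np
import pytest

from oeot import (
    GasSchedule,
    KineticTrace,
    extract_metrics,
    responding_fraction,
    response_map,
    smooth_trace,
)
from oeot.phantom import FRAME_INTERVAL_S, simulate_region_trace


def flat_trace(n=60, value=0.3):
    return KineticTrace(np.arange(n) * FRAME_INTERVAL_S, np.full(n, value))


class TestGasSchedule:
    def test_default_challenge_switch_times(self, schedule):
        assert schedule.challenge_switch_s == 300.0
        assert schedule.challenge_end_s == 1500.0
        assert schedule.switch_times == [300.0, 1500.0]

    def test_rejects_gap_between_segments(self):
        with pytest.raises(ValueError, match="contiguous"):
            GasSchedule((("air", 0, 300), ("o2", 310, 600)))

    def test_rejects_first_segment_not_air(self):
        with pytest.raises(ValueError, match="air"):
            GasSchedule((("o2", 0, 300), ("air", 300, 600)))

    def test_rejects_schedule_without_switch(self):
        with pytest.raises(ValueError, match="switch"):
            GasSchedule((("air", 0, 300),))

    def test_json_round_trip(self, schedule, tmp_path):
        p = tmp_path / "schedule.json"
        schedule.to_json(p)
        assert GasSchedule.from_json(p) == schedule


class TestSmoothing:
    def test_constant_trace_unchanged(self):
        t = flat_trace()
        s = smooth_trace(t, 5)
        np.testing.assert_allclose(s.values, t.values)

    def test_window_one_is_identity(self):
        t = flat_trace()
        t.values[10] = 0.9
        s = smooth_trace(t, 1)
        np.testing.assert_array_equal(s.values, t.values)

    def test_impulse_spreads_as_direct_convolution(self):
        # oracle: direct moving-average convolution of a unit impulse
        n, k = 31, 15
        vals = np.zeros(n)
        vals[k] = 1.0
        t = KineticTrace(np.arange(n, dtype=float), vals)
        s = smooth_trace(t, 5)
        expected = np.convolve(vals, np.ones(5) / 5, mode="same")
        np.testing.assert_allclose(s.values[3:-3], expected[3:-3])
        assert np.all(s.values[k - 2 : k + 3] == pytest.approx(0.2))

    def test_invalid_samples_excluded(self):
        t = KineticTrace(np.arange(9, dtype=float),
                         np.array([1, 1, 1, 1, 100.0, 1, 1, 1, 1]),
                         valid=np.array([1, 1, 1, 1, 0, 1, 1, 1, 1], bool))
        s = smooth_trace(t, 3)
        assert np.isnan(s.values[4])
        np.testing.assert_allclose(s.values[t.valid], 1.0)

    def test_window_larger_than_trace_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            smooth_trace(flat_trace(n=3), 5)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            smooth_trace(flat_trace(), 4)


class TestExtractMetrics:
    def test_ideal_step_metrics(self, schedule):
        times = np.arange(0, 1800, FRAME_INTERVAL_S)
        vals = np.where(times < 300.0, 0.27, 0.31)
        m = extract_metrics(KineticTrace(times, vals), schedule)
        assert m.so2_air == pytest.approx(0.27)
        assert m.so2_o2 == pytest.approx(0.31)
        assert m.delta_so2 == pytest.approx(0.04)
        assert m.t_half_s < FRAME_INTERVAL_S

    def test_exponential_half_time_recovered(self):
        # long O2 plateau so the plateau average sits at the asymptote
        schedule = GasSchedule((("air", 0, 300), ("o2", 300, 3900),
                                ("air", 3900, 4200)))
        times = np.arange(0, 4200, FRAME_INTERVAL_S)
        a, d = 0.27, 0.1
        vals = np.where(times < 300, a,
                        a + d * (1 - 2 ** (-(times - 300) / 300.0)))
        m = extract_metrics(KineticTrace(times, vals), schedule)
        assert m.t_half_s == pytest.approx(300.0, abs=FRAME_INTERVAL_S)
        assert m.delta_so2 == pytest.approx(d, abs=1e-3)

    def test_flat_noisy_trace_has_undefined_t_half(self, schedule):
        rng = np.random.default_rng(5)
        times = np.arange(0, 1800, FRAME_INTERVAL_S)
        vals = 0.3 + rng.normal(0, 0.01, times.size)
        m = extract_metrics(KineticTrace(times, vals), schedule, noise_k=2.0)
        assert np.isnan(m.t_half_s)
        assert abs(m.delta_so2) < 0.02

    def test_delta_identity(self, schedule):
        trace = simulate_region_trace(0.3, 0.08, 120.0, schedule,
                                      noise_sd=0.02,
                                      rng=np.random.default_rng(1))
        m = extract_metrics(trace, schedule)
        assert m.delta_so2 == pytest.approx(m.so2_o2 - m.so2_air, abs=1e-15)

    def test_step_estimates_shorter_t_half_than_slow_exponential(self, schedule):
        # healthy-vs-tumour contrast: a step responder is always estimated
        # faster than a 300 s exponential responder
        for seed in range(8):
            rng = np.random.default_rng(seed)
            t_step = extract_metrics(
                smooth_to(simulate_region_trace(0.49, 0.1, 0.0, schedule,
                                                kinetic_shape="step",
                                                noise_sd=0.02, rng=rng)),
                schedule).t_half_s
            t_exp = extract_metrics(
                smooth_to(simulate_region_trace(0.27, 0.1, 300.0, schedule,
                                                noise_sd=0.02, rng=rng)),
                schedule).t_half_s
            assert t_step < t_exp


def smooth_to(trace, window=5):
    return smooth_trace(trace, window)


class TestResponseMap:
    def make_stack(self, delta_map, schedule, so2_air=0.3, n_frames=157):
        times = np.arange(n_frames) * FRAME_INTERVAL_S
        on = (times >= schedule.challenge_switch_s) & (times < schedule.challenge_end_s)
        stack = so2_air + delta_map[None] * on[:, None, None]
        return stack, times

    def test_ground_truth_responders_recovered(self, schedule):
        rng = np.random.default_rng(2)
        truth = rng.random((20, 20)) < 0.6
        delta_map = np.where(truth, 0.08, 0.0)
        stack, times = self.make_stack(delta_map, schedule)
        rmap = response_map(stack, times, schedule, pixel_spacing=0.225)
        np.testing.assert_array_equal(rmap.responding_mask, truth)
        rf = responding_fraction(rmap, np.ones((20, 20), bool))
        assert rf == pytest.approx(truth.mean())

    def test_subthreshold_delta_gives_empty_mask(self, schedule):
        delta_map = np.full((10, 10), 0.02)
        stack, times = self.make_stack(delta_map, schedule)
        rmap = response_map(stack, times, schedule, pixel_spacing=0.225)
        assert not rmap.responding_mask.any()

    def test_negative_response_reported_separately(self, schedule):
        delta_map = np.full((10, 10), -0.05)
        stack, times = self.make_stack(delta_map, schedule)
        rmap = response_map(stack, times, schedule, pixel_spacing=0.225)
        assert rmap.negative_mask.all()
        assert not rmap.responding_mask.any()

    def test_rf_threshold_insensitivity_on_bimodal_phantom(self, schedule):
        rng = np.random.default_rng(4)
        truth = rng.random((16, 16)) < 0.5
        delta_map = np.where(truth, 0.08, 0.0)
        stack, times = self.make_stack(delta_map, schedule)
        roi = np.ones((16, 16), bool)
        rfs = []
        for thr in (0.02, 0.03, 0.04):
            rmap = response_map(stack, times, schedule, pixel_spacing=0.225,
                                threshold=thr)
            rfs.append(responding_fraction(rmap, roi))
        assert rfs[0] == rfs[1] == rfs[2] == pytest.approx(truth.mean())

    def test_rf_monotone_non_increasing_in_threshold(self, schedule):
        rng = np.random.default_rng(9)
        delta_map = rng.normal(0.03, 0.03, (25, 25))
        stack, times = self.make_stack(delta_map, schedule)
        roi = np.ones((25, 25), bool)
        rfs = [
            responding_fraction(
                response_map(stack, times, schedule, pixel_spacing=0.225,
                             threshold=t), roi)
            for t in np.linspace(0.0, 0.08, 9)
        ]
        assert all(a >= b for a, b in zip(rfs, rfs[1:]))

    def test_empty_roi_rejected(self, schedule):
        stack, times = self.make_stack(np.zeros((5, 5)), schedule)
        rmap = response_map(stack, times, schedule, pixel_spacing=0.225)
        with pytest.raises(ValueError, match="empty"):
            responding_fraction(rmap, np.zeros((5, 5), bool))
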