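"""Smoothing, transition detection, cycle assembly and phase metrics."""

import numpy as np
import pytest
from scipy import signal as sps

from thermoresp import (
    TemperatureTrace,
    build_cycles,
    detect_transition_points,
    mean_cycle,
    phase_metrics,
    residual_trace,
    segment_trace,
    smooth_trace,
    simulate_trace,
)
from thermoresp.segmentation import (
    TransitionPoints,
    breathing_rate,
    interpolated_median,
)
from thermoresp.simulate import BreathModelParams


def make_trace(values, fps=30.0):
    return TemperatureTrace("s", "i", fps, np.arange(len(values)),
                            np.asarray(values, dtype=float))


class TestSmoothTrace:
    def test_constant_trace_unchanged(self):
        trace = make_trace(np.full(300, 31.0))
        out = smooth_trace(trace)
        assert np.allclose(out.temperature_C, 31.0, atol=1e-9)

    def test_tone_attenuation_matches_forward_backward_response(self):
        # a 0.6 Hz tone through the zero-phase filter is attenuated by the
        # squared Butterworth magnitude at that normalized frequency
        fps, f0 = 30.0, 0.6
        t = np.arange(3000) / fps
        trace = make_trace(np.sin(2 * np.pi * f0 * t))
        out = smooth_trace(trace).temperature_C
        b, a = sps.butter(2, 0.2, btype="low")
        _, h = sps.freqz(b, a, worN=[2 * np.pi * f0 / fps])
        expected_gain = np.abs(h[0]) ** 2
        mid = slice(500, 2500)  # avoid filter edge effects
        measured_gain = (np.sqrt(np.mean(out[mid] ** 2))
                         / np.sqrt(np.mean(trace.temperature_C[mid] ** 2)))
        assert measured_gain == pytest.approx(expected_gain, rel=1e-3)

    def test_high_frequency_noise_removed(self, rng):
        fps = 30.0
        t = np.arange(1500) / fps
        clean = np.sin(2 * np.pi * 0.6 * t)
        noisy = clean + 0.3 * np.sin(2 * np.pi * 10.0 * t) \
            + rng.normal(0, 0.05, size=len(t))
        out = smooth_trace(make_trace(noisy)).temperature_C
        assert np.corrcoef(out, clean)[0, 1] > 0.99

    def test_cutoff_in_hz_equivalent_to_normalized(self):
        trace = make_trace(np.sin(np.linspace(0, 20, 600)))
        a = smooth_trace(trace, critical_frequency=0.2).temperature_C
        b = smooth_trace(trace, cutoff_Hz=3.0).temperature_C
        assert np.allclose(a, b)

    def test_too_short_trace_raises(self):
        with pytest.raises(ValueError, match="warm-up"):
            smooth_trace(make_trace(np.zeros(5)))


class TestTransitionDetection:
    def test_monotone_trace_has_no_transitions(self):
        trace = make_trace(np.linspace(30, 35, 400))
        assert detect_transition_points(smooth_trace(trace)) == []

    def test_noiseless_cycles_recovered_within_two_frames(self, noiseless_trace):
        trace, gt = noiseless_trace
        det = detect_transition_points(smooth_trace(trace),
                                       raw_values=trace.temperature_C)
        assert len(det) == len(gt.cycles)
        for d, g in zip(det, gt.cycles):
            assert abs(d.pause_end_frame - g.insp_start_frame) <= 2
            assert abs(d.max_inspiration_frame - g.max_insp_frame) <= 2
            assert abs(d.pause_start_frame - g.pause_start_frame) <= 2

    def test_identical_cycles_give_congruent_triples(self, noiseless_trace):
        trace, gt = noiseless_trace
        det = detect_transition_points(smooth_trace(trace),
                                       raw_values=trace.temperature_C)
        period = gt.cycles[1].insp_start_frame - gt.cycles[0].insp_start_frame
        # interior triples (away from segment edges) repeat exactly
        for a, b in zip(det[1:-2], det[2:-1]):
            assert b.max_inspiration_frame - a.max_inspiration_frame \
                == pytest.approx(period, abs=1)
            assert (b.pause_end_frame - a.pause_end_frame
                    == b.max_inspiration_frame - a.max_inspiration_frame)

    def test_transition_point_ordering_enforced(self):
        with pytest.raises(ValueError):
            TransitionPoints(10, 5, 20)


class TestBuildCycles:
    def test_three_triples_give_two_complete_cycles(self, noiseless_trace):
        trace, _ = noiseless_trace
        smoothed = smooth_trace(trace)
        det = detect_transition_points(smoothed,
                                       raw_values=trace.temperature_C)[:3]
        cycles = build_cycles(det, smoothed)
        assert len(cycles) == 3
        assert [c.complete for c in cycles] == [True, True, False]
        # trailing cycle lacks only the pause
        assert [p.kind for p in cycles[-1].phases] == ["inspiration",
                                                       "expiration"]

    def test_phases_tile_the_transition_span(self, quiet_trace):
        trace, _ = quiet_trace
        smoothed, cycles = segment_trace(trace)
        for c in cycles:
            for p, q in zip(c.phases, c.phases[1:]):
                assert p.end_frame == q.start_frame
        complete = [c for c in cycles if c.complete]
        for c, nxt in zip(complete, complete[1:]):
            assert c.end_frame <= nxt.start_frame

    def test_expiration_count_at_least_pause_count(self, quiet_trace):
        trace, _ = quiet_trace
        _, cycles = segment_trace(trace)
        kinds = [p.kind for c in cycles for p in c.phases]
        assert kinds.count("expiration") >= kinds.count("expiratory_pause")

    def test_grossly_overlapping_transitions_raise(self, noiseless_trace):
        trace, _ = noiseless_trace
        smoothed = smooth_trace(trace)
        bad = [TransitionPoints(10, 20, 90), TransitionPoints(40, 60, 80)]
        with pytest.raises(ValueError, match="overlap"):
            build_cycles(bad, smoothed)


class TestPhaseMetrics:
    def test_linear_descent_metrics(self):
        values = np.linspace(30.0, 28.0, 31)  # 30 frames at 30 fps
        d, a, s = phase_metrics(0, 30, values, fps=30.0)
        assert (d, a, s) == (1.0, pytest.approx(2.0), pytest.approx(2.0))

    def test_plateau_has_zero_amplitude_and_slope(self):
        d, a, s = phase_metrics(0, 15, np.full(16, 31.2), fps=30.0)
        assert a == 0.0 and s == 0.0

    def test_slope_is_amplitude_over_duration_identity(self, quiet_trace):
        trace, _ = quiet_trace
        _, cycles = segment_trace(trace)
        for c in cycles:
            for p in c.phases:
                assert p.slope == pytest.approx(p.amplitude_C / p.duration_s)

    def test_metrics_match_brute_force_recomputation(self, quiet_trace):
        trace, _ = quiet_trace
        _, cycles = segment_trace(trace)
        raw = trace.temperature_C
        for c in cycles:
            for p in c.phases:
                assert p.duration_s == pytest.approx(
                    (p.end_frame - p.start_frame) / trace.fps)
                assert p.amplitude_C == pytest.approx(
                    abs(raw[p.end_frame] - raw[p.start_frame]))

    def test_zero_length_phase_raises(self):
        with pytest.raises(ValueError, match="zero-length"):
            phase_metrics(5, 5, np.zeros(10), fps=30.0)


class TestResidualAndMeanCycle:
    def test_constant_trace_residuals_zero(self):
        assert np.allclose(residual_trace(np.full(10, 31.0)), 0.0)

    def test_simple_residuals(self):
        assert np.allclose(residual_trace([1.0, 2.0, 3.0]), [-1, 0, 1])

    def test_residual_mean_near_zero_random(self, rng):
        for _ in range(5):
            r = residual_trace(rng.normal(31, 1, size=500))
            assert abs(r.mean()) < 1e-9

    def test_identical_cycles_zero_ci_width(self, noiseless_trace):
        trace, _ = noiseless_trace
        smoothed, cycles = segment_trace(trace)
        mc = mean_cycle([c for c in cycles if c.complete][1:-1], smoothed,
                        n_points=50)
        width = mc.ci_high - mc.ci_low
        assert np.max(width) < 0.02  # sub-frame boundary jitter only

    def test_mean_of_mean_cycle_near_zero(self, quiet_trace):
        trace, _ = quiet_trace
        smoothed, cycles = segment_trace(trace)
        mc = mean_cycle(cycles, smoothed, n_points=80)
        assert abs(mc.mean_residual_C.mean()) < 0.5

    def test_two_triangular_cycles_average_exactly(self):
        # hand-computable: two identical triangular residual cycles
        tri = np.concatenate([np.linspace(0, 1, 11), np.linspace(1, 0, 11)[1:]])
        values = 31.0 + np.tile(tri, 2)
        trace = make_trace(values)
        from thermoresp.segmentation import RespirationCycle, RespirationPhase
        cycles = [
            RespirationCycle(0, [RespirationPhase("inspiration", 0, 20, 1, 1, 1)]),
            RespirationCycle(1, [RespirationPhase("inspiration", 21, 41, 1, 1, 1)]),
        ]
        mc = mean_cycle(cycles, trace, n_points=21)
        resid = values - values.mean()
        expected = 0.5 * (resid[0:21] + resid[21:42])
        assert np.allclose(mc.mean_residual_C, expected, atol=0.06)

    def test_fewer_than_two_cycles_raises(self, noiseless_trace):
        trace, _ = noiseless_trace
        smoothed, cycles = segment_trace(trace)
        with pytest.raises(ValueError):
            mean_cycle(cycles[:1], smoothed)


class TestRateAndRecovery:
    def test_breathing_rate_on_regular_cycles(self, noiseless_trace):
        trace, gt = noiseless_trace
        det = detect_transition_points(smooth_trace(trace),
                                       raw_values=trace.temperature_C)
        assert breathing_rate(det, trace.fps) == pytest.approx(1 / 2.0,
                                                               rel=0.02)

    def test_rate_recovery_with_noise_within_five_percent(self):
        params = BreathModelParams(noise_sd_C=0.05)
        trace, gt = simulate_trace(params, 120, seed=21)
        det = detect_transition_points(smooth_trace(trace),
                                       raw_values=trace.temperature_C)
        assert breathing_rate(det, 30.0) == pytest.approx(gt.mean_rate_Hz,
                                                          rel=0.05)

    def test_inspiration_expiration_ratio_symmetric_cycles(self):
        # time-symmetric limbs: detected duration ratio close to 1
        trace, _ = simulate_trace(BreathModelParams(), 150, seed=5)
        _, cycles = segment_trace(trace)
        insp = [p.duration_s for c in cycles for p in c.phases
                if p.kind == "inspiration"]
        exp = [p.duration_s for c in cycles for p in c.phases
               if p.kind == "expiration"]
        assert np.mean(insp) / np.mean(exp) == pytest.approx(1.0, abs=0.05)


def test_interpolated_median_recovers_continuous_median(rng):
    cont = rng.lognormal(np.log(0.65), 0.5, size=4000)
    quantized = np.round(cont * 30) / 30
    est = interpolated_median(quantized, 1 / 30)
    assert est == pytest.approx(0.65, rel=0.03)
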