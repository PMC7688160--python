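import numpy as np
import pytest
from scipy.optimize import brentq

from valvephenoquant import doppler as dop
from valvephenoquant import synthetic as syn


def _flat_trace(r_peaks, t_end, value=500.0, fs=1000.0):
    t = np.arange(0.0, t_end + 0.5 / fs, 1.0 / fs)
    return dop.VelocityTrace(t, np.full_like(t, value), np.asarray(r_peaks))


class TestSegmentation:
    def test_consecutive_peaks_give_half_open_cycles(self):
        trace = _flat_trace([0.0, 0.13, 0.26], t_end=0.26)
        cycles = dop.segment_cycles(trace)
        assert [(c.start, c.end) for c in cycles] == [(0.0, 0.13), (0.13, 0.26)]
        # half-open: no sample is in two cycles
        assert sum(len(c.time) for c in cycles) == np.sum(trace.time < 0.26)

    def test_generator_contract_one_cycle_per_peak(self):
        trace = syn.simulate_doppler(syn.DopplerGroundTruth(n_cycles=100))
        assert len(dop.segment_cycles(trace)) == 100

    def test_single_peak_raises_gating_error(self):
        trace = _flat_trace([0.1], t_end=0.2)
        with pytest.raises(dop.GatingError):
            dop.segment_cycles(trace)

    def test_nonuniform_sampling_rejected(self):
        t = np.array([0.0, 0.1, 0.3, 0.7, 1.5])
        with pytest.raises(ValueError):
            dop.VelocityTrace(t, np.zeros_like(t), np.array([0.0, 1.0]))


class TestEjectionWindow:
    def test_sin_squared_window_covers_root_solved_fraction(self, aligned_doppler_gt):
        """The >10%-of-max run of a sin^2 lobe spans 1 - 2 x0 of the
        ejection time where sin^2(pi x0) = 0.1 (numeric root find)."""
        x0 = brentq(lambda x: np.sin(np.pi * x) ** 2 - 0.1, 0.0, 0.5)
        expected = 1.0 - 2.0 * x0  # ~ 0.7952
        trace = syn.simulate_doppler(aligned_doppler_gt)
        cycle = dop.segment_cycles(trace)[0]
        i0, i1 = dop.detect_ejection_window(cycle)
        dt = 1.0 / aligned_doppler_gt.sampling_rate
        frac = (i1 - i0) * dt / aligned_doppler_gt.ejection_duration
        assert frac == pytest.approx(expected, abs=0.01)

    def test_constant_velocity_window_is_whole_cycle(self):
        trace = _flat_trace([0.0, 0.2], t_end=0.2)
        cycle = dop.segment_cycles(trace)[0]
        i0, i1 = dop.detect_ejection_window(cycle)
        assert (i0, i1) == (0, len(cycle.velocity))

    def test_all_zero_cycle_raises(self):
        trace = _flat_trace([0.0, 0.2], t_end=0.2, value=0.0)
        cycle = dop.segment_cycles(trace)[0]
        with pytest.raises(ValueError):
            dop.detect_ejection_window(cycle)


class TestPeakVelocity:
    def test_noise_free_peak_is_exact(self, aligned_doppler_gt):
        trace = syn.simulate_doppler(aligned_doppler_gt)
        cycle = dop.segment_cycles(trace)[0]
        assert dop.peak_systolic_velocity(cycle) == pytest.approx(1000.0, abs=1e-9)

    def test_zero_cycle_has_zero_peak(self):
        trace = _flat_trace([0.0, 0.2], t_end=0.2, value=0.0)
        cycle = dop.segment_cycles(trace)[0]
        assert dop.peak_systolic_velocity(cycle) == 0.0

    def test_noisy_recovery_is_nearly_unbiased(self):
        """Smoothed per-cycle maxima recover the planted peak within 3%
        at envelope noise of 5% of Vpeak (reduced-size Monte Carlo)."""
        estimates = []
        for seed in range(5):
            gt = syn.DopplerGroundTruth(
                peak_velocity=1200.0, noise_sd=60.0, n_cycles=10, seed=seed
            )
            image, _ = dop.analyze_trace(syn.simulate_doppler(gt))
            estimates.append(image.peak_velocity)
        assert np.mean(estimates) == pytest.approx(1200.0, rel=0.03)


class TestMeanGradient:
    def test_constant_velocity_gradient(self):
        trace = _flat_trace([0.0, 0.2], t_end=0.2, value=1000.0)
        cycle = dop.segment_cycles(trace)[0]
        assert dop.mean_pressure_gradient(cycle) == pytest.approx(4.0)

    def test_sin_squared_gradient_matches_closed_form(self, aligned_doppler_gt):
        gt = syn.DopplerGroundTruth(
            peak_velocity=1200.0, n_cycles=3, sampling_rate=8000.0
        )
        trace = syn.simulate_doppler(gt)
        cycle = dop.segment_cycles(trace)[0]
        assert dop.mean_pressure_gradient(cycle) == pytest.approx(2.16, rel=0.05)

    def test_zero_velocity_on_forced_window_is_zero(self):
        trace = _flat_trace([0.0, 0.2], t_end=0.2, value=0.0)
        cycle = dop.segment_cycles(trace)[0]
        assert dop.mean_pressure_gradient(cycle, window=(0, len(cycle.velocity))) == 0.0

    def test_scaling_velocity_scales_gradient_quadratically(self, aligned_doppler_gt):
        trace = syn.simulate_doppler(aligned_doppler_gt)
        cycle = dop.segment_cycles(trace)[0]
        scaled = dop.CardiacCycle(cycle.start, cycle.end, cycle.time, 3.0 * cycle.velocity)
        assert dop.mean_pressure_gradient(scaled) == pytest.approx(
            9.0 * dop.mean_pressure_gradient(cycle)
        )

    def test_time_translation_invariance(self, aligned_doppler_gt):
        trace = syn.simulate_doppler(aligned_doppler_gt)
        shifted = dop.VelocityTrace(trace.time + 5.0, trace.velocity, trace.r_peaks + 5.0)
        c0 = dop.segment_cycles(trace)[0]
        c1 = dop.segment_cycles(shifted)[0]
        assert dop.mean_pressure_gradient(c1) == pytest.approx(dop.mean_pressure_gradient(c0))


class TestSummaries:
    def _image(self, peak, grad=2.0, n=10):
        return dop.HemodynamicSummary(peak, grad, n, dop.SummaryLevel.IMAGE)

    def test_mouse_summary_is_unweighted_mean_of_images(self):
        mouse = dop.summarize_mouse([self._image(1000), self._image(1100), self._image(1200)])
        assert mouse.peak_velocity == pytest.approx(1100.0)
        assert mouse.n_cycles == 30
        assert mouse.level is dop.SummaryLevel.MOUSE

    def test_image_summary_is_mean_of_cycle_metrics(self, aligned_doppler_gt):
        trace = syn.simulate_doppler(aligned_doppler_gt)
        image, cycles = dop.analyze_trace(trace, smooth_ms=0.0)
        assert image.peak_velocity == pytest.approx(
            np.mean([c.peak_velocity for c in cycles]), abs=1e-12
        )
        assert image.mean_gradient == pytest.approx(
            np.mean([c.mean_gradient for c in cycles]), abs=1e-12
        )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            dop.summarize_mouse([])


class TestSeverity:
    @pytest.mark.parametrize(
        "peak, severe", [(1400.0, True), (1000.0, False), (1320.0, False)]
    )
    def test_threshold_is_strict(self, peak, severe):
        mouse = dop.HemodynamicSummary(peak, 5.0, 100, dop.SummaryLevel.MOUSE)
        assert dop.classify_severe(mouse) is severe

    def test_requires_mouse_level(self):
        image = dop.HemodynamicSummary(1400.0, 5.0, 10, dop.SummaryLevel.IMAGE)
        with pytest.raises(ValueError):
            dop.classify_severe(image)


def test_csv_round_trip(tmp_path, aligned_doppler_gt):
    trace = syn.simulate_doppler(aligned_doppler_gt)
    trace.to_csv(tmp_path / "t.csv", tmp_path / "r.csv")
    back = dop.VelocityTrace.from_csv(tmp_path / "t.csv", tmp_path / "r.csv")
    assert np.allclose(back.velocity, trace.velocity)
    assert np.allclose(back.r_peaks, trace.r_peaks)
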