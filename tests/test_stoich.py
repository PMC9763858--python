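"""Molecule counting: CK filtering, step detection, calibration, periodicity."""

import numpy as np
import pytest

from patchstoich import (CalibrationResult, Track, chung_kennedy_filter,
                         detect_steps, initial_track_intensity, periodicity,
                         simulate_intensity_trace, single_fluorophore_brightness,
                         stoichiometry_kde, track_stoichiometry)
from patchstoich.detect import Focus
from patchstoich.errors import CalibrationError, ParameterError


def make_track(intensities, start_frame=0, track_id=0):
    foci = [Focus(frame=start_frame + i, x=10.0, y=10.0, intensity=float(v),
                  bg=0.0, sigma=1.4, snr=10.0)
            for i, v in enumerate(intensities)]
    return Track(id=track_id, foci=foci)


class TestChungKennedyFilter:
    def test_constant_trace_unchanged(self):
        trace = np.full(40, 123.0)
        np.testing.assert_allclose(chung_kennedy_filter(trace, 5, 2.0), trace)

    def test_noiseless_step_preserved(self):
        trace, _ = simulate_intensity_trace([(200.0, 50), (100.0, 50)])
        filt = chung_kennedy_filter(trace, 5, 2.0)
        # plateaus exact away from the transition
        np.testing.assert_allclose(filt[:48], 200.0)
        np.testing.assert_allclose(filt[52:], 100.0)
        # transition localized within one sample of the true boundary
        crossing = np.where(np.diff(filt < 150.0))[0]
        assert len(crossing) == 1 and abs(crossing[0] + 1 - 50) <= 1

    def test_noise_is_suppressed_on_plateaus(self, rng):
        trace, _ = simulate_intensity_trace([(100.0, 200)], noise_sd=10.0,
                                            seed=rng)
        filt = chung_kennedy_filter(trace, 5, 2.0)
        assert filt[20:-20].std() < trace[20:-20].std()

    def test_short_trace_rejected(self):
        with pytest.raises(ParameterError):
            chung_kennedy_filter(np.zeros(10), window=5)


class TestDetectSteps:
    def test_single_noiseless_step(self):
        trace, _ = simulate_intensity_trace([(200.0, 50), (100.0, 50)])
        filt = chung_kennedy_filter(trace, 5, 2.0)
        steps = detect_steps(filt, min_step=50.0, raw=trace)
        assert len(steps) == 1
        pos, size = steps[0]
        assert size == pytest.approx(100.0) and abs(pos - 50) <= 1

    def test_noiseless_bleach_cascade_modal_step_is_unitary(self):
        schedule = [(400.0, 40), (300.0, 40), (200.0, 40), (100.0, 40), (0.0, 40)]
        trace, _ = simulate_intensity_trace(schedule)
        filt = chung_kennedy_filter(trace, 5, 2.0)
        steps = detect_steps(filt, min_step=50.0, raw=trace)
        sizes = [s for _, s in steps]
        assert len(sizes) == 4
        np.testing.assert_allclose(sizes, 100.0)

    def test_noisy_two_step_trace_detected(self):
        trace, true_pos = simulate_intensity_trace(
            [(200.0, 60), (100.0, 60), (0.0, 60)], noise_sd=15.0, seed=4)
        filt = chung_kennedy_filter(trace, 5, 2.0)
        steps = detect_steps(filt, min_step=50.0, raw=trace)
        assert len(steps) == 2
        for (pos, _), tp in zip(steps, true_pos):
            assert abs(pos - tp) <= 2

    def test_sub_threshold_changes_merged(self):
        trace, _ = simulate_intensity_trace([(100.0, 50), (80.0, 50)])
        filt = chung_kennedy_filter(trace, 5, 2.0)
        assert detect_steps(filt, min_step=50.0, raw=trace) == []


class TestCalibration:
    def test_noiseless_postbleach_mode_is_exact(self):
        vals = np.full(20, 100.0)
        res = single_fluorophore_brightness(method="modal_postbleach",
                                            postbleach_intensities=vals)
        assert res.I1 == pytest.approx(100.0, abs=0.1)
        assert res.support == 20

    def test_noisy_postbleach_mode_within_ten_percent(self, rng):
        vals = np.concatenate([rng.normal(100, 12, 200),
                               rng.normal(200, 18, 60)])
        res = single_fluorophore_brightness(method="modal_postbleach",
                                            postbleach_intensities=vals)
        assert res.I1 == pytest.approx(100.0, rel=0.10)

    def test_too_few_foci_is_a_calibration_error(self):
        with pytest.raises(CalibrationError):
            single_fluorophore_brightness(method="modal_postbleach",
                                          postbleach_intensities=np.full(5, 100.0))

    def test_step_interval_calibration_on_synthetic_traces(self, rng):
        traces = []
        for _ in range(25):
            n = int(rng.integers(2, 5))
            schedule = [(100.0 * k, int(rng.integers(25, 60)))
                        for k in range(n, -1, -1)]
            traces.append(simulate_intensity_trace(schedule, noise_sd=12.0,
                                                   seed=rng)[0])
        res = single_fluorophore_brightness(method="step_intervals",
                                            traces=traces, min_step=50.0)
        assert res.I1 == pytest.approx(100.0, rel=0.10)

    def test_external_standard_passthrough(self):
        res = single_fluorophore_brightness(method="external_standard",
                                            external_value=87.0)
        assert res.I1 == 87.0 and res.method == "external_standard"


class TestInitialIntensity:
    def test_flat_track(self):
        assert initial_track_intensity(make_track([100.0] * 5)) == \
            pytest.approx(100.0)

    def test_linear_decay_from_frame_one_extrapolates_to_110(self):
        # intensities 100..60 at frames 1..5: slope -10, intercept 110 at t0=0
        track = make_track([100.0, 90.0, 80.0, 70.0, 60.0], start_frame=1)
        assert initial_track_intensity(track, t0_frame=0) == pytest.approx(110.0)

    def test_matches_closed_form_ols_on_exponential_decay(self):
        y = 300.0 * np.exp(-0.05 * np.arange(5))
        track = make_track(y)
        t = np.arange(5.0)
        # independent closed-form OLS
        beta = np.sum((t - t.mean()) * (y - y.mean())) / np.sum((t - t.mean()) ** 2)
        alpha = y.mean() - beta * t.mean()
        assert initial_track_intensity(track, t0_frame=0) == \
            pytest.approx(alpha, abs=1e-9)

    def test_positive_slope_falls_back_to_mean(self):
        track = make_track([100.0, 110.0, 120.0, 130.0, 140.0])
        assert initial_track_intensity(track) == pytest.approx(120.0)

    def test_single_focus_track_has_no_initial_intensity(self):
        assert initial_track_intensity(make_track([100.0])) is None

    def test_scaling_intensities_scales_I0(self):
        y = [220.0, 190.0, 181.0, 160.0, 140.0]
        i0 = initial_track_intensity(make_track(y))
        i0c = initial_track_intensity(make_track([3.0 * v for v in y]))
        assert i0c == pytest.approx(3.0 * i0, rel=1e-12)


class TestTrackStoichiometry:
    CAL = CalibrationResult(I1=100.0, method="external_standard", support=0)

    def test_simple_ratio(self):
        track = make_track([200.0] * 5)
        assert track_stoichiometry(track, self.CAL) == pytest.approx(2.0)

    def test_late_start_excluded(self):
        track = make_track([200.0] * 5, start_frame=30)
        assert track_stoichiometry(track, self.CAL) is None
        assert track.excluded

    def test_start_frame_gate_boundary(self):
        # "first 10 frames" of exposure: start 9 included, start 10 excluded
        assert track_stoichiometry(make_track([200.0] * 5, start_frame=9),
                                   self.CAL) is not None
        assert track_stoichiometry(make_track([200.0] * 5, start_frame=10),
                                   self.CAL) is None

    def test_length_one_excluded(self):
        assert track_stoichiometry(make_track([200.0]), self.CAL) is None

    def test_scale_equivariance(self):
        y = [412.0, 395.0, 380.0, 371.0, 355.0]
        s1 = track_stoichiometry(make_track(y), self.CAL)
        cal_scaled = CalibrationResult(I1=250.0, method="external_standard",
                                      support=0)
        s2 = track_stoichiometry(make_track([2.5 * v for v in y]), cal_scaled)
        assert s2 == pytest.approx(s1, rel=1e-12)


class TestStoichiometryKde:
    def test_single_value_gaussian_shape(self):
        grid, dens = stoichiometry_kde(np.array([5.0]), kernel_width=0.6)
        peak = grid[np.argmax(dens)]
        assert peak == pytest.approx(5.0, abs=0.05)
        at_peak = dens.max()
        at_sd = dens[np.argmin(np.abs(grid - 5.6))]
        assert at_sd / at_peak == pytest.approx(np.exp(-0.5), rel=0.02)

    def test_four_equal_modes(self):
        grid, dens = stoichiometry_kde(np.array([2.0, 4.0, 6.0, 8.0]))
        interior = (dens[1:-1] > dens[2:]) & (dens[1:-1] >= dens[:-2])
        peaks = grid[1:-1][interior]
        assert len(peaks) == 4
        np.testing.assert_allclose(peaks, [2, 4, 6, 8], atol=0.1)

    def test_density_integrates_to_one(self, rng):
        vals = rng.uniform(3, 20, 40)
        grid, dens = stoichiometry_kde(vals)
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            stoichiometry_kde(np.array([]))


class TestPeriodicity:
    def test_exact_dimer_ladder(self):
        res = periodicity(np.array([2.0, 4.0, 6.0, 8.0, 10.0]))
        assert res.interval == pytest.approx(2.0, abs=0.02)
        assert res.n_under_peak == 4
        # error = width * sqrt(mean(S)/n_extrap) / n_under_peak
        assert res.error == pytest.approx(0.6 * np.sqrt(6.0 / 5.0) / 4.0)
        assert res.error_alt == pytest.approx(0.6 * np.sqrt(6.0 / (5.0 * 4.0)))

    def test_value_and_peak_forms_agree_on_sparse_ladder(self):
        vals = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
        a = periodicity(vals, intervals_from="peaks")
        b = periodicity(vals, intervals_from="values")
        assert a.interval == pytest.approx(b.interval, abs=0.02)

    def test_noisy_dimer_ladder_recovers_period_two(self):
        rng = np.random.default_rng(77)
        hits = 0
        for _ in range(20):
            vals = 2.0 * np.arange(1, 21) + rng.normal(0, 0.3, 20)
            res = periodicity(vals)
            hits += 1.7 <= res.interval <= 2.3
        assert hits >= 18

    def test_multiply_occupied_levels_still_recover_period(self):
        # occupancy ~25 tracks per level with noise growing as sqrt(S): the
        # peak-interval form stays near the true period for most realizations
        rng = np.random.default_rng(5)
        estimates = []
        for _ in range(12):
            k = rng.integers(1, 19, size=450)
            vals = 2.0 * k + rng.normal(0, 0.18 * np.sqrt(2.0 * k))
            estimates.append(periodicity(vals).interval)
        # individual realizations scatter ~+/-0.3 around the true period;
        # the median is the stable summary and no estimate may land on a
        # harmonic (~4) or collapse to the sub-resolution regime (<1)
        assert 1.7 <= np.median(estimates) <= 2.3
        assert min(estimates) > 1.2 and max(estimates) < 3.5

    def test_too_few_values_rejected(self):
        with pytest.raises(ParameterError):
            periodicity(np.array([2.0, 4.0]))
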