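import numpy as np
import pytest

from abquant.isoquant import (
    CalibrationCurve,
    IsoEstimate,
    RatioMeasurement,
    estimate_sample,
    fit_calibration,
    marker_ratio,
    matrix_effect_check,
    predict_fraction,
)
from abquant.spectra import match_fragments
from abquant.synthdata import (
    SpectrumSimConfig,
    _default_iso_profile,
    simulate_calibration_series,
    simulate_spectrum,
)


def ratio_at(fraction, config, seed, ladder, marker="b6", base="b11"):
    spectrum = simulate_spectrum(fraction, config, seed)
    return marker_ratio(match_fragments(spectrum, ladder), marker, base)


def curve_from_series(series, ladder, marker="b6", base="b11"):
    measurements = [
        (
            fraction,
            marker_ratio(match_fragments(s, ladder), marker, base),
        )
        for fraction, s in series
    ]
    return fit_calibration(measurements, marker=marker, base=base)


class TestRatioMeasurement:
    def test_validates_labels(self):
        with pytest.raises(ValueError):
            RatioMeasurement("s", "b5", "b11", 0.5)
        with pytest.raises(ValueError):
            RatioMeasurement("s", "b6", "b9", 0.5)

    def test_valid(self):
        m = RatioMeasurement("s", "y10", "y11", 0.5, n_spectra=20)
        assert m.ratio == 0.5


class TestMarkerRatio:
    def test_simple_arithmetic(self, ladder_1_16, noiseless_config):
        spectrum = simulate_spectrum(0.0, noiseless_config, seed=0)
        matches = match_fragments(spectrum, ladder_1_16)
        # default profile: b6 = 40, b11 = 100
        assert marker_ratio(matches) == pytest.approx(0.4)

    def test_missing_base_is_error(self, ladder_1_16, noiseless_config):
        spectrum = simulate_spectrum(0.0, noiseless_config, seed=0)
        matches = match_fragments(spectrum, ladder_1_16)
        matches.matches = {
            ion: (None if ion.label == "b11" else peak)
            for ion, peak in matches.matches.items()
        }
        with pytest.raises(ValueError, match="base fragment missing"):
            marker_ratio(matches)

    def test_missing_marker_warns_and_returns_zero(
        self, ladder_1_16, noiseless_config
    ):
        spectrum = simulate_spectrum(0.0, noiseless_config, seed=0)
        matches = match_fragments(spectrum, ladder_1_16)
        matches.matches = {
            ion: (None if ion.label == "b6" else peak)
            for ion, peak in matches.matches.items()
        }
        with pytest.warns(UserWarning, match="marker"):
            assert marker_ratio(matches) == 0.0

    def test_strictly_increasing_in_fraction_at_zero_noise(
        self, ladder_1_16, noiseless_config
    ):
        ratios = [
            ratio_at(f, noiseless_config, 0, ladder_1_16)
            for f in range(0, 101, 10)
        ]
        assert all(b > a for a, b in zip(ratios, ratios[1:]))


class TestFitCalibration:
    def test_exact_line(self):
        curve = fit_calibration([(0, 0.2), (50, 0.6), (100, 1.0)])
        assert curve.fit_kind == "linear"
        assert curve.slope == pytest.approx(0.008)
        assert curve.intercept == pytest.approx(0.2)
        assert curve.residual_sd == pytest.approx(0.0, abs=1e-12)

    def test_too_few_fractions_rejected(self):
        with pytest.raises(ValueError, match="3 distinct"):
            fit_calibration([(0, 0.2), (100, 1.0)])

    def test_narrow_design_rejected(self):
        with pytest.raises(ValueError, match="50 percentage points"):
            fit_calibration([(0, 0.2), (10, 0.3), (20, 0.4)])

    def test_constant_ratios_rejected(self):
        points = [(f, 0.5) for f in range(0, 101, 10)]
        with pytest.raises(ValueError, match="non-monotone"):
            fit_calibration(points)

    def test_decreasing_ratios_rejected(self):
        points = [(f, 1.0 - f / 100) for f in range(0, 101, 10)]
        with pytest.raises(ValueError, match="non-monotone"):
            fit_calibration(points)

    def test_recovers_generator_slope(self, ladder_1_16):
        config = SpectrumSimConfig(noise_cv=0.05)
        series = simulate_calibration_series(10, 3, config, seed=7)
        curve = curve_from_series(series, ladder_1_16)
        # generator truth: ratio 0.4 at 0% to 0.8 at 100% -> slope 0.004
        n = len(series)
        se = curve.residual_sd / np.sqrt(
            np.sum((np.array([f for f, _ in series]) - 50.0) ** 2)
        )
        assert curve.slope == pytest.approx(0.004, abs=2 * se)

    def test_monotone_fallback_on_nonmonotone_means(self):
        rng = np.random.default_rng(0)
        measurements = []
        for fraction, mean in zip(
            (0, 25, 50, 75, 100), (0.2, 0.7, 0.3, 0.8, 1.0)
        ):
            for _ in range(3):
                measurements.append((fraction, mean + rng.normal(0, 0.01)))
        curve = fit_calibration(measurements)
        assert curve.fit_kind == "monotone"
        grid = np.linspace(0, 100, 101)
        assert np.all(np.diff(curve.predict_ratio(grid)) >= 0)

    def test_json_round_trip(self, tmp_path):
        curve = fit_calibration([(0, 0.2), (50, 0.6), (100, 1.0)])
        path = tmp_path / "curve.json"
        curve.to_json(path)
        loaded = CalibrationCurve.from_json(path)
        assert loaded.slope == pytest.approx(curve.slope)
        assert loaded.fit_kind == curve.fit_kind
        est = predict_fraction(loaded, 0.6)
        assert est.fraction_pct == pytest.approx(50.0)


class TestPredictFraction:
    @pytest.fixture
    def line_curve(self):
        return fit_calibration([(0, 0.2), (50, 0.6), (100, 1.0)])

    def test_midpoint(self, line_curve):
        est = predict_fraction(line_curve, 0.6)
        assert est.fraction_pct == pytest.approx(50.0)
        assert not est.clamped

    def test_below_range_clamped_to_zero(self, line_curve):
        est = predict_fraction(line_curve, 0.1)
        assert est.fraction_pct == 0.0
        assert est.clamped

    def test_above_range_clamped_to_hundred(self, line_curve):
        est = predict_fraction(line_curve, 1.5)
        assert est.fraction_pct == 100.0
        assert est.clamped

    def test_round_trip_identity_noise_free(
        self, ladder_1_16, noiseless_config
    ):
        series = simulate_calibration_series(10, 1, noiseless_config, seed=0)
        curve = curve_from_series(series, ladder_1_16)
        for fraction in range(0, 101, 10):
            ratio = ratio_at(fraction, noiseless_config, 0, ladder_1_16)
            est = predict_fraction(curve, ratio)
            assert est.fraction_pct == pytest.approx(fraction, abs=1.0)

    def test_estimate_bounds_enforced(self):
        with pytest.raises(ValueError):
            IsoEstimate(fraction_pct=120.0, sd_pct=1.0, n_spectra=1)


class TestEstimateSample:
    @pytest.fixture
    def noise_free_curve(self, ladder_1_16, noiseless_config):
        series = simulate_calibration_series(10, 1, noiseless_config, seed=0)
        return curve_from_series(series, ladder_1_16)

    def test_stochastic_recovery_at_30pct(self, noise_free_curve):
        config = SpectrumSimConfig(noise_cv=0.10)
        rng = np.random.default_rng(11)
        spectra = [
            simulate_spectrum(30.0, config, rng, replicate=i + 1)
            for i in range(20)
        ]
        est = estimate_sample(spectra, noise_free_curve)
        assert est.n_spectra == 20
        assert est.fraction_pct == pytest.approx(30.0, abs=5.0)

    def test_single_noise_free_spectrum_at_zero(
        self, noise_free_curve, noiseless_config
    ):
        spectrum = simulate_spectrum(0.0, noiseless_config, seed=5)
        est = estimate_sample([spectrum], noise_free_curve)
        assert est.fraction_pct == pytest.approx(0.0, abs=1e-6)

    def test_duplicated_spectra_give_identical_estimate_zero_sd(
        self, noise_free_curve
    ):
        spectrum = simulate_spectrum(40.0, SpectrumSimConfig(), seed=3)
        single = estimate_sample([spectrum], noise_free_curve)
        doubled = estimate_sample([spectrum, spectrum], noise_free_curve)
        assert doubled.fraction_pct == pytest.approx(single.fraction_pct)
        assert doubled.ratio_sd == pytest.approx(0.0, abs=1e-12)

    def test_empty_input_rejected(self, noise_free_curve):
        with pytest.raises(ValueError):
            estimate_sample([], noise_free_curve)

    def test_ratio_of_sums_mode_agrees_at_low_noise(self, noise_free_curve):
        config = SpectrumSimConfig(noise_cv=0.02)
        rng = np.random.default_rng(4)
        spectra = [
            simulate_spectrum(50.0, config, rng, replicate=i + 1)
            for i in range(20)
        ]
        mean_mode = estimate_sample(spectra, noise_free_curve)
        sum_mode = estimate_sample(
            spectra, noise_free_curve, averaging="ratio_of_sums"
        )
        assert sum_mode.fraction_pct == pytest.approx(
            mean_mode.fraction_pct, abs=2.0
        )

    def test_sd_decreases_with_replicate_count(self, noise_free_curve):
        # spread of the estimate across seeds shrinks from 5 to 20 spectra
        config = SpectrumSimConfig(noise_cv=0.10)
        estimates = {5: [], 20: []}
        for seed in range(100):
            rng = np.random.default_rng(seed)
            spectra = [
                simulate_spectrum(50.0, config, rng, replicate=i + 1)
                for i in range(20)
            ]
            estimates[5].append(
                estimate_sample(spectra[:5], noise_free_curve).fraction_pct
            )
            estimates[20].append(
                estimate_sample(spectra, noise_free_curve).fraction_pct
            )
        assert np.std(estimates[20]) < np.std(estimates[5])

    def test_marker_channel_equivalence(self, ladder_1_16, noiseless_config):
        # b6/b11 and y10/y11 calibrations agree on generator data
        series = simulate_calibration_series(10, 1, noiseless_config, seed=0)
        curve_b = curve_from_series(series, ladder_1_16, "b6", "b11")
        curve_y = curve_from_series(series, ladder_1_16, "y10", "y11")
        config = SpectrumSimConfig(noise_cv=0.08)
        rng = np.random.default_rng(21)
        spectra = [
            simulate_spectrum(40.0, config, rng, replicate=i + 1)
            for i in range(20)
        ]
        est_b = estimate_sample(spectra, curve_b, marker="b6", base="b11")
        est_y = estimate_sample(spectra, curve_y, marker="y10", base="y11")
        combined_sd = max(np.hypot(est_b.sd_pct, est_y.sd_pct), 1.0)
        assert abs(est_b.fraction_pct - est_y.fraction_pct) <= 3 * combined_sd


class TestMatrixEffect:
    def make_curve(self, rng, config, ladder, reps=3):
        series = simulate_calibration_series(10, reps, config, rng)
        return curve_from_series(series, ladder)

    def test_identical_curves_comparable_with_p_one(self):
        curve = fit_calibration(
            [(f, 0.2 + 0.006 * f + 0.01 * (-1) ** i)
             for i, f in enumerate(range(0, 101, 10))]
        )
        report = matrix_effect_check([curve, curve])
        assert report.comparable
        for comparison in report.comparisons:
            assert comparison["slope_p"] == pytest.approx(1.0)
            assert comparison["intercept_p"] == pytest.approx(1.0)

    def test_requires_two_curves(self):
        curve = fit_calibration([(0, 0.2), (50, 0.6), (100, 1.0)])
        with pytest.raises(ValueError):
            matrix_effect_check([curve])

    def test_mismatched_designs_rejected(self):
        a = fit_calibration([(0, 0.2), (50, 0.6), (100, 1.0)])
        b = fit_calibration([(0, 0.2), (25, 0.4), (50, 0.6), (100, 1.0)])
        with pytest.raises(ValueError, match="mismatched designs"):
            matrix_effect_check([a, b])

    def test_doubled_slope_flagged(self, ladder_1_16):
        rng = np.random.default_rng(1)
        config = SpectrumSimConfig(noise_cv=0.05)
        # marker enhancement 3 doubles the calibration slope
        steep = SpectrumSimConfig(
            noise_cv=0.05, pure_iso_profile=_default_iso_profile(3.0)
        )
        report = matrix_effect_check(
            [
                self.make_curve(rng, config, ladder_1_16, reps=5),
                self.make_curve(rng, steep, ladder_1_16, reps=5),
            ]
        )
        assert not report.comparable

    def test_seed_only_differences_usually_comparable(self, ladder_1_16):
        config = SpectrumSimConfig(noise_cv=0.05)
        rng = np.random.default_rng(42)
        n_comparable = sum(
            matrix_effect_check(
                [
                    self.make_curve(rng, config, ladder_1_16),
                    self.make_curve(rng, config, ladder_1_16),
                ]
            ).comparable
            for _ in range(100)
        )
        assert n_comparable >= 90
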