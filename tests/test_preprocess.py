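"""The seven preprocessing steps against direct oracles and generator truth."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fcdraman.core import Spectrum, ValidationError, WavenumberAxis
from fcdraman.preprocess import (
    PreprocessConfig,
    average_accumulations,
    calibrate_wavenumber,
    correct_instrument_response,
    fit_wavenumber_map,
    normalize_snv,
    remove_baseline_rollingball,
    run_preprocessing,
    smooth_savitzky_golay,
    subtract_dark,
    truncate_axis,
)
from fcdraman.synthetic import (
    default_instrument,
    default_profiles,
    gaussian_bands,
    make_calibration_refs,
    simulate_dataset,
    simulate_spectrum,
)


def _spec(y, lo=700.0, hi=1700.0, stage="raw"):
    y = np.asarray(y, float)
    return Spectrum("t", WavenumberAxis(np.linspace(lo, hi, y.size)), y, stage=stage)


class TestAveraging:
    def test_single_accumulation_is_identity(self):
        s = _spec(np.arange(32.0))
        out = average_accumulations([s])
        np.testing.assert_array_equal(out.intensity, s.intensity)
        assert out.stage == "averaged"

    def test_constant_spectra_average_to_midpoint(self):
        out = average_accumulations([_spec(np.full(16, 2.0)), _spec(np.full(16, 4.0))])
        np.testing.assert_array_equal(out.intensity, np.full(16, 3.0))

    def test_matches_brute_force_mean(self, profiles, instrument):
        sim = simulate_spectrum(profiles["normal"], instrument, seed=8)
        out = average_accumulations(sim.accumulations)
        brute = np.stack([a.intensity for a in sim.accumulations]).mean(axis=0)
        np.testing.assert_allclose(out.intensity, brute, atol=1e-12)

    def test_empty_and_mismatched_axes_rejected(self):
        with pytest.raises(ValidationError):
            average_accumulations([])
        with pytest.raises(ValidationError):
            average_accumulations([_spec(np.ones(16)), _spec(np.ones(17))])


class TestDarkSubtraction:
    def test_subtracting_self_gives_zero(self):
        s = _spec(np.arange(16.0) + 5)
        out = subtract_dark(s, s)
        np.testing.assert_array_equal(out.intensity, np.zeros(16))

    def test_zero_dark_is_identity(self):
        s = _spec(np.arange(16.0))
        out = subtract_dark(s, _spec(np.zeros(16)))
        np.testing.assert_array_equal(out.intensity, s.intensity)
        assert out.stage == "dark_subtracted"

    def test_known_dark_level_removed(self, profiles, instrument):
        # after subtracting the dark reference the mean offset in a
        # signal-free window is gone to within the averaged noise level
        prof = type(profiles["normal"])(
            "normal", profiles["normal"].bands.iloc[:0], baseline_amplitude=0.0)
        sim = simulate_spectrum(prof, instrument, seed=2)  # dark + noise only
        refs = make_calibration_refs(instrument, np.random.default_rng(0))
        out = subtract_dark(sim.averaged, refs.dark)
        n = out.intensity.size
        noise_of_mean = instrument.dark_noise_sd / np.sqrt(10 * n)
        assert abs(out.intensity.mean()) < 5 * noise_of_mean


class TestResponseCorrection:
    def test_identity_response_leaves_spectrum_unchanged(self, instrument):
        flat = default_instrument(response_floor=1.0, response_gain=0.0)
        refs = make_calibration_refs(flat, np.random.default_rng(3))
        # remove the measurement noise so measured == certified exactly
        refs.response_measured.intensity = refs.response_certified.intensity.copy()
        s = Spectrum("t", flat.axis(), np.linspace(1, 2, 1024), stage="averaged")
        out = correct_instrument_response(s, refs)
        np.testing.assert_allclose(out.intensity, s.intensity, rtol=1e-3)

    def test_scale_invariance_of_the_standard(self, instrument, rng):
        refs = make_calibration_refs(instrument, rng)
        s = Spectrum("t", instrument.axis(), np.linspace(1, 2, 1024), stage="averaged")
        out1 = correct_instrument_response(s, refs)
        refs.response_measured.intensity *= 2.0  # doubled exposure
        out2 = correct_instrument_response(s, refs)
        np.testing.assert_allclose(out1.intensity, out2.intensity, rtol=1e-12)

    def test_recovers_flat_response_simulation(self, profiles):
        shaped = default_instrument(dark_level=0.0, dark_noise_sd=0.0, shot_scale=0.0)
        flat = default_instrument(dark_level=0.0, dark_noise_sd=0.0, shot_scale=0.0,
                                  response_floor=1.0, response_gain=0.0)
        prof = type(profiles["normal"])(
            "normal", profiles["normal"].bands.assign(height_cv=0.0), baseline_amplitude=0.0)
        sim_shaped = simulate_spectrum(prof, shaped, seed=4)
        sim_flat = simulate_spectrum(prof, flat, seed=4)
        refs = make_calibration_refs(shaped, np.random.default_rng(5))
        out = correct_instrument_response(sim_shaped.averaged, refs)
        a = out.intensity / np.mean(out.intensity)
        b = sim_flat.averaged.intensity / np.mean(sim_flat.averaged.intensity)
        rms = np.sqrt(np.mean((a - b) ** 2)) / np.sqrt(np.mean(b ** 2))
        assert rms < 0.01


class TestWavenumberCalibration:
    def _identity_refs(self, instrument, rng):
        refs = make_calibration_refs(instrument, rng)
        refs.wavenumber_ref_peaks["measured_position"] = \
            refs.wavenumber_ref_peaks["known_position"]
        return refs

    def test_identity_pairs_leave_axis_unchanged(self, instrument, rng):
        refs = self._identity_refs(instrument, rng)
        s = Spectrum("t", instrument.axis(), np.ones(1024), stage="averaged")
        out = calibrate_wavenumber(s, refs, degree=3)
        np.testing.assert_allclose(out.axis.values, s.axis.values, atol=1e-9)

    def test_residual_rms_zero_on_exact_polynomial_pairs(self, instrument, rng):
        refs = self._identity_refs(instrument, rng)
        _, rms = fit_wavenumber_map(refs, degree=3)
        assert rms == pytest.approx(0.0, abs=1e-9)

    def test_recovers_the_true_distortion_polynomial(self, instrument, rng):
        # reference pairs lie exactly on the instrument's cubic, so the
        # least-squares cubic must reproduce its coefficients
        refs = make_calibration_refs(instrument, rng)
        coeffs, rms = fit_wavenumber_map(refs, degree=3)
        np.testing.assert_allclose(coeffs, instrument.distortion_coeffs, rtol=1e-6)
        assert rms < 1e-6

    def test_too_few_pairs_rejected(self, instrument, rng):
        refs = make_calibration_refs(instrument, rng)
        refs.wavenumber_ref_peaks = refs.wavenumber_ref_peaks.iloc[:4]
        s = Spectrum("t", instrument.axis(), np.ones(1024), stage="averaged")
        calibrate_wavenumber(s, refs, degree=3)  # 4 pairs: exactly enough
        with pytest.raises(ValidationError):
            calibrate_wavenumber(s, refs, degree=4)

    def test_resampling_grid_hits_the_anchor(self, instrument, rng):
        refs = make_calibration_refs(instrument, rng)
        s = Spectrum("t", instrument.axis(), np.ones(1024), stage="averaged")
        out = calibrate_wavenumber(s, refs, degree=3, resample_spacing=1.1)
        k = np.round((out.axis.values - 700.0) / 1.1)
        np.testing.assert_allclose(out.axis.values, 700.0 + 1.1 * k, atol=1e-9)


class TestSavitzkyGolay:
    def test_reproduces_cubics_exactly(self):
        x = np.arange(64.0)
        y = 0.5 * x ** 3 - 2 * x ** 2 + x - 7
        out = smooth_savitzky_golay(_spec(y), order=3, window=11)
        np.testing.assert_allclose(out.intensity, y, rtol=1e-9)

    def test_interior_equals_windowed_least_squares_oracle(self, rng):
        # brute-force oracle: at every interior point, fit a cubic to the
        # 11 surrounding samples and evaluate at the center
        for _ in range(50):
            y = rng.normal(size=40)
            out = smooth_savitzky_golay(_spec(y), order=3, window=11).intensity
            for i in range(5, 35):
                idx = np.arange(i - 5, i + 6, dtype=float)
                expect = np.polyval(np.polyfit(idx, y[i - 5:i + 6], 3), float(i))
                assert out[i] == pytest.approx(expect, abs=1e-8)

    def test_white_noise_variance_contracts(self, rng):
        y = rng.normal(size=256)
        out = smooth_savitzky_golay(_spec(y), 3, 11)
        assert out.intensity.var() < y.var()

    def test_invalid_windows_rejected(self):
        with pytest.raises(ValidationError):
            smooth_savitzky_golay(_spec(np.ones(32)), 3, 10)
        with pytest.raises(ValidationError):
            smooth_savitzky_golay(_spec(np.ones(32)), 3, 3)


class TestRollingBall:
    def test_pure_exponential_baseline_removed(self):
        x = np.linspace(700, 1700, 910)
        amp = 1000.0
        y = amp * np.exp(-(x - 700.0) / 700.0)
        corrected, baseline = remove_baseline_rollingball(_spec(y), radius=120.0)
        rms = np.sqrt(np.mean(corrected.intensity ** 2))
        assert rms < 0.02 * amp

    def test_zero_input_gives_zero_baseline(self):
        corrected, baseline = remove_baseline_rollingball(_spec(np.zeros(910)), 120.0)
        np.testing.assert_array_equal(baseline.intensity, np.zeros(910))
        np.testing.assert_array_equal(corrected.intensity, np.zeros(910))

    def test_narrow_peak_on_linear_baseline_preserved(self):
        from scipy.optimize import curve_fit
        x = np.linspace(700, 1700, 910)
        true_h = 50.0
        peak = true_h * np.exp(-4 * np.log(2) * (x - 1200.0) ** 2 / 10.0 ** 2)
        y = peak + 0.05 * x + 10.0
        corrected, _ = remove_baseline_rollingball(_spec(y), radius=120.0)

        def g(x, h, mu, w, c):
            return h * np.exp(-4 * np.log(2) * (x - mu) ** 2 / w ** 2) + c

        m = np.abs(x - 1200) < 30
        popt, _ = curve_fit(g, x[m], corrected.intensity[m], p0=[40, 1200, 10, 0])
        assert popt[0] == pytest.approx(true_h, rel=0.05)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValidationError):
            remove_baseline_rollingball(_spec(np.ones(910)), radius=-1.0)


class TestTruncation:
    def test_closed_interval_bounds(self):
        s = Spectrum("t", WavenumberAxis(np.linspace(300, 1800, 1024)),
                     np.ones(1024), stage="smoothed")
        out = truncate_axis(s, 700, 1700)
        assert out.axis.values.min() >= 700 and out.axis.values.max() <= 1700

    def test_full_span_is_identity(self):
        s = _spec(np.arange(910.0))
        out = truncate_axis(s, 600, 1800)
        np.testing.assert_array_equal(out.intensity, s.intensity)

    def test_unit_grid_retains_1001_bins(self):
        s = Spectrum("t", WavenumberAxis(np.arange(300.0, 1801.0)),
                     np.ones(1501), stage="smoothed")
        assert len(truncate_axis(s, 700, 1700).axis) == 1001

    def test_empty_result_rejected(self):
        with pytest.raises(ValidationError):
            truncate_axis(_spec(np.ones(910)), 2000, 2100)


class TestSNV:
    def test_closed_form_three_points(self):
        out = normalize_snv(_spec([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(out.intensity, [-1.0, 0.0, 1.0], atol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(a=st.floats(0.1, 100), b=st.floats(-1000, 1000))
    def test_affine_invariance(self, a, b):
        y = np.sin(np.linspace(0, 7, 64)) + np.linspace(0, 1, 64)
        out1 = normalize_snv(_spec(y)).intensity
        out2 = normalize_snv(_spec(a * y + b)).intensity
        np.testing.assert_allclose(out1, out2, atol=1e-9)

    def test_mean_zero_sd_one(self, rng):
        out = normalize_snv(_spec(rng.normal(10, 3, 256)))
        assert out.intensity.mean() == pytest.approx(0.0, abs=1e-9)
        assert out.intensity.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_constant_spectrum_rejected(self):
        with pytest.raises(ValidationError):
            normalize_snv(_spec(np.full(32, 5.0)))


class TestFullChain:
    def test_outputs_are_snv_with_invariants(self, preprocessed):
        from fcdraman.core import validate_spectrum
        spectra, audit = preprocessed
        for s in spectra:
            assert s.stage == "snv"
            validate_spectrum(s)
        assert all(rec["n_bins_final"] == 910 for rec in audit)

    def test_order_independence_across_spectra(self, small_dataset):
        subset = small_dataset.spectra[:6]
        out_fwd, _ = run_preprocessing(subset, small_dataset.refs)
        out_rev, _ = run_preprocessing(subset[::-1], small_dataset.refs)
        rev_by_id = {s.spectrum_id: s for s in out_rev}
        for s in out_fwd:
            np.testing.assert_array_equal(s.intensity, rev_by_id[s.spectrum_id].intensity)

    def test_class_contrast_signs_survive_preprocessing(self, preprocessed,
                                                        small_dataset, profiles):
        from fcdraman.core import band_catalogue
        spectra, _ = preprocessed
        by_id = {s.spectrum_id: s for s in spectra}
        labels = small_dataset.meta.set_index("spectrum_id")["diagnosis"]
        x = spectra[0].axis.values

        def class_mean(diag):
            ids = labels.index[labels == diag]
            return np.mean([by_id[i].intensity for i in ids], axis=0)

        m_norm, m_iia, m_iib = (class_mean(d) for d in ("normal", "FCD_IIa", "FCD_IIb"))
        m_fcd = (m_iia * (labels == "FCD_IIa").sum()
                 + m_iib * (labels == "FCD_IIb").sum()) / (labels != "normal").sum()
        for band in band_catalogue():
            i = int(np.argmin(np.abs(x - band.position)))
            if band.fcd_vs_normal != "ns":
                sign = 1.0 if band.fcd_vs_normal == "FCD" else -1.0
                assert sign * (m_fcd[i] - m_norm[i]) > 0, f"band {band.position} (model 1)"
            if band.iia_vs_iib != "ns":
                sign = 1.0 if band.iia_vs_iib == "IIb" else -1.0
                assert sign * (m_iib[i] - m_iia[i]) > 0, f"band {band.position} (model 2)"

    def test_output_invariant_to_baseline_amplitude(self, profiles):
        # SNV after baseline removal: quadrupling the autofluorescence
        # amplitude changes the final spectrum by < 2% RMS. Checked in the
        # noiseless limit (shot noise necessarily grows with the baseline).
        quiet = default_instrument(dark_noise_sd=0.0, shot_scale=0.0)
        outs = []
        for amp_factor in (1.0, 4.0):
            prof = default_profiles(effect_scale=3.0)["normal"]
            prof.baseline_amplitude *= amp_factor
            prof.bands = prof.bands.assign(height_cv=0.0)
            ds = simulate_dataset({"normal": prof}, quiet, counts={"normal": 1},
                                  patients_per_class={"normal": 1}, seed=13,
                                  patient_sd=0.0)
            out, _ = run_preprocessing(ds.spectra, ds.refs)
            outs.append(out[0].intensity)
        rms = np.sqrt(np.mean((outs[0] - outs[1]) ** 2))
        assert rms < 0.02  # SNV output has unit SD

    def test_wrong_stage_rejected(self, small_dataset):
        s = small_dataset.spectra[0].with_(stage="smoothed")
        with pytest.raises(ValidationError):
            run_preprocessing([s], small_dataset.refs)
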