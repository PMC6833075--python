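"""Filtering, resampling, detrending, segmentation and augmentation oracles."""

import numpy as np
import pytest
from scipy import signal as sig

from painfusion.errors import ConfigurationError, SegmentationError, ValidationError
from painfusion.io import TrialLabel
from painfusion.preprocess import (
    AugmentationConfig,
    FilterSpec,
    SegmentationConfig,
    apply_filter,
    augment,
    default_filter_specs,
    design_filter,
    detrend_poly,
    preprocess_recording,
    resample,
    segment,
)
from painfusion.synthetic import MultiModalRecording


def _mag_db(sos, f_hz, fs_hz):
    w, h = sig.sosfreqz(sos, worN=[2 * np.pi * f_hz / fs_hz])
    return 20 * np.log10(np.abs(h[0]))


class TestResample:
    def test_identity_at_equal_rates(self, rng):
        x = rng.normal(size=1000)
        np.testing.assert_array_equal(resample(x, 256.0, 256.0), x)

    def test_half_rate_length(self):
        x = np.zeros(5120)  # 10 s at 512 Hz
        assert len(resample(x, 512.0, 256.0)) == 2560

    def test_sinusoid_preserved_under_decimation(self):
        t_in = np.arange(5120) / 512.0
        y = resample(np.sin(2 * np.pi * 5 * t_in), 512.0, 256.0)
        t_out = np.arange(len(y)) / 256.0
        ref = np.sin(2 * np.pi * 5 * t_out)
        # ignore filter edge effects
        r = np.corrcoef(y[100:-100], ref[100:-100])[0, 1]
        assert r > 0.999

    def test_upsampling_rejected(self):
        with pytest.raises(ConfigurationError, match="upsampling"):
            resample(np.zeros(100), 256.0, 512.0)


class TestFilterDesign:
    def test_eda_lowpass_is_3db_down_at_cutoff(self):
        spec = FilterSpec(order=3, kind="lowpass", band_hz=(0.2,), fs_hz=256.0)
        sos = design_filter(spec)
        assert _mag_db(sos, 0.2, 256.0) == pytest.approx(-3.0103, abs=0.1)

    def test_unit_dc_gain_for_lowpass(self):
        sos = design_filter(FilterSpec(order=3, kind="lowpass", band_hz=(0.2,), fs_hz=256.0))
        assert _mag_db(sos, 0.0, 256.0) == pytest.approx(0.0, abs=1e-6)

    def test_emg_band_lower_edge_after_nyquist_clipping(self):
        spec = FilterSpec(order=4, kind="bandpass", band_hz=(20.0, 250.0), fs_hz=256.0)
        with pytest.warns(UserWarning, match="clipping"):
            sos = design_filter(spec)
        assert _mag_db(sos, 20.0, 256.0) == pytest.approx(-3.0103, abs=0.1)

    def test_no_clipping_needed_at_native_rate(self):
        spec = FilterSpec(order=4, kind="bandpass", band_hz=(20.0, 250.0), fs_hz=512.0)
        assert spec.clipped().band_hz == (20.0, 250.0)

    def test_empty_band_after_clipping_rejected(self):
        spec = FilterSpec(order=4, kind="bandpass", band_hz=(130.0, 250.0), fs_hz=256.0)
        with pytest.warns(UserWarning):
            with pytest.raises(ConfigurationError, match="empty band"):
                design_filter(spec)


class TestApplyFilter:
    def test_dc_passes_eda_lowpass(self):
        sos = design_filter(FilterSpec(order=3, kind="lowpass", band_hz=(0.2,), fs_hz=256.0))
        x = np.full(4000, 3.7)
        np.testing.assert_allclose(apply_filter(sos, x), 3.7, atol=1e-6)

    def test_stopband_sinusoid_attenuated(self):
        sos = design_filter(FilterSpec(order=3, kind="lowpass", band_hz=(0.2,), fs_hz=256.0))
        t = np.arange(256 * 30) / 256.0
        x = np.sin(2 * np.pi * 50 * t)
        # a 0.2 Hz filter rings for seconds; evaluate away from the edges
        y = apply_filter(sos, x)[2048:-2048]
        assert np.sqrt(np.mean(y**2)) < 0.01 * np.sqrt(np.mean(x**2))

    def test_ecg_bandpass_rejects_very_slow_drift(self):
        spec = FilterSpec(order=3, kind="bandpass", band_hz=(0.1, 250.0), fs_hz=512.0)
        sos = design_filter(spec)
        t = np.arange(512 * 120) / 512.0
        x = np.sin(2 * np.pi * 0.05 * t)
        y = apply_filter(sos, x[: len(t)])
        assert np.sqrt(np.mean(y**2)) < 0.5 * np.sqrt(np.mean(x**2))

    def test_zero_phase_preserves_pulse_symmetry(self):
        sos = design_filter(FilterSpec(order=3, kind="lowpass", band_hz=(5.0,), fs_hz=256.0))
        n = 2001
        x = np.exp(-0.5 * ((np.arange(n) - n // 2) / 30.0) ** 2)
        y = apply_filter(sos, x)
        np.testing.assert_allclose(y, y[::-1], atol=1e-8)

    def test_linearity(self, rng):
        sos = design_filter(FilterSpec(order=3, kind="lowpass", band_hz=(0.2,), fs_hz=256.0))
        x, y = rng.normal(size=(2, 3000))
        lhs = apply_filter(sos, 2.5 * x - 1.5 * y)
        rhs = 2.5 * apply_filter(sos, x) - 1.5 * apply_filter(sos, y)
        np.testing.assert_allclose(lhs, rhs, atol=1e-8)

    def test_too_short_signal_rejected(self):
        sos = design_filter(FilterSpec(order=3, kind="lowpass", band_hz=(0.2,), fs_hz=256.0))
        with pytest.raises(ValidationError, match="too short"):
            apply_filter(sos, np.zeros(10))


class TestPreprocessRecording:
    def test_output_rate_and_eda_spectrum(self, native_rate_recording):
        out = preprocess_recording(native_rate_recording)
        assert out.fs_hz == 256.0
        assert out.n_samples == pytest.approx(native_rate_recording.n_samples / 2, abs=1)
        f, pxx = sig.periodogram(out.eda - out.eda.mean(), fs=256.0)
        high = pxx[f > 1.0].sum()
        assert high < 0.01 * pxx.sum()

    def test_zero_signals_stay_zero(self):
        n = 512 * 60
        rec = MultiModalRecording(
            subject_id="Z", fs_hz=512.0, eda=np.zeros(n), ecg=np.zeros(n), emg=np.zeros(n)
        )
        out = preprocess_recording(rec)
        for mod in ("eda", "ecg", "emg"):
            np.testing.assert_allclose(out.modality(mod), 0.0, atol=1e-12)


class TestDetrend:
    def test_quintic_removed_exactly(self, rng):
        x = np.linspace(-1, 1, 1152)
        coeffs = rng.normal(size=6)
        seg = np.polynomial.polynomial.polyval(x, coeffs) * 100
        out = detrend_poly(seg)
        assert np.max(np.abs(out)) < 1e-8 * max(1.0, np.max(np.abs(seg)))

    def test_zero_in_zero_out(self):
        np.testing.assert_allclose(detrend_poly(np.zeros(500)), 0.0, atol=1e-15)

    def test_projection_property(self, rng):
        seg = rng.normal(size=1152)
        once = detrend_poly(seg)
        twice = detrend_poly(once)
        np.testing.assert_allclose(twice, once, atol=1e-8)

    def test_sinusoid_recovered_from_planted_trend(self, rng):
        n = 1152
        t = np.arange(n) / 256.0
        wave = np.sin(2 * np.pi * 8 * t)
        trend = np.polynomial.polynomial.polyval(np.linspace(-1, 1, n), rng.normal(size=6)) * 50
        out = detrend_poly(wave + trend)
        assert np.corrcoef(out, wave)[0, 1] > 0.99

    def test_degenerate_length_rejected(self):
        with pytest.raises(ValidationError):
            detrend_poly(np.zeros(5), degree=5)


def _flat_recording(n, fs=256.0):
    sig_ = np.arange(n, dtype=float)
    return MultiModalRecording(
        subject_id="S000", fs_hz=fs, eda=sig_, ecg=sig_ * 0, emg=sig_ * 0.5
    )


class TestSegmentation:
    def test_example_window_indices(self):
        rec = _flat_recording(256 * 30)
        labels = [TrialLabel("S000", 0, "T0", 10.0)]
        segs = segment(rec, labels)
        # start = (10 + 4) * 256 = 3584, half-open end = 4736
        np.testing.assert_array_equal(
            segs["eda"].data[0, :, 0], np.arange(3584, 4736, dtype=float)
        )

    def test_window_length_is_1152_at_defaults(self, tiny_recording):
        labels = [TrialLabel("S000", 0, "T0", 10.0)]
        segs = segment(tiny_recording, labels)
        for mod in ("eda", "emg", "ecg"):
            assert segs[mod].data.shape == (1, 1152, 1)

    def test_one_window_per_trial_per_modality(self, tiny_recording, tiny_config):
        from painfusion.synthetic import make_schedule
        from painfusion.synthetic import _labels_for

        labels = _labels_for(tiny_recording.schedule, "S000")
        segs = segment(tiny_recording, labels)
        n_trials = tiny_config.trials_per_subject
        for mod in ("eda", "emg", "ecg"):
            assert segs[mod].n_windows == n_trials
            assert not segs[mod].is_augmented.any()

    def test_brute_force_index_oracle_on_randomized_onsets(self, rng):
        """Window contents must equal the raw signal at indices computed by
        independent brute-force arithmetic, for 1000 random onsets."""
        fs = 256.0
        n = int(256 * 4000)
        rec = _flat_recording(n)
        onsets = np.round(rng.uniform(0.0, 3990.0, size=1000), 3)
        labels = [TrialLabel("S000", i, "T0", float(o)) for i, o in enumerate(sorted(set(onsets)))]
        segs = segment(rec, labels)
        for row, lab_onset in enumerate(sorted(set(onsets))):
            start = int(round((lab_onset + 4.0) * fs))
            expected = np.arange(start, start + 1152, dtype=float)
            np.testing.assert_array_equal(segs["eda"].data[row, :, 0], expected)

    def test_window_past_recording_end_raises(self):
        rec = _flat_recording(256 * 12)
        labels = [TrialLabel("S000", 7, "T0", 5.0)]  # needs samples up to 13.5 s
        with pytest.raises(SegmentationError, match="trial 7"):
            segment(rec, labels)

    def test_ecg_windows_are_detrended(self):
        n = 256 * 30
        t = np.arange(n) / 256.0
        drift = 0.001 * t**2
        rec = MultiModalRecording(
            subject_id="S", fs_hz=256.0, eda=np.zeros(n), ecg=drift, emg=np.zeros(n)
        )
        segs = segment(rec, [TrialLabel("S", 0, "T0", 10.0)])
        assert np.max(np.abs(segs["ecg"].data)) < 1e-8  # quadratic fully removed


class TestAugmentation:
    def test_default_shift_grid_gives_8_augmented_windows(self):
        rec = _flat_recording(256 * 40)
        labels = [TrialLabel("S000", 0, "T0", 15.0)]
        segs = augment(rec, labels)
        assert segs["eda"].n_windows == 9
        assert segs["eda"].is_augmented.sum() == 8
        assert set(segs["eda"].labels) == {"T0"}

    def test_single_step_gives_two_augmented_windows(self):
        rec = _flat_recording(256 * 40)
        labels = [TrialLabel("S000", 0, "T4", 15.0)]
        segs = augment(rec, labels, aug_cfg=AugmentationConfig(step_s=0.25, max_shift_s=0.25))
        assert segs["eda"].n_windows == 3
        assert segs["eda"].is_augmented.sum() == 2

    def test_augmented_window_contents_match_shifts(self):
        rec = _flat_recording(256 * 40)
        labels = [TrialLabel("S000", 0, "T0", 15.0)]
        segs = augment(rec, labels, aug_cfg=AugmentationConfig(step_s=0.5, max_shift_s=0.5))
        starts = sorted(int(segs["eda"].data[i, 0, 0]) for i in range(3))
        base = int(round((15.0 + 4.0) * 256))
        assert starts == [base - 128, base, base + 128]

    def test_out_of_bounds_shifts_skipped_with_warning(self):
        rec = _flat_recording(int(256 * 23.6))  # base window barely fits
        labels = [TrialLabel("S000", 0, "T0", 15.0)]
        with pytest.warns(UserWarning, match="out-of-bounds"):
            segs = augment(rec, labels)
        assert segs["eda"].n_windows < 9
        assert (~segs["eda"].is_augmented).sum() == 1

    def test_non_integer_shift_grid_rejected(self):
        with pytest.raises(ConfigurationError):
            AugmentationConfig(step_s=0.3, max_shift_s=1.0).validate()
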