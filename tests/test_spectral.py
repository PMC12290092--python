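import numpy as np
import pandas as pd
import pytest
from scipy import signal as scipy_signal

from laminar_ephys.preprocess import ExclusionMask
from laminar_ephys.recording import LaminarLFP, TrialTable
from laminar_ephys.spectral import (band_bins, band_power, band_power_linear,
                                    depth_psd, gamma_change_summary,
                                    mean_power_over_sets, session_spectra,
                                    stft_centers, stft_spectrogram,
                                    stimulus_psd_change)

FS = 2500.0


def make_lfp(values, fs=FS):
    values = np.atleast_2d(values)
    return LaminarLFP(values=values, sampling_rate_hz=fs,
                      depth_um=20.0 * np.arange(values.shape[0]))


def visual_trials(onsets):
    return TrialTable(pd.DataFrame({
        "trial_id": range(len(onsets)), "modality": "visual",
        "onset_s": onsets, "n_stimuli": 1, "stim_param": ""}))


class TestSTFT:
    def test_matches_scipy_spectrogram_exactly(self):
        # scipy is the independent oracle for the streaming implementation
        rng = np.random.default_rng(0)
        x = rng.standard_normal(30000)
        f, t, S = scipy_signal.spectrogram(
            x, fs=FS, window="hamming", nperseg=5000, noverlap=4750,
            detrend=False, scaling="density", mode="psd")
        spec = stft_spectrogram(x, FS)
        np.testing.assert_allclose(spec.freq_hz, f)
        np.testing.assert_allclose(spec.time_s, t)
        np.testing.assert_allclose(spec.power, S.T, rtol=1e-10, atol=1e-15)

    def test_sinusoid_peaks_at_its_frequency(self):
        t = np.arange(int(10 * FS)) / FS
        spec = stft_spectrogram(np.sin(2 * np.pi * 70.0 * t), FS)
        peak = spec.freq_hz[np.argmax(spec.power.mean(axis=0))]
        assert peak == pytest.approx(70.0)

    def test_dc_signal_concentrates_at_zero(self):
        spec = stft_spectrogram(np.full(int(6 * FS), 2.0), FS)
        mean_p = spec.power.mean(axis=0)
        assert np.argmax(mean_p) == 0
        assert mean_p[4:].max() < 1e-20 * mean_p[0]

    def test_white_noise_parseval_within_5pct(self):
        rng = np.random.default_rng(1)
        s = 0.7
        x = rng.normal(0, s, int(60 * FS))
        spec = stft_spectrogram(x, FS)
        total = spec.power.mean(axis=0).sum() * spec.df_hz
        assert total == pytest.approx(s**2, rel=0.05)

    def test_parseval_holds_at_other_rates_and_windows(self):
        rng = np.random.default_rng(2)
        for fs, win in ((1000.0, 1.0), (500.0, 4.0)):
            x = rng.normal(0, 1.3, int(60 * fs))
            spec = stft_spectrogram(x, fs, window_s=win, step_s=win / 4)
            total = spec.power.mean(axis=0).sum() * spec.df_hz
            assert total == pytest.approx(1.3**2, rel=0.05)

    def test_streaming_means_equal_full_spectrogram_means(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(20000)
        spec = stft_spectrogram(x, FS)
        sets = [np.arange(spec.time_s.size) % 2 == 0,
                spec.time_s > 3.0]
        means = mean_power_over_sets(x, FS, sets)
        for m, mask in zip(means, sets):
            np.testing.assert_allclose(m, spec.power[mask].mean(axis=0))


class TestDepthPSD:
    def test_halving_amplitude_lowers_psd_6db(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(int(30 * FS))
        a = depth_psd(make_lfp(x))
        b = depth_psd(make_lfp(x / 2))
        np.testing.assert_allclose(a.power_dbmv - b.power_dbmv,
                                   20 * np.log10(2), rtol=1e-9)

    def test_excluded_transient_does_not_contaminate(self):
        rng = np.random.default_rng(5)
        clean = rng.standard_normal(int(60 * FS))
        dirty = clean.copy()
        dirty[int(20 * FS):int(25 * FS)] += 50.0 * rng.standard_normal(int(5 * FS))
        mask = ExclusionMask(np.array([[18.0, 27.0]]))
        psd_dirty = depth_psd(make_lfp(dirty), mask)
        centers, _ = stft_centers(clean.size, FS)
        keep = ~mask.contains(centers)
        spec = stft_spectrogram(clean, FS)
        expected = 10 * np.log10(spec.power[keep].mean(axis=0))
        np.testing.assert_allclose(psd_dirty.power_dbmv[0], expected, atol=0.2)

    def test_all_excluded_is_error(self):
        x = np.random.default_rng(6).standard_normal(int(30 * FS))
        with pytest.raises(ValueError):
            depth_psd(make_lfp(x), ExclusionMask(np.array([[0.0, 40.0]])))

    def test_time_shift_invariance(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(int(30 * FS))
        a = depth_psd(make_lfp(x))
        shifted = make_lfp(x)
        shifted.start_time_s = 123.0
        b = depth_psd(shifted)
        np.testing.assert_array_equal(a.power_dbmv, b.power_dbmv)


class TestBandPower:
    def test_flat_reference_is_zero_dbmv(self):
        psd_vals = np.zeros((2, 241))  # 0 dB everywhere = 1 mV^2/Hz
        from laminar_ephys.spectral import DepthPSD
        psd = DepthPSD(depth_um=np.array([0.0, 20.0]),
                       freq_hz=0.5 * np.arange(241), power_dbmv=psd_vals)
        assert band_power(psd, (30, 120)) == 0.0

    def test_band_snapping_gives_181_bins(self):
        freq = 0.5 * np.arange(0, 2501)
        mask = band_bins(freq, (30.0, 120.0))
        assert mask.sum() == 181

    def test_injected_gamma_raises_only_gamma_band(self):
        rng = np.random.default_rng(8)
        base = rng.standard_normal(int(60 * FS))
        t = np.arange(base.size) / FS
        with_gamma = base + 0.5 * np.sin(2 * np.pi * 70.0 * t)
        a = depth_psd(make_lfp(base))
        b = depth_psd(make_lfp(with_gamma))
        # a spectral line lifts the dB-mean scalar modestly but the linear
        # band power massively; the low band must not move at all
        assert band_power(b, (30, 120)) > band_power(a, (30, 120)) + 0.15
        assert band_power_linear(b, (30, 120)) > band_power_linear(a, (30, 120)) + 3.0
        assert band_power(b, (0.5, 10)) == pytest.approx(
            band_power(a, (0.5, 10)), abs=0.01)

    def test_linear_and_db_reductions_differ_predictably(self):
        from laminar_ephys.spectral import DepthPSD
        psd = DepthPSD(depth_um=np.array([0.0]), freq_hz=np.array([30.0, 30.5]),
                       power_dbmv=np.array([[0.0, 20.0]]))
        assert band_power(psd, (30, 30.5)) == pytest.approx(10.0)
        assert band_power_linear(psd, (30, 30.5)) == pytest.approx(
            10 * np.log10((1 + 100) / 2))


class TestStimulusPSDChange:
    def _burst_session(self, amp, seed=9, n_trials=12):
        rng = np.random.default_rng(seed)
        dur = 10.0 + n_trials * 9.0
        x = rng.standard_normal(int(dur * FS))
        onsets = 5.0 + 9.0 * np.arange(n_trials)
        t = np.arange(x.size) / FS
        for on in onsets:
            seg = slice(int(on * FS), int((on + 5.0) * FS))
            x[seg] += amp * np.sin(2 * np.pi * 70.0 * t[seg])
        return make_lfp(x), visual_trials(onsets)

    def test_no_stimulus_effect_is_near_zero(self):
        lfp, trials = self._burst_session(0.0)
        change = stimulus_psd_change(lfp, trials)
        assert abs(gamma_change_summary(change)) < 15.0

    def test_burst_produces_peak_near_70hz(self):
        lfp, trials = self._burst_session(0.8)
        change = stimulus_psd_change(lfp, trials)
        peak = change.freq_hz[int(np.nanargmax(change.percent[0]))]
        assert 60.0 <= peak <= 80.0

    def test_rescaling_recording_leaves_percent_change_unchanged(self):
        lfp, trials = self._burst_session(0.8)
        a = stimulus_psd_change(lfp, trials)
        scaled = make_lfp(lfp.values * 5.0)
        b = stimulus_psd_change(scaled, trials)
        np.testing.assert_allclose(a.percent, b.percent, rtol=1e-9)

    def test_doubled_power_reads_plus_100pct(self):
        # noise variance exactly doubles during 5-s "stimulation" periods
        rng = np.random.default_rng(10)
        n_trials = 30
        dur = 10.0 + n_trials * 9.0
        x = rng.standard_normal(int(dur * FS))
        onsets = 5.0 + 9.0 * np.arange(n_trials)
        for on in onsets:
            x[int(on * FS):int((on + 5.0) * FS)] *= np.sqrt(2.0)
        change = stimulus_psd_change(make_lfp(x), visual_trials(onsets))
        mean_over_freq = np.nanmean(change.percent[0])
        assert mean_over_freq == pytest.approx(100.0, abs=10.0)

    def test_session_spectra_matches_separate_ops(self):
        lfp, trials = self._burst_session(0.5, n_trials=6)
        psd_a = depth_psd(lfp)
        change_a = stimulus_psd_change(lfp, trials)
        psd_b, change_b = session_spectra(lfp, trials)
        np.testing.assert_allclose(psd_b.power_dbmv, psd_a.power_dbmv)
        np.testing.assert_allclose(change_b.percent, change_a.percent,
                                   equal_nan=True)
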