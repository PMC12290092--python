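"""Spectrograms, depth-resolved PSD in dBmV, and stimulus-induced PSD change.

All spectral estimates share one short-time Fourier machinery: Hamming-tapered
windows of 2 s advanced in 0.1-s steps (0.5 Hz frequency resolution, 95 %
overlap), normalized as one-sided power spectral density in mV^2/Hz so that
white noise of variance s^2 has mean density s^2/(fs/2).  "dBmV" throughout
means 10*log10(PSD / 1 mV^2/Hz); the absolute dB values quoted anywhere in
this package depend on that reference.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sig

from .preprocess import ExclusionMask, filter_trials
from .recording import LaminarLFP, TrialTable

log = logging.getLogger(__name__)

GAMMA_BAND_HZ = (30.0, 120.0)


@dataclass
class Spectrogram:
    """Windowed PSD estimates: ``power[t, f]`` in mV^2/Hz at window centers."""
    time_s: np.ndarray
    freq_hz: np.ndarray
    power: np.ndarray

    @property
    def df_hz(self) -> float:
        return float(self.freq_hz[1] - self.freq_hz[0])


@dataclass
class DepthPSD:
    """Session-mean PSD per depth row, in dB re 1 mV^2/Hz."""
    depth_um: np.ndarray
    freq_hz: np.ndarray
    power_dbmv: np.ndarray  # (n_depth, n_freq); -inf where raw power was 0


@dataclass
class PSDChange:
    """Stimulus-induced percent PSD change per depth row and frequency bin."""
    depth_um: np.ndarray
    freq_hz: np.ndarray
    percent: np.ndarray        # (n_depth, n_freq)
    flagged: np.ndarray        # bins with zero baseline power, excluded from summaries
    n_trials: int


def _stft_plan(n_samples: int, fs_hz: float, window_s: float, step_s: float):
    """Window, scale, frequency bins and center times of the moving STFT."""
    nperseg = int(np.round(window_s * fs_hz))
    step = int(np.round(step_s * fs_hz))
    if n_samples < nperseg:
        raise ValueError("signal shorter than one STFT window")
    if step > nperseg:
        log.warning("STFT step (%g s) exceeds the window (%g s); gaps between "
                    "windows", step_s, window_s)
    win = sig.get_window("hamming", nperseg)
    scale = 1.0 / (fs_hz * (win**2).sum())  # PSD (density) normalization
    n_windows = (n_samples - nperseg) // step + 1
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / fs_hz)
    times = (nperseg / 2.0 + step * np.arange(n_windows)) / fs_hz
    return nperseg, step, win, scale, freqs, times


def _stft_power_chunks(signal: np.ndarray, nperseg: int, step: int,
                       win: np.ndarray, scale: float, chunk: int = 256):
    """Yield (start_index, power_block) over window chunks.

    Chunked so the strided frame matrix never materializes at once; power is
    the one-sided Hamming periodogram density (DC and Nyquist not doubled),
    identical to scipy's spectrogram with ``detrend=False, mode='psd'``.
    """
    frames = np.lib.stride_tricks.sliding_window_view(signal, nperseg)[::step]
    n_windows = frames.shape[0]
    for c0 in range(0, n_windows, chunk):
        block = frames[c0:c0 + chunk] * win
        X = np.fft.rfft(block, axis=1)
        P = (X.real**2 + X.imag**2) * scale
        P[:, 1:-1 if nperseg % 2 == 0 else None] *= 2.0
        yield c0, P


def stft_spectrogram(signal: np.ndarray, fs_hz: float, window_s: float = 2.0,
                     step_s: float = 0.1) -> Spectrogram:
    """Moving-window Hamming periodogram, PSD-normalized.

    Reported times are window centers; normalization is power spectral
    density in mV^2/Hz (taper power compensated), so white noise of variance
    s^2 has mean density s^2/(fs/2).  A step larger than the window leaves
    gaps and only warns.
    """
    signal = np.asarray(signal, dtype=float)
    nperseg, step, win, scale, freqs, times = _stft_plan(
        signal.size, fs_hz, window_s, step_s)
    power = np.empty((times.size, freqs.size))
    for c0, P in _stft_power_chunks(signal, nperseg, step, win, scale):
        power[c0:c0 + P.shape[0]] = P
    return Spectrogram(time_s=times, freq_hz=freqs, power=power)


def mean_power_over_sets(signal: np.ndarray, fs_hz: float,
                         window_sets: list[np.ndarray],
                         window_s: float = 2.0, step_s: float = 0.1
                         ) -> list[np.ndarray]:
    """Mean STFT power over each boolean set of window indices, in one pass.

    ``window_sets`` are boolean masks over the window centers (see
    :func:`stft_centers`).  Streaming accumulation: the full spectrogram is
    never materialized, which is what makes many-row sessions tractable.
    An empty set yields an all-NaN row.
    """
    signal = np.asarray(signal, dtype=float)
    nperseg, step, win, scale, freqs, times = _stft_plan(
        signal.size, fs_hz, window_s, step_s)
    sums = [np.zeros(freqs.size) for _ in window_sets]
    counts = [0] * len(window_sets)
    for c0, P in _stft_power_chunks(signal, nperseg, step, win, scale):
        sl = slice(c0, c0 + P.shape[0])
        for i, mask in enumerate(window_sets):
            m = mask[sl]
            if m.any():
                sums[i] += P[m].sum(axis=0)
                counts[i] += int(m.sum())
    return [s / c if c else np.full(freqs.size, np.nan)
            for s, c in zip(sums, counts)]


def stft_centers(n_samples: int, fs_hz: float, window_s: float = 2.0,
                 step_s: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Window-center times and frequency bins of the moving STFT."""
    _, _, _, _, freqs, times = _stft_plan(n_samples, fs_hz, window_s, step_s)
    return times, freqs


def band_bins(freq_hz: np.ndarray, band_hz: tuple[float, float]) -> np.ndarray:
    """Boolean bin mask; band edges snap to the nearest bins, inclusive."""
    lo, hi = band_hz
    if hi <= lo:
        raise ValueError("empty frequency band")
    lo_snap = freq_hz[np.argmin(np.abs(freq_hz - lo))]
    hi_snap = freq_hz[np.argmin(np.abs(freq_hz - hi))]
    return (freq_hz >= lo_snap) & (freq_hz <= hi_snap)


def depth_psd(lfp: LaminarLFP, exclude: ExclusionMask | None = None,
              window_s: float = 2.0, step_s: float = 0.1) -> DepthPSD:
    """Session PSD per depth row, averaging spectrogram windows whose centers
    fall outside the exclusion mask; result in dB re 1 mV^2/Hz."""
    if exclude is None:
        exclude = ExclusionMask.empty()
    times, freq = stft_centers(lfp.n_samples, lfp.sampling_rate_hz,
                               window_s, step_s)
    keep = ~exclude.contains(lfp.start_time_s + times)
    if not keep.any():
        raise ValueError("all spectrogram windows are excluded")
    kept_span = keep.sum() * step_s
    if kept_span < 10.0:
        raise ValueError(
            f"only {kept_span:.1f} s survive exclusion; need >= 10 s")
    power = np.empty((lfp.values.shape[0], freq.size))
    for i in range(lfp.values.shape[0]):
        power[i] = mean_power_over_sets(lfp.values[i], lfp.sampling_rate_hz,
                                        [keep], window_s, step_s)[0]
    with np.errstate(divide="ignore"):
        dbmv = 10.0 * np.log10(power)
    n_zero = int(np.sum(~np.isfinite(dbmv)))
    if n_zero:
        log.warning("depth_psd: %d bins had exactly zero power (reported -inf)",
                    n_zero)
    return DepthPSD(depth_um=lfp.depth_um, freq_hz=freq, power_dbmv=dbmv)


def band_power(psd: DepthPSD, band_hz: tuple[float, float] = GAMMA_BAND_HZ,
               depth_range_um: tuple[float, float] | None = None) -> float:
    """Session scalar: mean of the dB values over band bins and depth rows.

    Averaging is done on the dB scale (not dB of the linear mean); see
    :func:`band_power_linear` for the alternative reduction.
    """
    fmask = band_bins(psd.freq_hz, band_hz)
    dmask = _depth_mask(psd.depth_um, depth_range_um)
    return float(psd.power_dbmv[np.ix_(dmask, fmask)].mean())


def band_power_linear(psd: DepthPSD, band_hz: tuple[float, float] = GAMMA_BAND_HZ,
                      depth_range_um: tuple[float, float] | None = None) -> float:
    """Alternative session scalar: dB of the linear-mean band power."""
    fmask = band_bins(psd.freq_hz, band_hz)
    dmask = _depth_mask(psd.depth_um, depth_range_um)
    lin = 10.0 ** (psd.power_dbmv[np.ix_(dmask, fmask)] / 10.0)
    return float(10.0 * np.log10(lin.mean()))


def _depth_mask(depth_um: np.ndarray,
                depth_range_um: tuple[float, float] | None) -> np.ndarray:
    if depth_range_um is None:
        return np.ones(depth_um.size, dtype=bool)
    lo, hi = depth_range_um
    mask = (depth_um >= lo) & (depth_um <= hi)
    if not mask.any():
        raise ValueError("no depth rows in the requested range")
    return mask


def stimulus_psd_change(lfp: LaminarLFP, trials: TrialTable,
                        stim_window_s: tuple[float, float] = (1.0, 4.0),
                        base_window_s: tuple[float, float] = (-2.0, -1.0),
                        exclude: ExclusionMask | None = None,
                        window_s: float = 2.0, step_s: float = 0.1,
                        depth_range_um: tuple[float, float] | None = None
                        ) -> PSDChange:
    """Percent PSD change during stimulation relative to pre-stimulus baseline.

    Per depth row and frequency bin: 100 * (P_stim - P_base) / P_base, with
    P_stim and P_base the means over all spectrogram windows whose centers
    fall in the respective onset-relative windows, pooled across surviving
    trials.  Bins with zero baseline power are flagged and left out of any
    summary.  The statistic is a ratio, hence invariant to rescaling the
    whole recording.
    """
    if exclude is None:
        exclude = ExclusionMask.empty()
    lo = min(base_window_s[0], stim_window_s[0], 0.0)
    hi = max(base_window_s[1], stim_window_s[1], 0.0)
    trials = filter_trials(trials, exclude, (lo, hi))
    if not len(trials):
        raise ValueError("no trials survive the exclusion mask")
    times, freq = stft_centers(lfp.n_samples, lfp.sampling_rate_hz,
                               window_s, step_s)
    s_mask, b_mask = trial_window_sets(lfp.start_time_s + times,
                                       trials.onsets(), stim_window_s,
                                       base_window_s)
    dmask = _depth_mask(lfp.depth_um, depth_range_um)
    rows = np.flatnonzero(dmask)
    p_stim = np.empty((rows.size, freq.size))
    p_base = np.empty((rows.size, freq.size))
    for out_i, i in enumerate(rows):
        p_stim[out_i], p_base[out_i] = mean_power_over_sets(
            lfp.values[i], lfp.sampling_rate_hz, [s_mask, b_mask],
            window_s, step_s)
    flagged = p_base == 0.0
    if flagged.any():
        log.warning("stimulus_psd_change: %d bins with zero baseline power "
                    "flagged", int(flagged.sum()))
    percent = np.full_like(p_stim, np.nan)
    ok = ~flagged
    percent[ok] = 100.0 * (p_stim[ok] - p_base[ok]) / p_base[ok]
    return PSDChange(depth_um=lfp.depth_um[rows], freq_hz=freq,
                     percent=percent, flagged=flagged, n_trials=len(trials))


def session_spectra(lfp: LaminarLFP, visual_trials: TrialTable,
                    exclude: ExclusionMask | None = None,
                    stim_window_s: tuple[float, float] = (1.0, 4.0),
                    base_window_s: tuple[float, float] = (-2.0, -1.0),
                    window_s: float = 2.0, step_s: float = 0.1,
                    depth_range_um: tuple[float, float] | None = None
                    ) -> tuple[DepthPSD, PSDChange]:
    """Session PSD and stimulus-induced change in a single STFT pass per row.

    Numerically identical to running :func:`depth_psd` and
    :func:`stimulus_psd_change` separately (the three window sets share one
    streaming spectrogram), at half the cost; used by the pipeline.
    """
    if exclude is None:
        exclude = ExclusionMask.empty()
    lo = min(base_window_s[0], stim_window_s[0], 0.0)
    hi = max(base_window_s[1], stim_window_s[1], 0.0)
    visual_trials = filter_trials(visual_trials, exclude, (lo, hi))
    if not len(visual_trials):
        raise ValueError("no trials survive the exclusion mask")
    times, freq = stft_centers(lfp.n_samples, lfp.sampling_rate_hz,
                               window_s, step_s)
    centers = lfp.start_time_s + times
    keep = ~exclude.contains(centers)
    if keep.sum() * step_s < 10.0:
        raise ValueError("fewer than 10 s survive exclusion")
    s_mask, b_mask = trial_window_sets(centers, visual_trials.onsets(),
                                       stim_window_s, base_window_s)
    rows = np.flatnonzero(_depth_mask(lfp.depth_um, depth_range_um))
    p_all = np.empty((rows.size, freq.size))
    p_stim = np.empty((rows.size, freq.size))
    p_base = np.empty((rows.size, freq.size))
    for out_i, i in enumerate(rows):
        p_all[out_i], p_stim[out_i], p_base[out_i] = mean_power_over_sets(
            lfp.values[i], lfp.sampling_rate_hz, [keep, s_mask, b_mask],
            window_s, step_s)
    with np.errstate(divide="ignore"):
        dbmv = 10.0 * np.log10(p_all)
    psd = DepthPSD(depth_um=lfp.depth_um[rows], freq_hz=freq, power_dbmv=dbmv)
    flagged = p_base == 0.0
    percent = np.full_like(p_stim, np.nan)
    ok = ~flagged
    percent[ok] = 100.0 * (p_stim[ok] - p_base[ok]) / p_base[ok]
    change = PSDChange(depth_um=lfp.depth_um[rows], freq_hz=freq,
                       percent=percent, flagged=flagged,
                       n_trials=len(visual_trials))
    return psd, change


def trial_window_sets(centers_s: np.ndarray, onsets_s: np.ndarray,
                      stim_window_s: tuple[float, float],
                      base_window_s: tuple[float, float]
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Boolean window-center sets for the stimulus and baseline periods."""
    s_mask = np.zeros(centers_s.size, dtype=bool)
    b_mask = np.zeros(centers_s.size, dtype=bool)
    for on in onsets_s:
        s_mask |= (centers_s >= on + stim_window_s[0]) & (centers_s <= on + stim_window_s[1])
        b_mask |= (centers_s >= on + base_window_s[0]) & (centers_s <= on + base_window_s[1])
    if not s_mask.any() or not b_mask.any():
        raise ValueError("stimulus or baseline window catches no spectrogram "
                         "centers")
    return s_mask, b_mask


def gamma_change_summary(change: PSDChange,
                         band_hz: tuple[float, float] = GAMMA_BAND_HZ) -> float:
    """Scalar summary: mean percent change over the gamma band and depth rows."""
    fmask = band_bins(change.freq_hz, band_hz)
    vals = change.percent[:, fmask]
    return float(np.nanmean(vals))
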