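"""Epileptiform-event detection by z-scored low-frequency band power.

The detector follows a plain threshold-run rule on the spectrogram of a
single depth row (500 um by default): mean 0.5--10 Hz power per 2-s Hamming
window stepped at 0.1 s, per-frequency median subtracted over the whole
session in linear power, band-averaged, z-scored with the session mean and
SD, and thresholded at z > 2 sustained for at least 10 s.  Because the trace
is z-scored, the detector is invariant to overall amplitude rescaling.

The duration of a supra-threshold run is counted as the span between its
first and last window centers plus one step, so 100 consecutive 0.1-s steps
(9.9 s span + 0.1 s) meet a 10-s minimum and 99 do not.  Runs separated by
even a single sub-threshold step are not merged.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .recording import LaminarLFP
from .spectral import band_bins, stft_spectrogram

log = logging.getLogger(__name__)

DETECTION_BAND_HZ = (0.5, 10.0)
DETECTION_DEPTH_UM = 500.0


@dataclass
class EpileptiformEvent:
    start_s: float
    end_s: float
    peak_z: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def band_zscore_trace(signal: np.ndarray, fs_hz: float,
                      band_hz: tuple[float, float] = DETECTION_BAND_HZ,
                      window_s: float = 2.0, step_s: float = 0.1
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Z-scored band-power trace at spectrogram window centers.

    Steps: STFT spectrogram; per-frequency median over all window centers
    subtracted in linear power; mean over the band bins; z-score against the
    session mean and SD of the resulting trace.  Returns (centers_s, z).
    """
    signal = np.asarray(signal, dtype=float)
    if signal.size < 60.0 * fs_hz:
        raise ValueError("band_zscore_trace needs at least 60 s of signal for "
                         "a stable z-score baseline")
    spec = stft_spectrogram(signal, fs_hz, window_s=window_s, step_s=step_s)
    demedianed = spec.power - np.median(spec.power, axis=0, keepdims=True)
    trace = demedianed[:, band_bins(spec.freq_hz, band_hz)].mean(axis=1)
    sd = trace.std()
    if sd == 0.0:
        raise ValueError("degenerate trace: band power has zero variance")
    return spec.time_s, (trace - trace.mean()) / sd


def detect_events(centers_s: np.ndarray, z: np.ndarray, step_s: float,
                  z_threshold: float = 2.0, min_duration_s: float = 10.0
                  ) -> list[EpileptiformEvent]:
    """Maximal supra-threshold runs lasting at least ``min_duration_s``.

    Event boundaries are the first/last run center -+ half a step.
    """
    z = np.asarray(z, dtype=float)
    centers_s = np.asarray(centers_s, dtype=float)
    above = z > z_threshold
    events: list[EpileptiformEvent] = []
    if not above.any():
        return events
    edges = np.diff(above.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(above.size)
    for i0, i1 in zip(starts, ends):
        span = centers_s[i1 - 1] - centers_s[i0] + step_s
        if span >= min_duration_s - 1e-9:
            events.append(EpileptiformEvent(
                start_s=float(centers_s[i0] - step_s / 2.0),
                end_s=float(centers_s[i1 - 1] + step_s / 2.0),
                peak_z=float(z[i0:i1].max())))
    return events


def detect_session_events(lfp: LaminarLFP,
                          target_depth_um: float = DETECTION_DEPTH_UM,
                          band_hz: tuple[float, float] = DETECTION_BAND_HZ,
                          window_s: float = 2.0, step_s: float = 0.1,
                          z_threshold: float = 2.0,
                          min_duration_s: float = 10.0
                          ) -> tuple[list[EpileptiformEvent], float]:
    """Run the detector on the depth row nearest the target depth.

    Requires a row within 50 um of ``target_depth_um``; returns the events
    and the depth actually used.
    """
    i = int(np.argmin(np.abs(lfp.depth_um - target_depth_um)))
    used = float(lfp.depth_um[i])
    if abs(used - target_depth_um) > 50.0:
        raise ValueError(
            f"no depth row within 50 um of {target_depth_um:.0f} um "
            f"(nearest: {used:.0f} um)")
    if used != target_depth_um:
        log.info("detect_session_events: using depth row %.0f um for target "
                 "%.0f um", used, target_depth_um)
    centers, z = band_zscore_trace(lfp.values[i], lfp.sampling_rate_hz,
                                   band_hz, window_s, step_s)
    events = detect_events(lfp.start_time_s + centers, z, step_s,
                           z_threshold, min_duration_s)
    log.info("detect_session_events: %d event(s) at depth %.0f um",
             len(events), used)
    return events, used
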