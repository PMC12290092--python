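"""Artifact exclusion, trial filtering and baseline-corrected trial averaging.

Detected epileptiform events contaminate all subsequent analyses, so every
event is excluded together with a guard band of 15 s on each side; trials
whose analysis window touches an excluded interval are dropped before any
averaging.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .csd import DepthTimeProfile
from .recording import LaminarLFP, TrialTable

log = logging.getLogger(__name__)


@dataclass
class ExclusionMask:
    """Disjoint, sorted, bounds-clipped excluded time intervals."""

    intervals: np.ndarray  # (k, 2) array of (start_s, end_s)

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float).reshape(-1, 2)
        if len(self.intervals):
            if np.any(self.intervals[:, 1] < self.intervals[:, 0]):
                raise ValueError("interval end before start")
            starts = self.intervals[:, 0]
            if np.any(np.diff(starts) < 0):
                raise ValueError("intervals must be sorted")
            if np.any(self.intervals[1:, 0] < self.intervals[:-1, 1]):
                raise ValueError("intervals must be disjoint")

    def __len__(self) -> int:
        return len(self.intervals)

    def total_duration_s(self) -> float:
        if not len(self.intervals):
            return 0.0
        return float(np.sum(self.intervals[:, 1] - self.intervals[:, 0]))

    def contains(self, t: np.ndarray) -> np.ndarray:
        """Boolean mask: which times fall inside an excluded interval."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.zeros(t.shape, dtype=bool)
        for a, b in self.intervals:
            out |= (t >= a) & (t <= b)
        return out

    def overlaps(self, start_s: float, end_s: float) -> bool:
        for a, b in self.intervals:
            if start_s <= b and end_s >= a:
                return True
        return False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.intervals, columns=["start_s", "end_s"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExclusionMask":
        return cls(df[["start_s", "end_s"]].to_numpy(float))

    @classmethod
    def empty(cls) -> "ExclusionMask":
        return cls(np.empty((0, 2)))


def exclusion_mask_from_events(events: list[tuple[float, float]],
                               pad_s: float = 15.0,
                               bounds: tuple[float, float] | None = None
                               ) -> ExclusionMask:
    """Expand each event by ``pad_s`` on both sides, merge overlaps, clip.

    The 15-s default guard band removes pre-ictal buildup and post-ictal
    depression along with the event itself.
    """
    if pad_s < 0:
        raise ValueError("pad_s must be nonnegative")
    if not events:
        return ExclusionMask.empty()
    expanded = sorted((a - pad_s, b + pad_s) for a, b in events)
    merged = [list(expanded[0])]
    for a, b in expanded[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    arr = np.asarray(merged, dtype=float)
    if bounds is not None:
        lo, hi = bounds
        arr = np.clip(arr, lo, hi)
        arr = arr[arr[:, 1] > arr[:, 0]]
    return ExclusionMask(arr)


def filter_trials(trials: TrialTable, mask: ExclusionMask,
                  analysis_window_s: tuple[float, float]) -> TrialTable:
    """Drop trials whose onset-relative analysis window touches the mask."""
    pre, post = analysis_window_s
    if not (pre <= 0 <= post):
        raise ValueError("analysis window must bracket the onset (pre <= 0 <= post)")
    if not len(mask) or not len(trials):
        return trials
    keep = [not mask.overlaps(on + pre, on + post) for on in trials.df["onset_s"]]
    removed = len(trials) - sum(keep)
    if removed:
        log.info("filter_trials: removed %d of %d trials overlapping the "
                 "exclusion mask", removed, len(trials))
    return TrialTable(trials.df[keep].reset_index(drop=True))


def trial_average(lfp: LaminarLFP, trials: TrialTable,
                  window_s: tuple[float, float],
                  baseline_window_s: tuple[float, float] = (-2.0, -1.0)
                  ) -> DepthTimeProfile:
    """Onset-aligned, per-trial baseline-subtracted average LFP.

    For each trial, the snippet over ``window_s`` (relative to onset) has its
    own mean over ``baseline_window_s`` subtracted per depth row *before*
    averaging across trials; per-trial subtraction removes slow drift that a
    grand-mean baseline would leave in.
    """
    if not len(trials):
        raise ValueError("trial_average needs at least one surviving trial")
    fs = lfp.sampling_rate_hz
    pre, post = window_s
    n_win = int(np.round((post - pre) * fs))
    b0, b1 = baseline_window_s
    acc = np.zeros((lfp.values.shape[0], n_win))
    for onset in trials.df["onset_s"]:
        i0 = int(np.round((onset - lfp.start_time_s + pre) * fs))
        j0 = int(np.round((onset - lfp.start_time_s + b0) * fs))
        j1 = int(np.round((onset - lfp.start_time_s + b1) * fs))
        if i0 < 0 or i0 + n_win > lfp.n_samples or j0 < 0 or j1 > lfp.n_samples:
            raise ValueError(
                f"trial at {onset:.2f} s: analysis or baseline window falls "
                "outside the recording")
        baseline = lfp.values[:, j0:j1].mean(axis=1, keepdims=True)
        acc += lfp.values[:, i0:i0 + n_win] - baseline
    acc /= len(trials)
    time_s = pre + np.arange(n_win) / fs
    return DepthTimeProfile(depth_um=lfp.depth_um, time_s=time_s,
                            values=acc, units="mV")
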