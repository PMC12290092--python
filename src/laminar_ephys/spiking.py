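"""Peristimulus time histograms and cortical-layer assignment.

PETHs are trial-aligned firing rates in 10-ms bins, baseline-subtracted by
the mean rate in a pre-stimulus window (default 2 to 1 s before the first
stimulus), so evoked modulation reads directly in spikes/s above baseline
and may be negative.  Clusters are grouped into supragranular, granular and
infragranular compartments by their depth; the granular (thalamorecipient)
band sits around 400 um in mouse sensory cortex, so the default boundaries
are 350 and 500 um.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .recording import SpikeTable, TrialTable

log = logging.getLogger(__name__)

LAYERS = ("supragranular", "granular", "infragranular")
DEFAULT_LAYER_BOUNDS_UM = (350.0, 500.0)


@dataclass
class PETH:
    """Baseline-subtracted peristimulus rate histogram for one unit or population."""
    bin_edges_s: np.ndarray
    rate_hz: np.ndarray
    n_trials: int
    label: str
    layer: str | None = None

    def __post_init__(self) -> None:
        self.bin_edges_s = np.asarray(self.bin_edges_s, dtype=float)
        self.rate_hz = np.asarray(self.rate_hz, dtype=float)
        if self.rate_hz.size != self.bin_edges_s.size - 1:
            raise ValueError("rate_hz must have one entry per bin")
        if not np.all(np.isfinite(self.rate_hz)):
            raise ValueError("PETH rates must be finite")

    @property
    def bin_centers_s(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_s[:-1] + self.bin_edges_s[1:])


def assign_layer(depth_um: float,
                 bounds_um: tuple[float, float] = DEFAULT_LAYER_BOUNDS_UM) -> str:
    """Map a cortical depth to supragranular / granular / infragranular."""
    if depth_um < 0:
        raise ValueError("depth must be nonnegative")
    lo, hi = bounds_um
    if depth_um < lo:
        return "supragranular"
    if depth_um < hi:
        return "granular"
    return "infragranular"


def compute_peth(spike_times_s: np.ndarray, trials: TrialTable,
                 window_s: tuple[float, float] = (-0.1, 0.4),
                 bin_s: float = 0.010,
                 baseline_window_s: tuple[float, float] | None = (-2.0, -1.0),
                 label: str = "cluster") -> PETH:
    """Trial-aligned rate histogram, baseline-subtracted.

    Per bin: pooled spike count / (n_trials * bin_s), minus the mean rate in
    the baseline window (counted the same way).  Alignment is to the trial
    onset, i.e. the first stimulus of the trial.  Pass
    ``baseline_window_s=None`` for the raw (un-subtracted) histogram, whose
    integral over the window equals in-window spike count / n_trials.
    """
    if not len(trials):
        raise ValueError("compute_peth needs at least one trial")
    spike_times_s = np.asarray(spike_times_s, dtype=float)
    onsets = trials.onsets()
    lo, hi = window_s
    n_bins = int(np.round((hi - lo) / bin_s))
    edges = lo + bin_s * np.arange(n_bins + 1)
    counts = np.zeros(n_bins)
    n_base = 0
    for on in onsets:
        rel = spike_times_s - on
        counts += np.histogram(rel, bins=edges)[0]
        if baseline_window_s is not None:
            b0, b1 = baseline_window_s
            n_base += np.count_nonzero((rel >= b0) & (rel < b1))
    rate = counts / (len(onsets) * bin_s)
    if baseline_window_s is not None:
        b0, b1 = baseline_window_s
        base_rate = n_base / (len(onsets) * (b1 - b0))
    else:
        base_rate = 0.0
    return PETH(bin_edges_s=edges, rate_hz=rate - base_rate,
                n_trials=len(onsets), label=label)


def population_peth_by_layer(spikes: SpikeTable, trials: TrialTable,
                             window_s: tuple[float, float] = (-0.1, 0.4),
                             bin_s: float = 0.010,
                             baseline_window_s: tuple[float, float] = (-2.0, -1.0),
                             layer_bounds_um: tuple[float, float]
                             = DEFAULT_LAYER_BOUNDS_UM) -> list[PETH]:
    """Per-layer population PETHs: unweighted average over member clusters.

    Each cluster contributes one vote regardless of its spike count.  Layers
    with no clusters are omitted with a warning.  Because averaging is
    linear, the order (clusters then bins vs bins then clusters) is
    immaterial.
    """
    members: dict[str, list[PETH]] = {layer: [] for layer in LAYERS}
    for cid in spikes.cluster_ids():
        layer = assign_layer(spikes.cluster_depth(cid), layer_bounds_um)
        members[layer].append(compute_peth(
            spikes.spike_times(cid), trials, window_s, bin_s,
            baseline_window_s, label=f"cluster {cid}"))
    out: list[PETH] = []
    for layer in LAYERS:
        peths = members[layer]
        if not peths:
            log.warning("population_peth_by_layer: no clusters in the %s layer",
                        layer)
            continue
        rate = np.mean([p.rate_hz for p in peths], axis=0)
        out.append(PETH(bin_edges_s=peths[0].bin_edges_s, rate_hz=rate,
                        n_trials=peths[0].n_trials, label="POP", layer=layer))
    return out
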