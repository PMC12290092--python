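"""Domain objects and session-directory I/O for laminar multichannel recordings.

A *session* is a directory holding a depth-ordered multichannel LFP recording
(Neuropixels-like probe, LFP band 0.5--100 Hz sampled at 2.5 kHz in the study
this package targets), a channel-geometry table, a stimulus trial table and a
sorted spike table.  On disk the layout is

    meta.json   sampling rate, channel count, int16 scale and probe geometry
    lfp.bin     frame-interleaved little-endian int16 samples
    trials.tsv  trial_id, modality, onset_s, n_stimuli, stim_param
    spikes.tsv  cluster_id, spike_time_s, cluster_depth_um

Voltages are held in millivolts, depths in micrometers below the pia
(increasing downward), and times in session-relative seconds.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

TRIAL_COLUMNS = ["trial_id", "modality", "onset_s", "n_stimuli", "stim_param"]
SPIKE_COLUMNS = ["cluster_id", "spike_time_s", "cluster_depth_um"]
MODALITIES = ("tactile", "visual")


@dataclass
class ChannelGeometry:
    """Maps channel indices to cortical depth and lateral position.

    Channels sharing an identical ``depth_um`` form a *depth row*; rows are
    the spatial unit of all downstream analyses (same-depth averaging, the
    iCSD depth grid).  ``included`` flags usable channels.
    """

    channel_index: np.ndarray
    depth_um: np.ndarray
    lateral_um: np.ndarray
    included: np.ndarray

    def __post_init__(self) -> None:
        self.channel_index = np.asarray(self.channel_index, dtype=np.int64)
        self.depth_um = np.asarray(self.depth_um, dtype=float)
        self.lateral_um = np.asarray(self.lateral_um, dtype=float)
        self.included = np.asarray(self.included, dtype=bool)
        n = self.channel_index.size
        if not (self.depth_um.size == self.lateral_um.size == self.included.size == n):
            raise ValueError("geometry field lengths disagree")
        if np.unique(self.channel_index).size != n:
            raise ValueError("channel_index values must be unique")
        if not np.all(np.isfinite(self.depth_um)) or np.any(self.depth_um < 0):
            raise ValueError("depth_um must be finite and >= 0")
        if not self.included.any():
            raise ValueError("at least one channel must be included")

    @property
    def n_channels(self) -> int:
        return self.channel_index.size

    def depth_rows(self) -> np.ndarray:
        """Sorted unique depths of the included channels (one per depth row)."""
        return np.unique(self.depth_um[self.included])


@dataclass
class LaminarLFP:
    """Depth-ordered LFP matrix in millivolts.

    ``values`` has one row per channel or per depth row and one column per
    sample; ``depth_um`` gives the depth of each row.  When rows are depth
    rows the depth vector is strictly increasing.
    """

    values: np.ndarray
    sampling_rate_hz: float
    depth_um: np.ndarray
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.depth_um = np.asarray(self.depth_um, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (rows x samples) array")
        if self.values.shape[0] != self.depth_um.size:
            raise ValueError("row count of values must equal length of depth_um")
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("LFP values must be finite")

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def times(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.n_samples) / self.sampling_rate_hz

    def is_depth_ordered(self) -> bool:
        return bool(np.all(np.diff(self.depth_um) > 0))


@dataclass
class TrialTable:
    """Stimulus trials: onset of the first stimulus, modality, stimulus count."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in TRIAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"trial table missing columns: {missing}")
        self.df = self.df.loc[:, TRIAL_COLUMNS].reset_index(drop=True).astype(
            {"trial_id": "int64", "modality": "object", "onset_s": "float64",
             "n_stimuli": "int64", "stim_param": "object"})
        if len(self.df):
            onsets = self.df["onset_s"].to_numpy(float)
            if np.any(np.diff(onsets) <= 0):
                raise ValueError("trial onsets must be strictly increasing")
            bad = set(self.df["modality"]) - set(MODALITIES)
            if bad:
                raise ValueError(f"unknown trial modality: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.df)

    def onsets(self, modality: str | None = None) -> np.ndarray:
        df = self.df if modality is None else self.df[self.df["modality"] == modality]
        return df["onset_s"].to_numpy(float)

    def select(self, modality: str) -> "TrialTable":
        return TrialTable(self.df[self.df["modality"] == modality].reset_index(drop=True))

    @classmethod
    def empty(cls) -> "TrialTable":
        return cls(pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
            TRIAL_COLUMNS, ["int64", "object", "float64", "int64", "object"])}))


@dataclass
class SpikeTable:
    """Sorted spike times with per-cluster depth (spike sorting is upstream)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SPIKE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"spike table missing columns: {missing}")
        self.df = self.df.loc[:, SPIKE_COLUMNS].reset_index(drop=True).astype(
            {"cluster_id": "int64", "spike_time_s": "float64",
             "cluster_depth_um": "float64"})
        if len(self.df):
            if (self.df["spike_time_s"] < 0).any():
                raise ValueError("spike times must be nonnegative")
            if not np.all(np.isfinite(self.df["cluster_depth_um"])):
                raise ValueError("cluster_depth_um must be finite")
            # spike times sorted within cluster
            for cid, g in self.df.groupby("cluster_id"):
                t = g["spike_time_s"].to_numpy(float)
                if np.any(np.diff(t) < 0):
                    raise ValueError(f"spike times not sorted within cluster {cid}")

    def __len__(self) -> int:
        return len(self.df)

    def cluster_ids(self) -> np.ndarray:
        return np.unique(self.df["cluster_id"].to_numpy())

    def cluster_depth(self, cluster_id: int) -> float:
        d = self.df.loc[self.df["cluster_id"] == cluster_id, "cluster_depth_um"]
        return float(d.iloc[0])

    def spike_times(self, cluster_id: int) -> np.ndarray:
        return self.df.loc[self.df["cluster_id"] == cluster_id,
                           "spike_time_s"].to_numpy(float)

    @classmethod
    def empty(cls) -> "SpikeTable":
        return cls(pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
            SPIKE_COLUMNS, ["int64", "float64", "float64"])}))


# ---------------------------------------------------------------------------
# session directory I/O
# ---------------------------------------------------------------------------

_DEFAULT_MV_PER_BIT = 0.00195  # Neuropixels-like LFP gain


def write_session(session_dir: str | Path, geometry: ChannelGeometry,
                  lfp: LaminarLFP, trials: TrialTable, spikes: SpikeTable,
                  mv_per_bit: float = _DEFAULT_MV_PER_BIT) -> Path:
    """Write a session directory; deterministic byte output for equal inputs.

    LFP samples are quantized to int16 at ``mv_per_bit`` millivolts per bit.
    Values already on the quantization grid round-trip bit-exactly.
    """
    session_dir = Path(session_dir)
    session_dir.mkdir(parents=True, exist_ok=True)
    if lfp.values.shape[0] != geometry.n_channels:
        raise ValueError("write_session expects per-channel LFP rows matching geometry")
    quant = np.round(lfp.values / mv_per_bit)
    if np.any(np.abs(quant) > 32767):
        raise ValueError("LFP exceeds int16 range at the configured mV-per-bit scale")
    frames = quant.astype("<i2").T  # frame-interleaved: sample-major on disk
    meta = {
        "sampling_rate_hz": lfp.sampling_rate_hz,
        "n_channels": geometry.n_channels,
        "dtype": "int16",
        "byte_order": "little",
        "mv_per_bit": mv_per_bit,
        "start_time_s": lfp.start_time_s,
        "geometry": [
            {"channel_index": int(ci), "depth_um": float(d),
             "lateral_um": float(x), "included": bool(inc)}
            for ci, d, x, inc in zip(geometry.channel_index, geometry.depth_um,
                                     geometry.lateral_um, geometry.included)
        ],
    }
    (session_dir / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    frames.tofile(session_dir / "lfp.bin")
    trials.df.to_csv(session_dir / "trials.tsv", sep="\t", index=False,
                     float_format="%.10g", lineterminator="\n")
    spikes.df.to_csv(session_dir / "spikes.tsv", sep="\t", index=False,
                     float_format="%.10g", lineterminator="\n")
    return session_dir


def read_session(session_dir: str | Path
                 ) -> tuple[ChannelGeometry, LaminarLFP, TrialTable, SpikeTable]:
    """Read and validate a session directory written by :func:`write_session`.

    Missing trial/spike files yield empty tables with a logged warning; a
    sidecar contradicting the binary payload is a hard error naming the field.
    """
    session_dir = Path(session_dir)
    meta_path = session_dir / "meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"missing sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    for key in ("sampling_rate_hz", "n_channels", "mv_per_bit", "geometry"):
        if key not in meta:
            raise ValueError(f"sidecar missing field '{key}'")
    geo = meta["geometry"]
    geometry = ChannelGeometry(
        channel_index=[g["channel_index"] for g in geo],
        depth_um=[g["depth_um"] for g in geo],
        lateral_um=[g["lateral_um"] for g in geo],
        included=[g.get("included", True) for g in geo],
    )
    n_channels = int(meta["n_channels"])
    if geometry.n_channels != n_channels:
        raise ValueError("sidecar channel count disagrees with geometry table")
    bin_path = session_dir / "lfp.bin"
    n_bytes = bin_path.stat().st_size
    if n_bytes % (2 * n_channels) != 0:
        raise ValueError(
            f"lfp.bin size {n_bytes} B is not a whole number of frames for the "
            f"declared channel count {n_channels}")
    raw = np.fromfile(bin_path, dtype="<i2").reshape(-1, n_channels)
    values = raw.T.astype(float) * float(meta["mv_per_bit"])
    lfp = LaminarLFP(values=values, sampling_rate_hz=float(meta["sampling_rate_hz"]),
                     depth_um=geometry.depth_um,
                     start_time_s=float(meta.get("start_time_s", 0.0)))
    trials_path = session_dir / "trials.tsv"
    if trials_path.exists():
        tdf = pd.read_csv(trials_path, sep="\t")
        if tdf.empty:
            trials = TrialTable.empty()
        else:
            trials = TrialTable(tdf)
    else:
        log.warning("no trials.tsv in %s; returning empty trial table", session_dir)
        trials = TrialTable.empty()
    spikes_path = session_dir / "spikes.tsv"
    if spikes_path.exists():
        sdf = pd.read_csv(spikes_path, sep="\t")
        spikes = SpikeTable.empty() if sdf.empty else SpikeTable(sdf)
    else:
        log.warning("no spikes.tsv in %s; returning empty spike table", session_dir)
        spikes = SpikeTable.empty()
    return geometry, lfp, trials, spikes


# ---------------------------------------------------------------------------
# channel hygiene
# ---------------------------------------------------------------------------

def reject_channels(lfp: LaminarLFP, geometry: ChannelGeometry,
                    mad_k: float = 5.0) -> ChannelGeometry:
    """Flag broken/out-of-brain channels on per-channel LFP rows.

    A channel is excluded when its sample variance is exactly zero (dead or
    saturated line) or when its log-RMS deviates from the median log-RMS of
    the live channels by more than ``mad_k`` scaled median absolute
    deviations (MAD x 1.4826, the Gaussian-consistent robust SD).  Returns a
    copy of ``geometry`` with ``included`` updated.
    """
    if lfp.values.shape[0] != geometry.n_channels:
        raise ValueError("reject_channels expects per-channel rows matching geometry")
    if geometry.n_channels < 2:
        raise ValueError("channel rejection undefined for fewer than 2 channels")
    var = lfp.values.var(axis=1)
    dead = var == 0.0
    included = geometry.included & ~dead
    live = np.flatnonzero(~dead)
    if live.size >= 2:
        log_rms = 0.5 * np.log(var[live])
        med = np.median(log_rms)
        mad = 1.4826 * np.median(np.abs(log_rms - med))
        if mad > 0:
            outlier = np.abs(log_rms - med) > mad_k * mad
            included[live[outlier]] = False
    n_rej = int(geometry.included.sum() - included.sum())
    if n_rej:
        log.info("reject_channels: excluded %d of %d channels",
                 n_rej, geometry.n_channels)
    return replace(geometry, included=included)


def average_same_depth(lfp: LaminarLFP, geometry: ChannelGeometry) -> LaminarLFP:
    """Average included channels sharing a depth into one row per depth row.

    Output rows are sorted by increasing depth; depth rows with no included
    channel are dropped (logged).  Idempotent on already-averaged input.
    """
    if lfp.values.shape[0] != geometry.n_channels:
        raise ValueError("average_same_depth expects per-channel rows matching geometry")
    depths = geometry.depth_rows()
    all_depths = np.unique(geometry.depth_um)
    dropped = np.setdiff1d(all_depths, depths)
    if dropped.size:
        log.info("average_same_depth: dropping %d depth rows with no usable channel",
                 dropped.size)
    rows = np.empty((depths.size, lfp.n_samples))
    for i, d in enumerate(depths):
        sel = (geometry.depth_um == d) & geometry.included
        rows[i] = lfp.values[sel].mean(axis=0)
    return LaminarLFP(values=rows, sampling_rate_hz=lfp.sampling_rate_hz,
                      depth_um=depths, start_time_s=lfp.start_time_s)
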