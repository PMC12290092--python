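"""Synthetic laminar sessions with known ground truth.

Every analysis stage in this package is validated against recordings whose
truth is known by construction.  The generator emulates the features of a
laminar sensory-cortex recording that the analyses consume:

* 1/f (pink) background LFP with exponential spatial correlation across
  depth,
* stimulus-evoked CSD sink/source responses (separable Gaussian in depth and
  time, charge-balanced), rendered into LFP through an independent
  high-resolution quadrature of the disk forward model,
* gamma-band sinusoid bursts during visual stimulation,
* high-amplitude 1--4 Hz epileptiform episodes with cosine-ramped edges,
* inhomogeneous Poisson spike trains (baseline plus boxcar evoked rate).

The trial protocol mirrors the study design this package targets: tactile
trials of paired 20-ms air puffs at 500 ms inter-stimulus interval and 5-s
visual grating trials, interleaved in randomized order with inter-trial
intervals drawn uniformly from 3--5 s.

The forward route here (linear interpolation of the CSD onto a 1-um grid and
trapezoid quadrature of the disk kernel) is deliberately independent of the
spline machinery in :mod:`laminar_ephys.csd`, so round-trip tests pit two
separate implementations of the same physics against each other.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .csd import DepthTimeProfile, disk_kernel
from .recording import (ChannelGeometry, LaminarLFP, SpikeTable, TrialTable,
                        TRIAL_COLUMNS, SPIKE_COLUMNS)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class NoiseConfig:
    """Pink background noise, band-limited to the acquisition LFP band.

    PSD(f) = c / max(f, corner_hz) shaped by a Butterworth-magnitude
    low-pass |H(f)|^2 = 1 / (1 + (f/cutoff)^(2*rolloff_order)), with c fixed
    so the total RMS equals ``rms_mv``.  The 100-Hz cutoff mirrors the
    low-pass acquisition filter of the recordings this generator emulates; a
    smooth roll-off (rather than a brick wall) keeps above-cutoff bins at
    physically plausible, leakage-free power levels.
    """
    rms_mv: float = 0.1
    correlation_length_um: float = 200.0
    corner_hz: float = 0.5
    cutoff_hz: float = 100.0
    rolloff_order: int = 4


@dataclass
class EvokedComponent:
    """One charge-balanced sink/source pair, separable Gaussian(depth) x Gaussian(time).

    ``peak_amplitude_uA_mm3`` is the sink peak (negative for a sink); the
    paired source sits ``source_offset_um`` deeper and is rescaled so the
    on-grid depth sum cancels exactly.
    """
    depth_center_um: float = 400.0
    depth_sd_um: float = 100.0
    peak_amplitude_uA_mm3: float = -5.0
    latency_s: float = 0.025
    temporal_sd_s: float = 0.008
    source_offset_um: float = 300.0


@dataclass
class GammaConfig:
    """Sinusoidal gamma bursts added during visual stimulation."""
    frequency_hz: float = 70.0
    amplitude_mv: float = 0.05
    depth_band_um: tuple[float, float] = (0.0, 400.0)
    visual_only: bool = True
    ramp_s: float = 0.1


@dataclass
class EpileptiformEpisode:
    """A sustained high-amplitude low-frequency oscillation episode.

    Amplitude is ``amplitude_multiplier`` times the analytic 0.5--10 Hz band
    RMS of the configured background noise; edges get 1-s cosine ramps so the
    STFT sees no step artifacts.
    """
    start_s: float
    duration_s: float
    frequency_hz: float = 2.0
    amplitude_multiplier: float = 8.0
    ramp_s: float = 1.0


@dataclass
class TrialConfig:
    n_tactile: int = 50
    n_visual: int = 50
    iti_range_s: tuple[float, float] = (3.0, 5.0)
    tactile_n_stimuli: int = 2
    tactile_isi_s: float = 0.5
    visual_duration_s: float = 5.0
    start_pad_s: float = 5.0


@dataclass
class SpikeConfig:
    n_clusters: int = 10
    baseline_rate_hz: float = 5.0
    evoked_rate_hz: float = 15.0
    evoked_window_s: tuple[float, float] = (0.0, 0.05)
    cluster_depths_um: Sequence[float] | None = None


@dataclass
class SimConfig:
    """Full description of one simulated session; ``seed`` is mandatory."""

    seed: int
    duration_s: float | None = None  # None: auto-fit to the trial schedule
    n_depth_rows: int = 64
    depth_spacing_um: float = 20.0
    depth_start_um: float = 0.0
    sampling_rate_hz: float = 2500.0
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    evoked: list[EvokedComponent] = field(default_factory=lambda: [EvokedComponent()])
    gamma: GammaConfig = field(default_factory=GammaConfig)
    epileptiform: list[EpileptiformEpisode] = field(default_factory=list)
    trials: TrialConfig = field(default_factory=TrialConfig)
    spikes: SpikeConfig = field(default_factory=SpikeConfig)
    sigma_S_per_m: float = 0.3
    disk_radius_um: float = 500.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("SimConfig.seed is mandatory")
        if self.spikes.baseline_rate_hz < 0 or self.spikes.evoked_rate_hz < 0:
            raise ValueError("spike rates must be nonnegative")
        for ep in self.epileptiform:
            if not (1.0 <= ep.frequency_hz <= 4.0):
                raise ValueError("epileptiform frequency must lie in [1, 4] Hz")
        span = self.depth_start_um + (self.n_depth_rows - 1) * self.depth_spacing_um
        lo, hi = self.gamma.depth_band_um
        if lo > hi or hi < self.depth_start_um or lo > span:
            raise ValueError("gamma depth band outside the probe span")

    def depths_um(self) -> np.ndarray:
        return self.depth_start_um + self.depth_spacing_um * np.arange(self.n_depth_rows)


@dataclass
class GroundTruth:
    """What the generator actually injected; the recovery oracle."""
    true_csd: DepthTimeProfile
    event_intervals: list[tuple[float, float]]
    gamma_amplitude_mv: float
    gamma_frequency_hz: float
    baseline_rate_hz: float
    evoked_rate_hz: float
    evoked_window_s: tuple[float, float]
    noise_band_rms_mv: float
    seed: int


@dataclass
class SimulatedSession:
    geometry: ChannelGeometry
    lfp: LaminarLFP
    trials: TrialTable
    spikes: SpikeTable
    truth: GroundTruth


# ---------------------------------------------------------------------------
# pink noise with a closed-form spectral law
# ---------------------------------------------------------------------------

def pink_psd_shape(freq_hz: np.ndarray, corner_hz: float = 0.5,
                   cutoff_hz: float = 100.0, rolloff_order: int = 4
                   ) -> np.ndarray:
    """Unnormalized spectral law: 1/f flattened below the corner, Butterworth
    low-passed above the cutoff."""
    f = np.asarray(freq_hz, dtype=float)
    return (1.0 / np.maximum(f, corner_hz)
            / (1.0 + (f / cutoff_hz) ** (2 * rolloff_order)))


def pink_psd_constant(rms_mv: float, corner_hz: float, nyquist_hz: float,
                      cutoff_hz: float = 100.0, rolloff_order: int = 4
                      ) -> float:
    """Normalization c (mV^2/Hz at 1 Hz) so that the shaped PSD integrates
    to rms^2 over [0, Nyquist]; computed by fine-grid quadrature."""
    f = np.linspace(0.0, nyquist_hz, 200_001)
    integral = np.trapezoid(pink_psd_shape(f, corner_hz, cutoff_hz,
                                           rolloff_order), f)
    return rms_mv**2 / integral


def pink_band_rms(rms_mv: float, corner_hz: float, nyquist_hz: float,
                  band_hz: tuple[float, float],
                  cutoff_hz: float = 100.0, rolloff_order: int = 4) -> float:
    """RMS of the band-limited pink background within a frequency band."""
    c = pink_psd_constant(rms_mv, corner_hz, nyquist_hz, cutoff_hz,
                          rolloff_order)
    lo, hi = band_hz
    f = np.linspace(lo, min(hi, nyquist_hz), 50_001)
    power = c * np.trapezoid(pink_psd_shape(f, corner_hz, cutoff_hz,
                                            rolloff_order), f)
    return float(np.sqrt(max(power, 0.0)))


def _pink_rows(rng: np.random.Generator, n_rows: int, n_samples: int,
               fs_hz: float, noise: NoiseConfig) -> np.ndarray:
    """Independent pink-noise rows realizing the analytic PSD law."""
    nyq = fs_hz / 2.0
    c = pink_psd_constant(noise.rms_mv, noise.corner_hz, nyq,
                          noise.cutoff_hz, noise.rolloff_order)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs_hz)
    psd = c * pink_psd_shape(freqs, noise.corner_hz, noise.cutoff_hz,
                             noise.rolloff_order)
    psd[0] = 0.0  # no DC
    # E|X_k|^2 = PSD_k * fs * N / 2 makes irfft(X) realize the target PSD
    amp = np.sqrt(psd * fs_hz * n_samples / 2.0)
    shape = (n_rows, freqs.size)
    spec = amp * (rng.standard_normal(shape) + 1j * rng.standard_normal(shape)) / np.sqrt(2.0)
    return np.fft.irfft(spec, n=n_samples, axis=1)


def _spatial_mixer(depths_um: np.ndarray, correlation_length_um: float) -> np.ndarray:
    """Cholesky factor of the exponential depth-correlation matrix (unit diag)."""
    d = np.abs(depths_um[:, None] - depths_um[None, :])
    corr = np.exp(-d / correlation_length_um)
    # tiny jitter keeps the factorization stable for near-singular spacings
    return np.linalg.cholesky(corr + 1e-12 * np.eye(len(depths_um)))


# ---------------------------------------------------------------------------
# ground-truth CSD and the quadrature forward oracle
# ---------------------------------------------------------------------------

def make_evoked_csd_truth(cfg: SimConfig, time_s: np.ndarray | None = None
                          ) -> DepthTimeProfile:
    """Charge-balanced ground-truth CSD on the probe's depth grid.

    Each component contributes a Gaussian sink and, ``source_offset_um``
    deeper, a Gaussian source rescaled so the two cancel exactly in the
    on-grid depth sum (exact balance even when a Gaussian is truncated by the
    probe edge).  A component whose +-3 SD depth extent leaves the probe span
    triggers a warning.
    """
    if not cfg.evoked:
        raise ValueError("evoked component list is empty")
    z = cfg.depths_um()
    if time_s is None:
        t_max = max(c.latency_s + 6.0 * c.temporal_sd_s for c in cfg.evoked)
        n_t = int(np.round(t_max * cfg.sampling_rate_hz)) + 1
        time_s = np.arange(n_t) / cfg.sampling_rate_hz
    values = np.zeros((z.size, time_s.size))
    for comp in cfg.evoked:
        for center in (comp.depth_center_um,
                       comp.depth_center_um + comp.source_offset_um):
            if (center - 3 * comp.depth_sd_um < z[0]
                    or center + 3 * comp.depth_sd_um > z[-1]):
                warnings.warn(
                    f"evoked component at {center:.0f} um extends beyond the "
                    "probe span within 3 depth SDs; its Gaussian is truncated",
                    stacklevel=2)
        g_sink = np.exp(-0.5 * ((z - comp.depth_center_um) / comp.depth_sd_um) ** 2)
        g_src = np.exp(-0.5 * ((z - comp.depth_center_um - comp.source_offset_um)
                               / comp.depth_sd_um) ** 2)
        sink = comp.peak_amplitude_uA_mm3 * g_sink
        src_sum = g_src.sum()
        source = -(sink.sum() / src_sum) * g_src if src_sum > 0 else 0.0 * g_src
        temporal = np.exp(-0.5 * ((time_s - comp.latency_s) / comp.temporal_sd_s) ** 2)
        values += (sink + source)[:, None] * temporal[None, :]
    return DepthTimeProfile(depth_um=z, time_s=time_s, values=values,
                            units="uA_per_mm3")


def forward_lfp_from_csd(csd: DepthTimeProfile, sigma_S_per_m: float = 0.3,
                         disk_radius_um: float = 500.0,
                         quad_step_um: float = 1.0) -> DepthTimeProfile:
    """Potential of a CSD profile by high-resolution quadrature (the oracle).

    The CSD is linearly interpolated onto a ``quad_step_um`` grid spanning
    the electrode range (zero assumed outside) and integrated against the
    disk kernel by the trapezoid rule.  Output in mV for CSD in uA/mm^3.
    """
    if csd.units != "uA_per_mm3":
        raise ValueError("forward model expects CSD in uA/mm^3")
    if sigma_S_per_m <= 0 or disk_radius_um <= 0:
        raise ValueError("sigma and disk radius must be positive")
    z_mm = csd.depth_um / 1000.0
    R = disk_radius_um / 1000.0
    n_fine = int(np.round((csd.depth_um[-1] - csd.depth_um[0]) / quad_step_um)) + 1
    zf = np.linspace(z_mm[0], z_mm[-1], n_fine)
    # linear interpolation of all time columns onto the fine grid
    pos = (zf - z_mm[0]) / (z_mm[1] - z_mm[0])
    idx = np.clip(pos.astype(int), 0, z_mm.size - 2)
    frac = pos - idx
    fine = (1.0 - frac)[:, None] * csd.values[idx] + frac[:, None] * csd.values[idx + 1]
    dz = zf[1] - zf[0]
    w = np.full(n_fine, dz)
    w[0] = w[-1] = dz / 2.0
    K = w[None, :] * disk_kernel(zf[None, :], z_mm[:, None], R) / (2.0 * sigma_S_per_m)
    phi = K @ fine
    return DepthTimeProfile(depth_um=csd.depth_um, time_s=csd.time_s,
                            values=phi, units="mV")


# ---------------------------------------------------------------------------
# session assembly
# ---------------------------------------------------------------------------

def _schedule_trials(cfg: SimConfig, rng: np.random.Generator
                     ) -> tuple[pd.DataFrame, float]:
    """Randomized interleaved trial schedule; returns (table, end time)."""
    tc = cfg.trials
    modalities = np.array(["tactile"] * tc.n_tactile + ["visual"] * tc.n_visual)
    rng.shuffle(modalities)
    rows = []
    t = tc.start_pad_s
    for i, mod in enumerate(modalities):
        if mod == "tactile":
            span = tc.tactile_isi_s * (tc.tactile_n_stimuli - 1) + 0.1
            n_stim, param = tc.tactile_n_stimuli, f"air_puff isi={tc.tactile_isi_s}s"
        else:
            span = tc.visual_duration_s
            n_stim, param = 1, f"grating {tc.visual_duration_s}s"
        rows.append((i, mod, t, n_stim, param))
        t += span + rng.uniform(*tc.iti_range_s)
    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    return df, t


def _poisson_spikes(rng: np.random.Generator, rate_hz: float,
                    t0: float, t1: float) -> np.ndarray:
    n = rng.poisson(rate_hz * (t1 - t0))
    return np.sort(rng.uniform(t0, t1, size=n))


def simulate_session(cfg: SimConfig) -> SimulatedSession:
    """Build one fully reproducible session from its configuration.

    LFP = forward-modelled evoked component at every tactile stimulus
    + spatially correlated pink noise + gamma bursts during visual stimuli
    + epileptiform episodes; spikes are inhomogeneous Poisson.
    """
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.sampling_rate_hz
    depths = cfg.depths_um()

    trials_df, sched_end = _schedule_trials(cfg, rng)
    duration = cfg.duration_s
    if duration is None:
        duration = float(np.ceil(sched_end + 5.0))
    elif sched_end > duration:
        raise ValueError(
            f"trial schedule ({sched_end:.1f} s) does not fit in the "
            f"configured duration ({duration:.1f} s)")
    for ep in cfg.epileptiform:
        if ep.start_s < 0 or ep.start_s + ep.duration_s > duration:
            raise ValueError("epileptiform episode outside the session duration")
    n_samples = int(np.round(duration * fs))
    t_samp = np.arange(n_samples) / fs

    # background noise
    white_rows = _pink_rows(rng, cfg.n_depth_rows, n_samples, fs, cfg.noise)
    L = _spatial_mixer(depths, cfg.noise.correlation_length_um)
    values = L @ white_rows
    del white_rows

    # evoked responses, rendered once and pasted at each tactile stimulus
    tactile = trials_df[trials_df["modality"] == "tactile"]
    if cfg.evoked:
        truth_csd = make_evoked_csd_truth(cfg)
        evoked_lfp = forward_lfp_from_csd(truth_csd, cfg.sigma_S_per_m,
                                          cfg.disk_radius_um).values
        snip_len = evoked_lfp.shape[1]
        for onset, n_stim in zip(tactile["onset_s"], tactile["n_stimuli"]):
            for k in range(int(n_stim)):
                i0 = int(np.round((onset + k * cfg.trials.tactile_isi_s) * fs))
                i1 = min(i0 + snip_len, n_samples)
                if i0 < n_samples:
                    values[:, i0:i1] += evoked_lfp[:, :i1 - i0]
    else:
        truth_csd = DepthTimeProfile(depth_um=depths, time_s=np.array([0.0]),
                                     values=np.zeros((depths.size, 1)),
                                     units="uA_per_mm3")

    # gamma bursts during visual stimulation
    g = cfg.gamma
    in_band = (depths >= g.depth_band_um[0]) & (depths <= g.depth_band_um[1])
    visual = trials_df[trials_df["modality"] == "visual"]
    if g.amplitude_mv > 0 and in_band.any():
        for onset in visual["onset_s"]:
            i0 = int(np.round(onset * fs))
            i1 = min(i0 + int(np.round(cfg.trials.visual_duration_s * fs)), n_samples)
            tau = t_samp[i0:i1] - onset
            burst = g.amplitude_mv * np.sin(
                2 * np.pi * g.frequency_hz * tau + rng.uniform(0, 2 * np.pi))
            ramp = np.ones_like(tau)
            nr = int(np.round(g.ramp_s * fs))
            if nr > 0 and tau.size > 2 * nr:
                edge = 0.5 * (1 - np.cos(np.pi * np.arange(nr) / nr))
                ramp[:nr] = edge
                ramp[-nr:] = edge[::-1]
            values[in_band, i0:i1] += burst * ramp

    # epileptiform episodes, amplitude anchored to the analytic band RMS
    band_rms = pink_band_rms(cfg.noise.rms_mv, cfg.noise.corner_hz, fs / 2.0,
                             (0.5, 10.0), cfg.noise.cutoff_hz,
                             cfg.noise.rolloff_order)
    intervals: list[tuple[float, float]] = []
    for ep in sorted(cfg.epileptiform, key=lambda e: e.start_s):
        i0 = int(np.round(ep.start_s * fs))
        i1 = min(i0 + int(np.round(ep.duration_s * fs)), n_samples)
        tau = t_samp[i0:i1] - ep.start_s
        wave = (ep.amplitude_multiplier * band_rms
                * np.sin(2 * np.pi * ep.frequency_hz * tau + rng.uniform(0, 2 * np.pi)))
        env = np.ones_like(tau)
        nr = int(np.round(ep.ramp_s * fs))
        if nr > 0 and tau.size > 2 * nr:
            edge = 0.5 * (1 - np.cos(np.pi * np.arange(nr) / nr))
            env[:nr] = edge
            env[-nr:] = edge[::-1]
        values[:, i0:i1] += wave * env  # broadcast across all depth rows
        intervals.append((ep.start_s, ep.start_s + ep.duration_s))
    for (a0, a1), (b0, b1) in zip(intervals, intervals[1:]):
        if b0 < a1:
            raise ValueError("epileptiform episodes must be disjoint")

    # spikes: baseline Poisson plus boxcar evoked rate at each tactile stimulus
    sc = cfg.spikes
    if sc.cluster_depths_um is not None:
        cluster_depths = np.asarray(sc.cluster_depths_um, dtype=float)
    else:
        cluster_depths = np.linspace(depths[0], depths[-1],
                                     max(sc.n_clusters, 1))
    spike_rows = []
    w0, w1 = sc.evoked_window_s
    for cid in range(sc.n_clusters):
        times = [_poisson_spikes(rng, sc.baseline_rate_hz, 0.0, duration)]
        if sc.evoked_rate_hz > 0:
            for onset, n_stim in zip(tactile["onset_s"], tactile["n_stimuli"]):
                for k in range(int(n_stim)):
                    s = onset + k * cfg.trials.tactile_isi_s
                    times.append(_poisson_spikes(rng, sc.evoked_rate_hz,
                                                 s + w0, s + w1))
        t_all = np.sort(np.concatenate(times))
        spike_rows.append(pd.DataFrame({
            "cluster_id": cid, "spike_time_s": t_all,
            "cluster_depth_um": cluster_depths[cid % cluster_depths.size]}))
    if spike_rows:
        spikes = SpikeTable(pd.concat(spike_rows, ignore_index=True)
                            [SPIKE_COLUMNS]) if sum(map(len, spike_rows)) else SpikeTable.empty()
    else:
        spikes = SpikeTable.empty()

    geometry = ChannelGeometry(channel_index=np.arange(cfg.n_depth_rows),
                               depth_um=depths,
                               lateral_um=np.zeros(cfg.n_depth_rows),
                               included=np.ones(cfg.n_depth_rows, bool))
    lfp = LaminarLFP(values=values, sampling_rate_hz=fs, depth_um=depths)
    trials = TrialTable(trials_df) if len(trials_df) else TrialTable.empty()
    truth = GroundTruth(true_csd=truth_csd, event_intervals=intervals,
                        gamma_amplitude_mv=g.amplitude_mv,
                        gamma_frequency_hz=g.frequency_hz,
                        baseline_rate_hz=sc.baseline_rate_hz,
                        evoked_rate_hz=sc.evoked_rate_hz,
                        evoked_window_s=(w0, w1),
                        noise_band_rms_mv=band_rms, seed=cfg.seed)
    return SimulatedSession(geometry=geometry, lfp=lfp, trials=trials,
                            spikes=spikes, truth=truth)


# ---------------------------------------------------------------------------
# two-group cohorts
# ---------------------------------------------------------------------------

@dataclass
class GroupDeltas:
    """Multiplicative/additive differences of the second (KO-like) group."""
    evoked_amplitude_scale: float = 1.0
    latency_shift_s: float = 0.0
    gamma_amplitude_scale: float = 1.0


def apply_deltas(cfg: SimConfig, deltas: GroupDeltas, seed: int) -> SimConfig:
    evoked = [replace(c,
                      peak_amplitude_uA_mm3=c.peak_amplitude_uA_mm3
                      * deltas.evoked_amplitude_scale,
                      latency_s=c.latency_s + deltas.latency_shift_s)
              for c in cfg.evoked]
    gamma = replace(cfg.gamma,
                    amplitude_mv=cfg.gamma.amplitude_mv * deltas.gamma_amplitude_scale)
    return replace(cfg, evoked=evoked, gamma=gamma, seed=seed)


@dataclass
class CohortMember:
    """Lazy handle on one cohort session: config now, samples on demand."""
    group: str
    config: SimConfig

    def simulate(self) -> SimulatedSession:
        return simulate_session(self.config)


def simulate_cohort(base_cfg: SimConfig, deltas: GroupDeltas,
                    n_per_group: int, seed: int) -> list[CohortMember]:
    """Control-like and KO-like session handles differing only by the deltas.

    Per-session seeds derive deterministically from the master seed; sessions
    are materialized lazily (``member.simulate()``) so large cohorts need not
    coexist in memory.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s) for s in ss.generate_state(2 * n_per_group) % (2**31)]
    members = []
    for i in range(n_per_group):
        members.append(CohortMember(
            "control", apply_deltas(base_cfg, GroupDeltas(), child_seeds[2 * i])))
        members.append(CohortMember(
            "ko", apply_deltas(base_cfg, deltas, child_seeds[2 * i + 1])))
    return members
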