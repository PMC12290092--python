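# Methods

This note documents the models, estimators and numerical choices behind
`laminar_ephys`, in the order the pipeline applies them, together with what
the synthetic-data generator does and does not emulate.

## Recording model and units

A session is a depth-ordered multichannel LFP recording (Neuropixels-like
probe; the targeted acquisition band is 0.5–100 Hz sampled at 2.5 kHz), a
channel-geometry table, a stimulus trial table and a sorted spike table.
Conventions used everywhere:

* voltage in **millivolts**, depth in **micrometers below the pia**
  (increasing downward), time in **seconds**, session-relative;
* CSD in **µA/mm³**; with depths in mm and conductivity in S/m this makes
  the forward integral dimensionally closed: 1 mV · (S/m) / mm² = 1 µA/mm³;
* "dBmV" means 10·log₁₀(PSD / 1 mV²/Hz).  This reference is a package
  convention; absolute dB values depend on it, relative comparisons do not.

Channels sharing a depth form a *depth row*; included channels of a row are
arithmetically averaged before any analysis.  Broken or out-of-brain
channels are flagged by two parameter-light rules: exactly zero sample
variance, or a log-RMS further than `mad_k` (default 5) scaled median
absolute deviations (MAD × 1.4826) from the median log-RMS.  This rule is a
deliberate stand-in for whatever channel curation an acquisition toolbox
performs; it is reproducible and has a measured false-positive rate below
1 % on homogeneous Gaussian channels.

## Spline inverse CSD

The forward model treats the CSD as a stack of uniform disks of radius *R*
centered on the probe axis in a homogeneous, isotropic medium of
conductivity σ = 0.3 S/m:

    φ(z_i) = 1/(2σ) ∫ C(z) [ √((z − z_i)² + R²) − |z − z_i| ] dz

The spline variant takes C(z) to be the natural cubic spline through its
values at the electrode depths and zero outside the outermost contacts.
The forward matrix **F** is built by per-segment Gauss–Legendre quadrature
(16 nodes/segment) of the spline basis against the kernel — the |z − z_i|
kink always falls on a segment boundary, so each sub-integrand is smooth.
Estimation solves **F**·c = φ per time sample with a single LU
factorization reused across samples; there is no regularization, but the
condition number is checked (error above 1e8) and logged.

Numerical cross-checks built into the test battery:

* the potential of a uniform slab matches the closed form
  (h√(h²+R²) + R²·asinh(h/R))/2 to ~1e-5 %;
* a smooth Gaussian sink/source truth pushed through an *independent*
  forward route (linear interpolation to a 1-µm grid + trapezoid
  quadrature) and inverted recovers the truth with ~0.3 % relative L2 error
  at 20-µm spacing;
* in the large-R limit the spline estimate agrees with the classic
  −σ·second-difference estimator to ~0.2 % RMS on interior rows.

**The disk radius R is not identifiable from the data** and is therefore a
config knob (default 500 µm, the order of a cortical column); every output
should cite the R used.  The estimated CSD is finally convolved along depth
with a Gaussian (SD 0.1 mm, kernel truncated at ±4 SD and renormalized,
reflection padding).  Reflection padding plus a unit-sum kernel leaves
constant profiles untouched and conserves the depth-sum exactly; zero
padding would attenuate the estimate at the pia.  Peak responses are the
most negative deflection (sinks are negative) at a requested depth row
within a search window, ties broken to the earliest sample.

## Spectral analysis

One STFT backbone serves all spectral stages: Hamming windows of 2 s
stepped by 0.1 s (0.5-Hz bins, 95 % overlap), one-sided periodograms
normalized as spectral density so white noise of variance s² has mean
density s²/(fs/2).  The implementation streams over window chunks — the
full spectrogram of a long 48-row session is never materialized — and is
asserted bit-identical to `scipy.signal.spectrogram` in the tests.

* **Depth PSD**: per depth row, the mean over all non-excluded window
  centers, in dBmV.  The session gamma scalar is the mean of the *dB*
  values over the 30–120 Hz bins and a configured depth band (the dB of the
  linear mean is available as `band_power_linear`; the two differ whenever
  the band is spectrally inhomogeneous, and the dB-mean is the default
  because it weights decades rather than absolute power).
* **Stimulus-induced PSD change**: 100·(P_stim − P_base)/P_base per bin,
  with P_stim/P_base mean densities over windows whose centers fall in the
  stimulus (default 1–4 s after grating onset, so every 2-s window lies
  wholly inside the 5-s stimulus) and baseline (−2 to −1 s) periods, pooled
  across surviving trials.  Bins with zero baseline power are flagged and
  excluded from summaries.  As a ratio the statistic is invariant to
  rescaling the recording.  Band edges snap to the nearest bin, inclusive.

## Epileptiform-event detection

On the depth row nearest 500 µm (must be within 50 µm): STFT as above; per
frequency bin subtract that bin's session median *in linear power*; average
the 0.5–10 Hz bins; z-score the trace with its session mean and SD; report
maximal runs with z > 2 whose span (last minus first supra-threshold window
center plus one step) reaches 10 s.  Event bounds are the run's outer
centers ± half a step.  Runs separated by a single sub-threshold step are
not merged.  The z-scoring makes detection invariant to amplitude
rescaling.

Two caveats are inherent to the method and documented rather than patched:
the z-score baseline includes the events themselves, so sessions in which
episodes occupy a large fraction of the recording (≳15–20 % at 8× band
amplitude) push their own threshold up; and the 2-s window smears event
onsets by up to ~1 s, which bounds the achievable interval Jaccard against
ground truth at roughly d/(d+2) for a d-second event.

Detected events are excluded together with 15 s on each side; overlapping
exclusions merge, and trials whose analysis window touches an excluded
interval are dropped before every downstream stage.

## Trial averaging, PETHs and layers

Trial-averaged LFP subtracts each trial's own mean over a −2 to −1 s
pre-onset baseline before averaging (per-trial subtraction removes slow
drift that a grand mean would leave in).  PETHs use 10-ms bins, rate =
pooled count/(n_trials·bin), minus the mean rate in the same baseline
window; population PETHs average member clusters unweighted (one cluster,
one vote).  Clusters are assigned to cortical compartments by depth with
boundaries at 350 µm (supragranular/granular) and 500 µm
(granular/infragranular); the boundaries are config-exposed because
anatomical layer ranges, not cutpoints, are what is actually known
(granular ≈ 400 µm, layer II/III ≈ 100–300 µm, layer V ≈ 500–900 µm in
mouse sensory cortex).

## Rank-sum comparison

Per-session scalars (CSD peak amplitude and latency, gamma power, gamma PSD
change) are compared between groups with the Wilcoxon rank-sum test.
Midranks handle ties.  For n₁+n₂ ≤ 25 the exact permutation distribution of
the rank-sum W is computed by a shift/DP count over the doubled midranks
(integers), which remains valid with ties; the two-sided p doubles the
smaller tail, capped at 1 — the standard convention for discrete exact
tests, and the one the enumeration oracle in the tests reproduces to
machine precision.  Larger samples use the normal approximation with
tie-corrected variance and continuity correction (within 0.01 of exact at
n₁=n₂=15).  Group summaries are mean ± SEM (sample SD, n−1 denominator);
SEM is reported missing at n = 1.

## The synthetic generator

`simulate_session` composes, on a configurable depth grid:

* **Background**: pink noise with the spectral law PSD(f) ∝
  1/max(f, 0.5 Hz) shaped by an 8th-order Butterworth magnitude low-pass at
  100 Hz — the acquisition band of the recordings being emulated — and
  normalized by quadrature to a target RMS of 0.1 mV (a realistic cortical
  LFP background).  Rows are spatially mixed by the Cholesky factor of an
  exponential depth-correlation matrix (length 200 µm).  Pink, spatially
  correlated, band-limited noise keeps detector false-positive tests and
  CSD noise propagation honest: white noise would be unrealistically easy
  in both respects, and noise above the acquisition band would add trough
  jitter that real recordings cannot contain.  The smooth roll-off (rather
  than a brick wall) keeps above-cutoff spectrogram bins at small but
  well-defined power, so ratio statistics over the 30–120 Hz band remain
  meaningful.
* **Evoked responses**: separable Gaussian(depth)×Gaussian(time) sink
  (default −5 µA/mm³ at 400 µm depth, 100 µm SD, 25 ms latency, 8 ms
  temporal SD) paired with a source 300 µm deeper whose on-grid sum cancels
  the sink exactly (exact discrete charge balance even when a Gaussian is
  truncated at the probe edge, at the price of a slightly rescaled source
  peak).  The truth CSD is rendered to LFP through the 1-µm quadrature
  forward oracle — a route sharing no code with the spline estimator — and
  pasted at every tactile air-puff (two per trial, 500 ms apart).
* **Gamma bursts**: a 70-Hz sinusoid (default 0.05 mV) over a depth band
  (default 0–400 µm) for the duration of each 5-s visual grating, with
  0.1-s cosine ramps.
* **Epileptiform episodes**: 1–4 Hz sinusoids at a multiple (default 8×) of
  the *analytic* 0.5–10 Hz band RMS of the background, 1-s cosine ramps to
  avoid STFT step artifacts, applied across all rows.
* **Spikes**: homogeneous Poisson baseline (5 Hz) plus an independent
  Poisson boxcar (+15 spikes/s over 0–50 ms) after every tactile stimulus.
* **Protocol**: 50 tactile + 50 visual trials in randomized order,
  inter-trial intervals uniform in 3–5 s; the session duration auto-fits
  the schedule unless given.

Everything derives from a single mandatory seed; identical seeds produce
byte-identical session files.  Cohorts derive per-session seeds from a
master seed and apply group deltas (evoked amplitude scale, latency shift,
gamma amplitude scale) to the KO-like group only.

What the generator does **not** emulate: biophysical neuron models,
spike–LFP coupling, non-sinusoidal or depth-propagating epileptiform
morphology, behavioral covariates (locomotion, pupil), electrode drift, or
line noise.  Recovery of injected effects therefore demonstrates estimator
correctness and calibration under realistic noise spectra — not robustness
to every artifact of in-vivo data.

## Validation battery and problem sizes

`laminar_ephys.validation` fixes the desk-scale studies the acceptance
script and `tests/test_acceptance.py` both run (sizes chosen for a
single-CPU run and stated here as package choices):

* iCSD round trip on 64 rows × 20 µm, R = 0.5 mm;
* detector battery: 20 sessions of 600 s, each with one 12–40 s episode at
  8× band RMS plus one 5–8 s decoy (sparse events, a few percent duty — the
  regime the detector is meant for, given its self-normalized threshold),
  and 20 stationary sessions, on a 6-row patch around the 500-µm detection
  depth;
* gamma recovery: 6 replicate sessions of 50 visual trials on a 4-row
  patch, compared with the analytic expectation
  100·(a²/2)/(Δf·PSD(70 Hz)·n_bins);
* PETH recovery: 50 tactile trials, 10 clusters;
* rank-sum exactness: all 3418 tie-free inputs with n₁,n₂ ≤ 6 against a
  brute-force enumeration oracle;
* two-group cohort: 8 control-like vs 8 KO-like sessions, 48 rows, the full
  50+50 trial protocol, deltas ×0.3 amplitude / +5 ms latency / ×0.3 gamma;
  PSD metrics over the 0–400 µm band so measurement and truth average over
  the same rows.  Noise-free truth targets: the smoothed-truth peak for the
  amplitude metric (depth smoothing genuinely attenuates a Gaussian sink by
  σ_z/√(σ_z²+s²)), the configured latency for the time metric (depth-only
  smoothing cannot move a separable profile's temporal peak), and the
  analytic injected-power expectation for the gamma change;
* null calibration: 20 cohorts of 4 vs 4 sessions with zero deltas on a
  reduced 12-row patch (6+6 trials), counting comparisons with p < 0.05.

## Known limitations

* The spline iCSD assumes uniform electrode spacing, a known and fixed disk
  radius, and zero CSD beyond the outermost contacts; violations bias the
  depth profile near the edges.
* The dB-mean gamma scalar responds only logarithmically to narrow-band
  power increases; strong spectral lines move it by fractions of a dB.
* The exact rank-sum DP is O(n₁·n·ΣW) and is limited by `exact_limit`
  (default total n = 25); beyond that the normal approximation is used.
* The detector's full-session z-scoring is the literal method implemented;
  robust (median/MAD) z-scoring would tolerate higher event duty cycles but
  would be a different detector.
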