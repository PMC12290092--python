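# laminar-ephys

Analysis of laminar extracellular recordings from cortex: estimate
current-source density (CSD) from depth-resolved LFP with the spline
inverse-CSD method, quantify depth-resolved spectral power and
stimulus-induced gamma oscillations, detect epileptiform episodes by
z-scored low-frequency band power, build layer-resolved peristimulus time
histograms (PETHs) from sorted spikes, and compare per-session metrics
between two groups (e.g. genotypes) with the exact Wilcoxon rank-sum test.
A forward-model simulator generates complete synthetic sessions with known
ground truth, so every stage of the pipeline can be verified end to end.

The intended user records with dense laminar probes (Neuropixels-like,
LFP band 0.5–100 Hz at 2.5 kHz) in head-fixed rodents under sensory
stimulation and wants a reproducible, scriptable route from raw
depth-ordered voltage to statistics such as "the evoked CSD sink at 400 µm
is smaller and later in group B than in group A".

## The model at the core

The LFP φ at electrode depth *z_i* generated by a CSD profile *C(z)*
(uniform disks of radius *R* in a homogeneous medium of conductivity σ) is

    φ(z_i) = 1/(2σ) ∫ C(z) [ √((z − z_i)² + R²) − |z − z_i| ] dz

The spline iCSD method assumes *C* varies smoothly between contacts
(natural cubic spline through the values at the electrode depths, zero
outside), builds the forward matrix **F** against that basis by per-segment
Gauss–Legendre quadrature, and solves **F**·c = φ per time sample.  With
σ = 0.3 S/m, depths in mm and voltages in mV, the estimate comes out in
µA/mm³ and is finally smoothed along depth with a 0.1-mm Gaussian.
Epileptiform episodes are detected as runs of z > 2 lasting ≥ 10 s in the
median-corrected 0.5–10 Hz band power of the 500-µm LFP (2-s Hamming
windows, 0.1-s steps), and all data within 15 s of an event is excluded
from every other analysis.  See `docs/methods.md` for the full account.

## Worked example

Simulate a session with a known evoked sink and one injected epileptiform
episode, then run the detector and the CSD stage:

```python
from laminar_ephys import (SimConfig, TrialConfig, EpileptiformEpisode,
                           simulate_session, detect_session_events,
                           exclusion_mask_from_events, filter_trials,
                           trial_average, estimate_csd, smooth_csd_depth,
                           extract_peak_response, CSDConfig)

cfg = SimConfig(seed=42, n_depth_rows=48,
                trials=TrialConfig(n_tactile=50, n_visual=50),
                epileptiform=[EpileptiformEpisode(start_s=120.0,
                                                  duration_s=30.0)])
sess = simulate_session(cfg)

events, depth = detect_session_events(sess.lfp)
print(f"{len(events)} event(s) at {depth:.0f} um; first: "
      f"{events[0].start_s:.1f}-{events[0].end_s:.1f} s, peak z={events[0].peak_z:.1f}")

mask = exclusion_mask_from_events([(e.start_s, e.end_s) for e in events],
                                  pad_s=15.0, bounds=(0, sess.lfp.duration_s))
tactile = filter_trials(sess.trials.select("tactile"), mask, (-2.0, 0.4))
print(f"{len(tactile)} of 50 tactile trials survive exclusion")

avg = trial_average(sess.lfp, tactile, window_s=(-0.1, 0.4))
csd = smooth_csd_depth(estimate_csd(avg, CSDConfig()), 0.1)
amp, t_ms = extract_peak_response(csd, depth_um=400.0,
                                  search_window_s=(0.0, 0.06))
print(f"CSD peak at 400 um: {amp:.2f} uA/mm^3 at {t_ms:.1f} ms")
```

prints

```
1 event(s) at 500 um; first: 120.5-149.5 s, peak z=5.9
47 of 50 tactile trials survive exclusion
CSD peak at 400 um: -3.35 uA/mm^3 at 24.4 ms
```

The detected interval tracks the injected 120–150 s episode to within half
a second; three trials fell inside the event ± 15 s exclusion zone; and the
recovered sink is the configured −5 µA/mm³ truth attenuated by the 0.1-mm
depth smoothing and the overlapping return source (noise-free asymptote
≈ −3.2 µA/mm³), peaking within a sample or two of the configured 25-ms
latency.

The same stages are available from the shell (`laminar-ephys simulate /
detect-events / csd / psd / peth / compare / run-all`); `run-all` drives a
whole two-group study from one JSON config and writes per-session TSVs, a
rank-sum `comparison.tsv` and a reproducibility manifest.

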