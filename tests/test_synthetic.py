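
import numpy as np
import pytest

from laminar_ephys.csd import DepthTimeProfile, slab_potential
from laminar_ephys.synthetic import (EpileptiformEpisode, EvokedComponent,
                                     GammaConfig, GroupDeltas, SimConfig,
                                     SpikeConfig, TrialConfig,
                                     forward_lfp_from_csd,
                                     make_evoked_csd_truth, pink_band_rms, simulate_cohort,
                                     simulate_session)
from laminar_ephys.recording import write_session


def small_cfg(seed=0, **kw):
    defaults = dict(seed=seed, n_depth_rows=32, depth_spacing_um=20.0,
                    evoked=[EvokedComponent(depth_center_um=240.0,
                                            depth_sd_um=60.0,
                                            source_offset_um=160.0)],
                    gamma=GammaConfig(amplitude_mv=0.02,
                                      depth_band_um=(0.0, 200.0)),
                    trials=TrialConfig(n_tactile=3, n_visual=2),
                    spikes=SpikeConfig(n_clusters=2))
    defaults.update(kw)
    return SimConfig(**defaults)


class TestEvokedTruth:
    def test_charge_balance_at_every_time(self):
        truth = make_evoked_csd_truth(small_cfg())
        col_sums = truth.values.sum(axis=0)
        assert np.max(np.abs(col_sums)) < 1e-9 * np.max(np.abs(truth.values))

    def test_zero_amplitude_gives_zero_profile(self):
        cfg = small_cfg()
        cfg.evoked[0].peak_amplitude_uA_mm3 = 0.0
        truth = make_evoked_csd_truth(cfg)
        assert np.all(truth.values == 0.0)

    def test_sink_peak_at_configured_grid_point(self):
        cfg = small_cfg()
        truth = make_evoked_csd_truth(cfg)
        i_depth, i_time = np.unravel_index(np.argmin(truth.values),
                                           truth.values.shape)
        assert truth.depth_um[i_depth] == cfg.evoked[0].depth_center_um
        assert truth.time_s[i_time] == pytest.approx(cfg.evoked[0].latency_s,
                                                     abs=1.0 / cfg.sampling_rate_hz)

    def test_truncated_component_warns(self):
        cfg = small_cfg()
        cfg.evoked[0].depth_center_um = 600.0  # source at 760 off a 620-um probe
        with pytest.warns(UserWarning, match="probe span"):
            make_evoked_csd_truth(cfg)


class TestForwardOracle:
    def test_zero_csd_gives_zero_lfp(self):
        prof = DepthTimeProfile(depth_um=20.0 * np.arange(16),
                                time_s=np.arange(3) / 1e3,
                                values=np.zeros((16, 3)), units="uA_per_mm3")
        phi = forward_lfp_from_csd(prof)
        assert np.all(phi.values == 0.0)

    def test_uniform_slab_matches_closed_form(self):
        depths = 20.0 * np.arange(64)
        prof = DepthTimeProfile(depth_um=depths, time_s=np.array([0.0]),
                                values=np.full((64, 1), 2.5),
                                units="uA_per_mm3")
        phi = forward_lfp_from_csd(prof, 0.3, 500.0).values[:, 0]
        exact = slab_potential(depths / 1000.0, 0.0, depths[-1] / 1000.0,
                               2.5, 0.3, 0.5)
        assert np.max(np.abs(phi - exact)) < 1e-3 * np.max(np.abs(exact))

    def test_linearity_and_conductivity_scaling(self):
        rng = np.random.default_rng(0)
        depths = 20.0 * np.arange(24)
        t = np.arange(4) / 1e3
        a = DepthTimeProfile(depths, t, rng.standard_normal((24, 4)),
                             "uA_per_mm3")
        b = DepthTimeProfile(depths, t, rng.standard_normal((24, 4)),
                             "uA_per_mm3")
        mix = DepthTimeProfile(depths, t, 2.0 * a.values - 0.5 * b.values,
                               "uA_per_mm3")
        lhs = forward_lfp_from_csd(mix).values
        rhs = (2.0 * forward_lfp_from_csd(a).values
               - 0.5 * forward_lfp_from_csd(b).values)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-10, atol=1e-12)
        double_sigma = forward_lfp_from_csd(a, sigma_S_per_m=0.6).values
        np.testing.assert_allclose(double_sigma,
                                   forward_lfp_from_csd(a).values / 2.0,
                                   rtol=1e-12)


class TestSimulateSession:
    def test_same_seed_gives_byte_identical_sessions(self, tmp_path):
        for name in ("a", "b"):
            s = simulate_session(small_cfg(seed=11))
            write_session(tmp_path / name, s.geometry, s.lfp, s.trials, s.spikes)
        for f in ("meta.json", "lfp.bin", "trials.tsv", "spikes.tsv"):
            assert (tmp_path / "a" / f).read_bytes() == (tmp_path / "b" / f).read_bytes()

    def test_different_seeds_differ(self):
        a = simulate_session(small_cfg(seed=1))
        b = simulate_session(small_cfg(seed=2))
        assert not np.array_equal(a.lfp.values, b.lfp.values)

    def test_epileptiform_ground_truth_intervals(self):
        eps = [EpileptiformEpisode(start_s=20.0, duration_s=15.0),
               EpileptiformEpisode(start_s=60.0, duration_s=12.0)]
        cfg = small_cfg(seed=3, duration_s=100.0,
                        trials=TrialConfig(n_tactile=0, n_visual=0),
                        epileptiform=eps)
        s = simulate_session(cfg)
        assert s.truth.event_intervals == [(20.0, 35.0), (60.0, 72.0)]

    def test_schedule_overflow_is_an_error(self):
        cfg = small_cfg(seed=4, duration_s=10.0,
                        trials=TrialConfig(n_tactile=10, n_visual=10))
        with pytest.raises(ValueError, match="does not fit"):
            simulate_session(cfg)

    def test_trial_protocol_counts_and_iti(self):
        s = simulate_session(small_cfg(
            seed=5, trials=TrialConfig(n_tactile=6, n_visual=5)))
        df = s.trials.df
        assert (df["modality"] == "tactile").sum() == 6
        assert (df["modality"] == "visual").sum() == 5
        assert df["onset_s"].is_monotonic_increasing

    def test_pink_noise_band_rms_matches_analytic_law(self):
        cfg = small_cfg(seed=6, duration_s=120.0, evoked=[],
                        gamma=GammaConfig(amplitude_mv=0.0,
                                          depth_band_um=(0.0, 200.0)),
                        trials=TrialConfig(n_tactile=0, n_visual=0),
                        spikes=SpikeConfig(n_clusters=0))
        s = simulate_session(cfg)
        measured = s.lfp.values.std()
        assert measured == pytest.approx(cfg.noise.rms_mv, rel=0.1)
        from scipy.signal import butter, sosfiltfilt
        sos = butter(4, [0.5, 10.0], "bandpass", fs=cfg.sampling_rate_hz,
                     output="sos")
        band = sosfiltfilt(sos, s.lfp.values[0])
        expected = pink_band_rms(cfg.noise.rms_mv, cfg.noise.corner_hz,
                                 cfg.sampling_rate_hz / 2, (0.5, 10.0))
        assert band.std() == pytest.approx(expected, rel=0.2)


class TestCohort:
    def test_n_per_group_8_yields_16_members(self):
        members = simulate_cohort(small_cfg(), GroupDeltas(), 8, seed=1)
        assert len(members) == 16
        assert sum(m.group == "control" for m in members) == 8

    def test_deltas_only_affect_ko_configs(self):
        deltas = GroupDeltas(evoked_amplitude_scale=0.3,
                             latency_shift_s=0.005,
                             gamma_amplitude_scale=0.3)
        members = simulate_cohort(small_cfg(), deltas, 2, seed=1)
        ctrl = next(m for m in members if m.group == "control")
        ko = next(m for m in members if m.group == "ko")
        assert ko.config.evoked[0].peak_amplitude_uA_mm3 == pytest.approx(
            0.3 * ctrl.config.evoked[0].peak_amplitude_uA_mm3)
        assert ko.config.evoked[0].latency_s - ctrl.config.evoked[0].latency_s \
            == pytest.approx(0.005)
        assert ko.config.seed != ctrl.config.seed

    def test_zero_delta_groups_are_exchangeable(self):
        """Rank-sum p on a per-session scalar is super-uniform when the two
        groups differ only by their random seeds."""
        from laminar_ephys.stats import ranksum_test
        base = SimConfig(seed=0, n_depth_rows=4, depth_spacing_um=20.0,
                         duration_s=30.0, evoked=[],
                         gamma=GammaConfig(amplitude_mv=0.0,
                                           depth_band_um=(0.0, 60.0)),
                         trials=TrialConfig(n_tactile=0, n_visual=0),
                         spikes=SpikeConfig(n_clusters=0))
        pvals = []
        for rep in range(60):
            members = simulate_cohort(base, GroupDeltas(), 4, seed=1000 + rep)
            rms = {"control": [], "ko": []}
            for m in members:
                rms[m.group].append(float(m.simulate().lfp.values.std()))
            pvals.append(ranksum_test(rms["control"], rms["ko"]).p_two_sided)
        pvals = np.asarray(pvals)
        for alpha in (0.05, 0.1, 0.25, 0.5):
            se = np.sqrt(alpha * (1 - alpha) / len(pvals))
            assert (pvals <= alpha).mean() <= alpha + 3 * se
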