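import numpy as np
import pandas as pd
import pytest

from laminar_ephys.recording import (ChannelGeometry, LaminarLFP, SpikeTable,
                                     TrialTable, average_same_depth,
                                     read_session, reject_channels,
                                     write_session)


class TestSessionIO:
    def test_write_read_round_trip_is_identity(self, tiny_session, tmp_path):
        geometry, lfp, trials, spikes = tiny_session
        write_session(tmp_path / "s", geometry, lfp, trials, spikes)
        g2, l2, t2, s2 = read_session(tmp_path / "s")
        np.testing.assert_array_equal(g2.channel_index, geometry.channel_index)
        np.testing.assert_array_equal(g2.depth_um, geometry.depth_um)
        np.testing.assert_array_equal(g2.included, geometry.included)
        # values are on the quantization grid, so the round trip is exact
        np.testing.assert_array_equal(l2.values, lfp.values)
        assert l2.sampling_rate_hz == lfp.sampling_rate_hz
        pd.testing.assert_frame_equal(t2.df, trials.df)
        pd.testing.assert_frame_equal(s2.df, spikes.df)

    def test_write_is_byte_deterministic(self, tiny_session, tmp_path):
        geometry, lfp, trials, spikes = tiny_session
        for name in ("a", "b"):
            write_session(tmp_path / name, geometry, lfp, trials, spikes)
        for f in ("meta.json", "lfp.bin", "trials.tsv", "spikes.tsv"):
            assert (tmp_path / "a" / f).read_bytes() == (tmp_path / "b" / f).read_bytes()

    def test_channel_count_mismatch_is_hard_error(self, tiny_session, tmp_path):
        geometry, lfp, trials, spikes = tiny_session
        write_session(tmp_path / "s", geometry, lfp, trials, spikes)
        raw = (tmp_path / "s" / "lfp.bin").read_bytes()
        (tmp_path / "s" / "lfp.bin").write_bytes(raw[:-2])  # drop one sample
        with pytest.raises(ValueError, match="channel count"):
            read_session(tmp_path / "s")

    def test_int16_scale_conversion(self, tmp_path):
        geometry = ChannelGeometry([0], [0.0], [0.0], [True])
        lfp = LaminarLFP(values=np.array([[100 * 0.00195]]),
                         sampling_rate_hz=1000.0, depth_um=[0.0])
        write_session(tmp_path / "s", geometry, lfp, TrialTable.empty(),
                      SpikeTable.empty(), mv_per_bit=0.00195)
        raw = np.fromfile(tmp_path / "s" / "lfp.bin", dtype="<i2")
        assert raw[0] == 100
        _, l2, _, _ = read_session(tmp_path / "s")
        assert l2.values[0, 0] == pytest.approx(0.195)

    def test_empty_spike_table_writes_header_only(self, tiny_session, tmp_path):
        geometry, lfp, trials, _ = tiny_session
        write_session(tmp_path / "s", geometry, lfp, trials, SpikeTable.empty())
        lines = (tmp_path / "s" / "spikes.tsv").read_text().splitlines()
        assert lines == ["cluster_id\tspike_time_s\tcluster_depth_um"]

    def test_nan_lfp_is_refused(self):
        with pytest.raises(ValueError, match="finite"):
            LaminarLFP(values=np.array([[0.0, np.nan]]),
                       sampling_rate_hz=1000.0, depth_um=[0.0])

    def test_missing_tables_yield_empty_tables(self, tiny_session, tmp_path):
        geometry, lfp, trials, spikes = tiny_session
        write_session(tmp_path / "s", geometry, lfp, trials, spikes)
        (tmp_path / "s" / "trials.tsv").unlink()
        (tmp_path / "s" / "spikes.tsv").unlink()
        _, _, t2, s2 = read_session(tmp_path / "s")
        assert len(t2) == 0 and len(s2) == 0


class TestChannelRejection:
    def _lfp(self, values):
        values = np.asarray(values, dtype=float)
        return LaminarLFP(values=values, sampling_rate_hz=1000.0,
                          depth_um=20.0 * np.arange(values.shape[0]))

    def _geom(self, n):
        return ChannelGeometry(np.arange(n), 20.0 * np.arange(n),
                               np.zeros(n), np.ones(n, bool))

    def test_constant_channel_rejected_by_zero_variance_rule(self):
        rng = np.random.default_rng(0)
        values = rng.standard_normal((20, 500))
        values[7] = 0.0
        out = reject_channels(self._lfp(values), self._geom(20))
        assert not out.included[7]
        assert out.included.sum() == 19

    def test_loud_channel_rejected_by_log_rms_rule(self):
        # 5-channel fixture: hand-computed log-RMS robust z of the loud channel
        rng = np.random.default_rng(1)
        values = rng.standard_normal((5, 2000))
        values[2] *= 100.0
        rms = np.sqrt((values**2).mean(axis=1))
        log_rms = np.log(rms)
        med = np.median(log_rms)
        mad = 1.4826 * np.median(np.abs(log_rms - med))
        assert abs(log_rms[2] - med) / mad > 5.0  # the rule must fire
        out = reject_channels(self._lfp(values), self._geom(5))
        assert list(out.included) == [True, True, False, True, True]

    def test_false_positive_rate_below_one_percent(self):
        # homogeneous Gaussian channels, mad_k = 5: Monte-Carlo rejection rate
        rng = np.random.default_rng(7)
        n_rej = 0
        n_tot = 0
        for _ in range(1000):
            values = rng.standard_normal((20, 200))
            out = reject_channels(self._lfp(values), self._geom(20))
            n_rej += int((~out.included).sum())
            n_tot += 20
        assert n_rej / n_tot < 0.01

    def test_too_few_channels_error(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            reject_channels(self._lfp(np.zeros((1, 10)) + 1.0), self._geom(1))


class TestSameDepthAveraging:
    def test_mean_identity_and_depth_vector(self, tiny_geometry):
        values = np.zeros((4, 10))
        values[1] = 1.0  # depth 20
        values[2] = 3.0  # depth 20
        values[3] = 5.0  # depth 40
        lfp = LaminarLFP(values=values, sampling_rate_hz=1000.0,
                         depth_um=tiny_geometry.depth_um)
        out = average_same_depth(lfp, tiny_geometry)
        np.testing.assert_array_equal(out.depth_um, [0.0, 20.0, 40.0])
        assert out.values[1, 0] == pytest.approx(2.0)  # mean of 1 and 3
        assert out.values[2, 0] == pytest.approx(5.0)  # single channel row

    def test_idempotent_on_averaged_input(self, tiny_geometry):
        rng = np.random.default_rng(3)
        lfp = LaminarLFP(values=rng.standard_normal((4, 50)),
                         sampling_rate_hz=1000.0, depth_um=tiny_geometry.depth_um)
        once = average_same_depth(lfp, tiny_geometry)
        geom_rows = ChannelGeometry(np.arange(once.values.shape[0]),
                                    once.depth_um,
                                    np.zeros(once.values.shape[0]),
                                    np.ones(once.values.shape[0], bool))
        twice = average_same_depth(once, geom_rows)
        np.testing.assert_array_equal(once.values, twice.values)

    def test_depth_rows_without_included_channels_are_dropped(self, tiny_geometry):
        geom = ChannelGeometry(tiny_geometry.channel_index,
                               tiny_geometry.depth_um,
                               tiny_geometry.lateral_um,
                               [False, True, True, True])
        lfp = LaminarLFP(values=np.ones((4, 5)), sampling_rate_hz=1000.0,
                         depth_um=tiny_geometry.depth_um)
        out = average_same_depth(lfp, geom)
        np.testing.assert_array_equal(out.depth_um, [20.0, 40.0])
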