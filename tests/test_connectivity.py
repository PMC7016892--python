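import numpy as np
import pytest

from lfposc.connectivity import (ConnectivityResult, RegionScheme,
                                 connectivity_matrices,
                                 instantaneous_amplitude, regionalize,
                                 xcorr_max)

from conftest import make_recording


class TestInstantaneousAmplitude:
    def test_am_tone_envelope_tracks_modulator(self):
        rate = 500.0
        t = np.arange(int(120 * rate)) / rate
        modulator = 1.0 + 0.5 * np.sin(2 * np.pi * 0.2 * t)
        rec = make_recording(modulator * np.sin(2 * np.pi * 60.0 * t),
                             rate=rate)
        env = instantaneous_amplitude(rec, "fast-gamma").samples[0]
        core = slice(int(10 * rate), int(110 * rate))
        assert np.max(np.abs(env[core] - modulator[core])
                      / modulator[core]) < 0.02

    def test_constant_tone_constant_envelope(self):
        rate = 500.0
        t = np.arange(int(60 * rate)) / rate
        rec = make_recording(np.sin(2 * np.pi * 60.0 * t), rate=rate)
        env = instantaneous_amplitude(rec, "fast-gamma").samples[0]
        core = env[int(10 * rate):-int(10 * rate)]
        np.testing.assert_allclose(core, 1.0, atol=0.01)

    def test_zero_signal_zero_envelope(self):
        rec = make_recording(np.zeros(500 * 30), rate=500.0)
        env = instantaneous_amplitude(rec, "SO").samples
        np.testing.assert_allclose(env, 0.0, atol=1e-12)

    def test_band_beyond_nyquist_rejected(self):
        rec = make_recording(np.zeros(100 * 30), rate=100.0)
        with pytest.raises(ValueError, match="Nyquist"):
            instantaneous_amplitude(rec, "fast-gamma")


class TestXcorrMax:
    def test_identical_envelopes_give_unit_r_at_zero_lag(self, rng):
        env = np.abs(rng.standard_normal(10_000)) + 1.0
        r, lag = xcorr_max(env, env, 500.0, 200.0)
        assert r == pytest.approx(1.0, abs=1e-9)
        assert lag == 0.0

    def test_delayed_copy_recovers_lag_with_leader_negative(self, rng):
        # b is a delayed, a leads -> negative latency(a, b)
        rate, d = 500.0, 20  # 40 ms
        a = np.convolve(rng.standard_normal(60_000), np.ones(50) / 50, "same")
        b = np.roll(a, d)
        r, lag = xcorr_max(a[1000:-1000], b[1000:-1000], rate, 500.0)
        assert lag == pytest.approx(-40.0, abs=2.0)
        assert r > 0.95

    def test_independent_envelopes_stay_below_circular_null(self, rng):
        n = 150_000
        a = np.abs(rng.standard_normal(n))
        b = np.abs(rng.standard_normal(n))
        r, _ = xcorr_max(a, b, 500.0, 500.0)
        null = [xcorr_max(a, np.roll(b, int(s)), 500.0, 500.0)[0]
                for s in rng.integers(10_000, n - 10_000, 19)]
        assert r <= np.quantile(null, 0.95) * 1.5

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            xcorr_max(np.zeros(100), np.zeros(99), 500.0, 10.0)

    def test_lag_beyond_half_window_rejected(self):
        with pytest.raises(ValueError, match="half"):
            xcorr_max(np.zeros(100), np.zeros(100), 500.0, 1000.0)


class TestConnectivityMatrices:
    def test_matrices_recover_injected_lag_ladder(self, ladder_recording):
        cfg, rec, truth = ladder_recording
        res = connectivity_matrices(rec, "SO")
        np.testing.assert_allclose(res.latency_ms, truth.lag_ms, atol=2.0)
        assert res.coeff.min() > 0.9

    def test_pairwise_agrees_with_xcorr_max(self, ladder_recording):
        _, rec, _ = ladder_recording
        res = connectivity_matrices(rec, "SO", edge_trim_s=10.0)
        env = instantaneous_amplitude(rec, "SO").samples[:, 5000:-5000]
        r, lag = xcorr_max(env[0], env[3], rec.rate, 500.0)
        assert res.coeff[0, 3] == pytest.approx(r, abs=1e-9)
        assert res.latency_ms[0, 3] == pytest.approx(lag, abs=1e-9)

    def test_symmetry_and_antisymmetry_exact(self, ladder_recording):
        _, rec, _ = ladder_recording
        res = connectivity_matrices(rec, "SO")
        np.testing.assert_array_equal(res.coeff, res.coeff.T)
        np.testing.assert_array_equal(res.latency_ms, -res.latency_ms.T)
        np.testing.assert_array_equal(np.diag(res.coeff), 1.0)
        np.testing.assert_array_equal(np.diag(res.latency_ms), 0.0)

    def test_common_source_without_lags_gives_zero_latency(self):
        from lfposc.synth import SynthConfig, generate_lfp
        cfg = SynthConfig(n_channels=3, duration=120.0, rate=500.0,
                          band_power_fractions={"SO": 0.8, "theta": 0.2},
                          so_lag_per_channel=[0.0, 0.0, 0.0], seed=2)
        rec, _ = generate_lfp(cfg)
        res = connectivity_matrices(rec, "SO")
        np.testing.assert_allclose(res.latency_ms, 0.0, atol=2.0)
        assert res.coeff.min() > 0.95

    def test_shared_inband_copy_does_not_shift_latency(self, ladder_recording):
        """Adding the same constant-phase in-band component to both
        channels must not change the estimated latency beyond a sample."""
        _, rec, truth = ladder_recording
        rate = rec.rate
        t = np.arange(rec.n_samples) / rate
        common = 0.1 * rec.samples.std() * np.sin(2 * np.pi * 0.9 * t)
        rec2 = make_recording(rec.samples[[0, 3]] + common, rate=rate)
        res = connectivity_matrices(rec2, "SO")
        assert abs(res.latency_ms[0, 1] - truth.lag_ms[0, 3]) <= 4.0


class TestRegionalize:
    def make_result(self, lat, depths):
        n = len(depths)
        return ConnectivityResult(np.full((n, n), 0.5) + 0.5 * np.eye(n),
                                  lat, "SO", np.asarray(depths, float))

    def test_uniform_matrix_gives_uniform_regional_means(self):
        depths = [2300 - 100 * k for k in range(24)]
        res = self.make_result(np.zeros((24, 24)), depths)
        out = regionalize(res)
        assert all(v["coeff"] == pytest.approx(0.5)
                   for v in out["intra"].values())
        assert all(v["coeff"] == pytest.approx(0.5)
                   for v in out["cross"].values())

    def test_cross_regional_latency_is_mean_of_pair_lags(self):
        depths = [2300 - 100 * k for k in range(24)]
        lags = np.linspace(0.0, -69.0, 24)  # shallow channels lead
        lat = lags[:, None] - lags[None, :]
        res = self.make_result(lat, depths)
        out = regionalize(res)
        scheme = RegionScheme()
        ia = scheme.channels(np.asarray(depths, float), "L4/6")
        ib = scheme.channels(np.asarray(depths, float), "DG")
        expected = lat[np.ix_(ia, ib)].mean()
        assert out["cross"]["L4/6->DG"]["latency_ms"] == pytest.approx(expected)
        # cortex leads DG -> deep channels are delayed -> lat(L4/6, DG) < 0
        assert expected < 0

    def test_swapping_region_order_flips_latency_sign(self):
        depths = [2300 - 100 * k for k in range(24)]
        lags = np.linspace(0.0, -69.0, 24)
        lat = lags[:, None] - lags[None, :]
        res = self.make_result(lat, depths)
        fwd = regionalize(res, RegionScheme())
        swapped = regionalize(res, RegionScheme(
            order=("DG", "CA1", "L4/6", "L2/3")))
        assert fwd["cross"]["L4/6->DG"]["latency_ms"] == pytest.approx(
            -swapped["cross"]["DG->L4/6"]["latency_ms"])

    def test_region_with_single_channel_rejected(self):
        depths = [2300.0, 2200.0, 300.0]
        res = self.make_result(np.zeros((3, 3)), depths)
        with pytest.raises(ValueError, match="fewer than 2"):
            regionalize(res, RegionScheme())
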