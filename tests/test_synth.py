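import numpy as np
import pytest
from scipy.signal import find_peaks, welch

from lfposc.connectivity import instantaneous_amplitude, xcorr_max
from lfposc.synth import SynthConfig, generate_lfp, generate_physio

from conftest import SUM1_FRACTIONS


def oracle_glm_r2(phase, amplitude):
    """Independent normal-equations least squares of amplitude on
    {1, cos, sin} of phase; explained-variance fraction."""
    X = np.column_stack((np.ones_like(phase), np.cos(phase), np.sin(phase)))
    beta = np.linalg.solve(X.T @ X, X.T @ amplitude)
    resid = amplitude - X @ beta
    y = amplitude - amplitude.mean()
    return 1.0 - (resid @ resid) / (y @ y)


class TestConfigValidation:
    def test_fractions_must_sum_below_one(self):
        with pytest.raises(ValueError, match="sum"):
            SynthConfig(band_power_fractions={"SO": 0.8, "delta": 0.4})

    def test_pac_depth_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            SynthConfig(pac_depth={("SO", "fast-gamma"): 1.2})

    def test_epoch_outside_recording_rejected(self):
        with pytest.raises(ValueError, match="epoch"):
            SynthConfig(duration=300.0, rate=500.0,
                        unstable_epochs=[(250.0, 350.0, 1.0, "resp")])

    def test_lag_vector_length_checked(self):
        with pytest.raises(ValueError, match="per channel"):
            SynthConfig(n_channels=4, so_lag_per_channel=[0, 10])

    def test_non_integer_sample_count_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            SynthConfig(duration=1.0001, rate=500.0)


class TestGenerateLfp:
    def test_seed_determinism(self):
        cfg = SynthConfig(n_channels=2, duration=10.0, rate=500.0,
                          so_lag_per_channel=[0, 40], seed=9)
        a, _ = generate_lfp(cfg)
        b, _ = generate_lfp(cfg)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_ground_truth_lag_antisymmetry_and_sign(self):
        cfg = SynthConfig(n_channels=2, duration=10.0, rate=500.0,
                          so_lag_per_channel=[0, 40], seed=1)
        _, truth = generate_lfp(cfg)
        # channel 0 leads channel 1 by 40 ms -> negative under the
        # leader-negative convention
        assert truth.lag_ms[0, 1] == -40.0
        np.testing.assert_array_equal(truth.lag_ms, -truth.lag_ms.T)
        np.testing.assert_array_equal(np.diag(truth.lag_ms), 0.0)

    def test_null_structure_noise_only(self):
        """With all band fractions 0 the signal is pure 1/f background:
        low bands dominate in the 1/f ordering and channel envelopes
        show no above-chance correlation."""
        cfg = SynthConfig(n_channels=2, duration=300.0, rate=500.0,
                          band_power_fractions={}, so_lag_per_channel=[0, 40],
                          seed=3)
        rec, _ = generate_lfp(cfg)
        f, p = welch(rec.samples[0], fs=500.0, nperseg=5000)
        bands = [(0.1, 1.7), (1.7, 4.7), (4.7, 12.0), (12.0, 30.0)]
        pw = [np.trapezoid(p[(f >= lo) & (f <= hi)], f[(f >= lo) & (f <= hi)])
              for lo, hi in bands]
        assert pw == sorted(pw, reverse=True)  # 1/f profile decreases
        env = instantaneous_amplitude(rec, "SO").samples[:, 5000:-5000]
        r, _ = xcorr_max(env[0], env[1], 500.0, 500.0)
        # circular-shift null for the chance level
        rng = np.random.default_rng(0)
        null = [xcorr_max(env[0], np.roll(env[1], int(s)), 500.0, 500.0)[0]
                for s in rng.integers(25000, 100000, 19)]
        assert r < np.quantile(null, 0.95) * 1.5

    def test_band_variance_fractions_match_request(self):
        cfg = SynthConfig(n_channels=1, duration=300.0, rate=500.0,
                          band_power_fractions=dict(SUM1_FRACTIONS),
                          so_lag_per_channel=[0.0], seed=12)
        rec, _ = generate_lfp(cfg)
        f, p = welch(rec.samples[0], fs=500.0, nperseg=5000)
        total = np.trapezoid(p, f)
        for (lo, hi), frac in zip(
                [(0.1, 1.7), (1.7, 4.7), (45, 90)],
                [SUM1_FRACTIONS["SO"], SUM1_FRACTIONS["delta"],
                 SUM1_FRACTIONS["fast-gamma"]]):
            m = (f >= lo) & (f <= hi)
            rel = np.trapezoid(p[m], f[m]) / total
            assert abs(rel - frac) / frac < 0.15

    def test_pac_injection_detected_by_oracle_regression(self):
        """Injected SO->fast-gamma coupling at depth 0.8 must raise the
        oracle GLM index at least tenfold above the depth-0 index."""
        from scipy.signal import hilbert
        from lfposc.connectivity import band_passed

        def oracle_index(depth, seed):
            cfg = SynthConfig(
                n_channels=1, duration=300.0, rate=500.0,
                band_power_fractions={"SO": 0.6, "fast-gamma": 0.4},
                so_lag_per_channel=[0.0],
                pac_depth={("SO", "fast-gamma"): depth}, seed=seed)
            rec, _ = generate_lfp(cfg)
            phase = np.angle(hilbert(band_passed(rec, "SO").samples[0]))
            amp = np.abs(hilbert(band_passed(rec, "fast-gamma").samples[0]))
            return oracle_glm_r2(phase, amp)

        coupled = oracle_index(0.8, seed=21)
        null = oracle_index(0.0, seed=22)
        assert coupled >= 10 * null
        assert null < 0.01


class TestGeneratePhysio:
    def test_seed_determinism_bit_identical(self):
        cfg = SynthConfig(n_channels=1, duration=30.0, rate=500.0,
                          so_lag_per_channel=[0.0], seed=5)
        e1, r1 = generate_physio(cfg)
        e2, r2 = generate_physio(cfg)
        np.testing.assert_array_equal(e1.samples, e2.samples)
        np.testing.assert_array_equal(r1.samples, r2.samples)

    def test_stable_rates_give_constant_intervals(self):
        cfg = SynthConfig(n_channels=1, duration=120.0, rate=500.0,
                          so_lag_per_channel=[0.0], ecg_jitter=0.01,
                          resp_jitter=0.0, seed=6)
        ecg, resp = generate_physio(cfg)
        pk, _ = find_peaks(ecg.samples, height=0.5, distance=25)
        iei = np.diff(pk) / 500.0
        assert abs(np.median(iei) - 1.0 / cfg.ecg_rate) < 0.01
        assert iei.std() < 5 * 0.01 / cfg.ecg_rate  # within jitter scale

    def test_unstable_epoch_shifts_breath_count(self):
        """A +1 Hz respiration epoch over 100 s must contain ~(rate+1)*100
        breaths, the rest of the trace ~rate per second."""
        cfg = SynthConfig(n_channels=1, duration=400.0, rate=500.0,
                          so_lag_per_channel=[0.0], resp_jitter=0.0,
                          unstable_epochs=[(100.0, 200.0, 1.0, "resp")],
                          seed=8)
        _, resp = generate_physio(cfg)
        pk, _ = find_peaks(resp.samples, height=0.8, distance=100)
        t = pk / 500.0
        inside = np.sum((t >= 100.0) & (t < 200.0))
        before = np.sum(t < 100.0)
        assert abs(inside - (cfg.resp_rate + 1.0) * 100) <= 5
        assert abs(before - cfg.resp_rate * 100) <= 5
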