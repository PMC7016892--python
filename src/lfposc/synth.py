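"""Synthetic laminar LFP and physiology with fully known ground truth.

The generator emulates the statistical structure of anesthetized
cortico-hippocampal recordings: a 1/f background plus band-limited
rhythms whose variance fractions are prescribed, a slow-oscillation (SO)
component that propagates across channels with configurable lags of tens
of milliseconds, controllable nesting of high-frequency amplitude on SO
phase, and ECG/respiration traces with stable baseline rates into which
anomalous epochs can be injected.  Every injected feature is returned as
:class:`GroundTruth` so downstream stages (band power, envelope
connectivity, phase-amplitude coupling, stable-window selection) can be
verified without animal data.

Band-limited components are synthesized in the frequency domain with
exact band edges, so the injected variance fractions tile the band
scheme without cross-band spill; the analysis stages keep their own
zero-phase Butterworth band-passing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import hilbert

from .bands import DEFAULT_BANDS
from .containers import MultiChannelRecording, PhysioTrace, default_channel_depths

__all__ = ["SynthConfig", "GroundTruth", "generate_lfp", "generate_physio"]


def _default_fractions() -> dict[str, float]:
    # SO-dominated spectrum: together with the low-frequency-weighted 1/f
    # remainder (0.10) the Low range carries ~70% of total power, as seen
    # under urethane anesthesia.
    return {
        "SO": 0.50,
        "delta": 0.15,
        "theta": 0.08,
        "beta": 0.05,
        "slow-gamma": 0.04,
        "fast-gamma": 0.04,
        "epsilon": 0.04,
    }


def _default_lags(n: int) -> list[float]:
    # Cortex (shallow, high channel index) leads DG (deep, channel 0) by
    # ~70 ms, the scale of observed cortico-hippocampal SO propagation.
    if n <= 1:
        return [0.0] * n
    return [-70.0 * k / (n - 1) for k in range(n)]


@dataclass
class SynthConfig:
    """Configuration of the synthetic recording session.

    Attributes
    ----------
    n_channels, duration, rate
        Probe geometry and native clock.  ``duration * rate`` must be an
        integer number of samples.
    band_power_fractions
        Fraction of total LFP variance per elementary band; values >= 0,
        sum <= 1, the remainder is 1/f broadband noise.
    so_lag_per_channel
        Delay (ms) of each channel's SO component relative to channel 0.
        Negative values mean the channel leads channel 0.
    pac_depth
        Modulation depth ``m`` in [0, 1] per (phase-band, amplitude-band)
        pair: the amplitude-band component is multiplied by
        ``1 + m cos(phase)`` and re-standardized so band variance is
        preserved.
    noise_exponent
        Spectral slope of the 1/f background (PSD ~ f**-exponent).
    ecg_rate, resp_rate
        Baseline heart and breathing rates, Hz.
    unstable_epochs
        ``(start_s, end_s, rate_offset_hz, which)`` with ``which`` in
        {"ecg", "resp"}: within the epoch the instantaneous rate of that
        trace is offset by the requested amount.
    """

    n_channels: int = 24
    duration: float = 330.0
    rate: float = 10_000.0
    band_power_fractions: dict[str, float] = field(default_factory=_default_fractions)
    so_lag_per_channel: Optional[Sequence[float]] = None
    pac_depth: dict[tuple[str, str], float] = field(default_factory=dict)
    noise_exponent: float = 2.0
    total_std: float = 150.0  # uV; arbitrary scale, the methods are scale-free
    ecg_rate: float = 5.0
    resp_rate: float = 2.0
    #: slow bands built from a shared channel-0 master delayed by
    #: so_lag_per_channel — slow waves propagate coherently across the
    #: laminar probe, so both SO and delta travel with the same lags
    propagating_bands: tuple[str, ...] = ("SO", "delta")
    ecg_jitter: float = 0.02  # fractional inter-beat-interval jitter
    resp_jitter: float = 0.02
    unstable_epochs: list[tuple[float, float, float, str]] = field(default_factory=list)
    band_edges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.duration <= 0 or self.rate <= 0:
            raise ValueError("duration and rate must be positive")
        n = self.duration * self.rate
        if abs(n - round(n)) > 1e-6:
            raise ValueError("duration * rate must be an integer sample count")
        fr = self.band_power_fractions
        if any(v < 0 for v in fr.values()):
            raise ValueError("band power fractions must be >= 0")
        if sum(fr.values()) > 1.0 + 1e-9:
            raise ValueError("band power fractions must sum to <= 1")
        unknown = set(fr) - set(self.band_edges)
        if unknown:
            raise ValueError(f"fractions given for unknown bands {sorted(unknown)}")
        if self.so_lag_per_channel is None:
            self.so_lag_per_channel = _default_lags(self.n_channels)
        lags = list(self.so_lag_per_channel)
        if len(lags) != self.n_channels:
            raise ValueError("so_lag_per_channel must have one entry per channel")
        if any(abs(l) >= self.duration * 1e3 for l in lags):
            raise ValueError("SO lag exceeds recording duration")
        for (pb, ab), m in self.pac_depth.items():
            if not 0.0 <= m <= 1.0:
                raise ValueError(f"PAC depth for ({pb}, {ab}) outside [0, 1]: {m}")
            for b in (pb, ab):
                if b not in self.band_edges:
                    raise ValueError(f"PAC references unknown band {b!r}")
        for (t0, t1, _, which) in self.unstable_epochs:
            if not (0 <= t0 < t1 <= self.duration):
                raise ValueError(f"unstable epoch ({t0}, {t1}) outside [0, duration]")
            if which not in ("ecg", "resp"):
                raise ValueError(f"epoch trace must be 'ecg' or 'resp', got {which!r}")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.rate))


@dataclass
class GroundTruth:
    """Injected structure of a synthetic session, for verification.

    ``lag_ms[i, j]`` follows the analysis sign convention: negative when
    channel ``i`` leads channel ``j``; anti-symmetric with zero diagonal.
    """

    lag_ms: np.ndarray
    pac_depth: dict[tuple[str, str], float]
    band_power_fractions: dict[str, float]
    unstable_epochs: list[tuple[float, float, float, str]]

    def epoch_samples(self, which: str, rate: float) -> list[tuple[int, int]]:
        """Sample-index ranges of the unstable epochs of one trace."""
        return [
            (int(round(t0 * rate)), int(round(t1 * rate)))
            for (t0, t1, _, w) in self.unstable_epochs
            if w == which
        ]


def _band_noise(rng: np.random.Generator, n: int, rate: float,
                edges: tuple[float, float]) -> np.ndarray:
    """Unit-variance Gaussian process with spectrum confined to [lo, hi).

    Synthesized in the frequency domain with exact band edges so the
    injected variance fractions tile the band scheme without cross-band
    spill (a causal filter's skirts would systematically shift several
    percent of each band's power into its neighbours, corrupting the
    power ground truth).
    """
    lo, hi = edges
    if hi >= rate / 2:
        raise ValueError(f"band edge {hi} Hz at or above Nyquist ({rate / 2} Hz)")
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    mask = (freqs >= lo) & (freqs < hi)
    if not mask.any():
        raise ValueError(f"band {edges} unresolvable at length {n}")
    spec = np.where(mask, rng.standard_normal(freqs.size)
                    + 1j * rng.standard_normal(freqs.size), 0.0)
    x = np.fft.irfft(spec, n=n)
    return x / x.std()


def _one_over_f(rng: np.random.Generator, n: int, rate: float,
                exponent: float) -> np.ndarray:
    """Unit-variance 1/f**exponent background noise."""
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = shape * (rng.standard_normal(freqs.size)
                    + 1j * rng.standard_normal(freqs.size))
    x = np.fft.irfft(spec, n=n)
    return x / x.std()


def _fractional_delay(x: np.ndarray, delay_s: float, rate: float) -> np.ndarray:
    """Circularly delay ``x`` by ``delay_s`` seconds (FFT phase ramp).

    Exact for non-integer sample delays; the circular wrap is negligible
    for stationary noise with delays far below the record length.
    """
    if delay_s == 0.0:
        return x.copy()
    n = x.size
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    return np.fft.irfft(np.fft.rfft(x) * np.exp(-2j * np.pi * freqs * delay_s), n=n)


def generate_lfp(config: SynthConfig) -> tuple[MultiChannelRecording, GroundTruth]:
    """Generate the multichannel LFP and its ground truth.

    Each channel is a sum of band-limited Gaussian processes scaled to
    the requested variance fractions plus 1/f noise carrying the
    remainder.  The SO component of channel ``k`` is the channel-0 SO
    component delayed by ``so_lag_per_channel[k]``; other band components
    are independent across channels.  PAC is injected by modulating the
    amplitude-band component with ``1 + m cos(phase)`` of the phase-band
    component (same channel), then re-standardizing to the target band
    variance so power and coupling ground truths stay orthogonal.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    rate = config.rate
    fr = config.band_power_fractions
    noise_frac = max(0.0, 1.0 - sum(fr.values()))
    lags_ms = np.asarray(config.so_lag_per_channel, dtype=float)

    # Shared slow-wave sources (channel 0's components), delayed per
    # channel; other bands are independent across channels.
    masters: dict[str, np.ndarray] = {}
    pac_phase_bands = {pb for pb, _ in config.pac_depth}
    for band in config.propagating_bands:
        if fr.get(band, 0.0) > 0 or band in pac_phase_bands:
            masters[band] = _band_noise(rng, n, rate, config.band_edges[band])

    samples = np.zeros((config.n_channels, n))
    for ch in range(config.n_channels):
        comps: dict[str, np.ndarray] = {}
        for band, frac in fr.items():
            if frac == 0.0:
                continue
            if band in masters:
                x = _fractional_delay(masters[band], lags_ms[ch] / 1e3, rate)
                x = x / x.std()
            else:
                x = _band_noise(rng, n, rate, config.band_edges[band])
            comps[band] = x
        for (pband, aband), m in config.pac_depth.items():
            if m == 0.0 or aband not in comps:
                continue
            if pband in comps:
                phase_src = comps[pband]
            elif pband in masters:
                phase_src = _fractional_delay(masters[pband], lags_ms[ch] / 1e3,
                                              rate)
            else:
                raise ValueError(
                    f"PAC phase band {pband!r} has no generated component"
                )
            phi = np.angle(hilbert(phase_src))
            mod = comps[aband] * (1.0 + m * np.cos(phi))
            comps[aband] = mod / mod.std()
        for band, x in comps.items():
            samples[ch] += np.sqrt(fr[band]) * config.total_std * x
        if noise_frac > 0:
            samples[ch] += (np.sqrt(noise_frac) * config.total_std
                            * _one_over_f(rng, n, rate, config.noise_exponent))

    rec = MultiChannelRecording(
        samples, rate, default_channel_depths(config.n_channels)
    )
    truth = GroundTruth(
        lag_ms=lags_ms[:, None] - lags_ms[None, :],
        pac_depth=dict(config.pac_depth),
        band_power_fractions=dict(fr),
        unstable_epochs=list(config.unstable_epochs),
    )
    return rec, truth


def _event_times(rng: np.random.Generator, config: SynthConfig, which: str,
                 base_rate: float, jitter: float) -> np.ndarray:
    """Event times from the piecewise-constant instantaneous rate."""
    epochs = [(t0, t1, off) for (t0, t1, off, w) in config.unstable_epochs
              if w == which]

    def rate_at(t: float) -> float:
        r = base_rate
        for (t0, t1, off) in epochs:
            if t0 <= t < t1:
                r += off
        return max(r, 0.05)

    times = []
    t = float(rng.uniform(0, 1.0 / base_rate))
    while t < config.duration:
        times.append(t)
        iei = (1.0 / rate_at(t)) * (1.0 + jitter * rng.standard_normal())
        t += max(iei, 0.01)
    return np.asarray(times)


def _ecg_template(rate: float) -> np.ndarray:
    """20 ms biphasic spike (Gaussian derivative), peak-normalized."""
    t = np.arange(-0.01, 0.01, 1.0 / rate)
    sigma = 0.004
    w = -t * np.exp(-(t ** 2) / (2 * sigma ** 2))
    return w / np.abs(w).max()


def generate_physio(config: SynthConfig) -> tuple[PhysioTrace, PhysioTrace]:
    """Generate ECG and respiration traces time-locked to the LFP clock.

    ECG is a train of 20 ms biphasic spikes at ``ecg_rate``; respiration
    is a rectified sine at ``resp_rate``.  Within each unstable epoch the
    instantaneous event rate of the named trace is offset by the
    requested amount.  Identical config and seed give bit-identical
    traces; the physiology stream is seeded independently of the LFP so
    the two generators can be used separately.
    """
    rng = np.random.default_rng((config.seed, 0x9E3779B9))
    n = config.n_samples
    rate = config.rate

    # ECG: spike template train plus a small baseline noise floor.
    beat_times = _event_times(rng, config, "ecg", config.ecg_rate, config.ecg_jitter)
    if beat_times.size < 2:
        raise ValueError("duration too short for the configured ecg_rate")
    ecg = 0.01 * rng.standard_normal(n)
    tmpl = _ecg_template(rate)
    half = tmpl.size // 2
    for bt in beat_times:
        i = int(round(bt * rate))
        lo, hi = max(0, i - half), min(n, i - half + tmpl.size)
        ecg[lo:hi] += tmpl[lo - (i - half): hi - (i - half)]

    # Respiration: rectified sine with phase advanced at the (offset)
    # instantaneous rate; |sin(phi/2)| peaks once per 2*pi of phi.
    epochs = [(t0, t1, off) for (t0, t1, off, w) in config.unstable_epochs
              if w == "resp"]
    t = np.arange(n) / rate
    inst_rate = np.full(n, config.resp_rate)
    for (t0, t1, off) in epochs:
        inst_rate[(t >= t0) & (t < t1)] = max(config.resp_rate + off, 0.05)
    # slow multiplicative rate jitter (~0.05 Hz bandwidth); needs a trace
    # long enough to resolve the jitter band
    if config.resp_jitter > 0 and config.duration > 1.0 / 0.05:
        slow = _band_noise(rng, n, rate, (0.01, 0.05))
        inst_rate = inst_rate * (1.0 + config.resp_jitter * slow)
    phi = 2.0 * np.pi * np.cumsum(inst_rate) / rate
    resp = np.abs(np.sin(phi / 2.0)) + 0.01 * rng.standard_normal(n)

    return (
        PhysioTrace(ecg, rate, "ecg"),
        PhysioTrace(resp, rate, "respiration"),
    )
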