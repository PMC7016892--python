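"""Envelope-based functional connectivity with signed latencies.

For a chosen band, each channel is zero-phase band-passed and its
instantaneous amplitude taken as the modulus of the analytic (Hilbert)
signal.  Connectivity between two channels is the maximal normalized
cross-correlation of their mean-subtracted envelopes over a bounded lag
range; the lag at the maximum is the latency.

Sign convention: ``latency(A, B) < 0`` means A leads B (A's envelope
precedes B's).  With channels ordered deepest-first this makes a cortex
that anticipates the dentate gyrus produce a negative cortex-vs-DG
latency.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, correlate, correlation_lags, hilbert, sosfiltfilt

from .bands import DEFAULT_BANDS, DEFAULT_REGIONS
from .containers import MultiChannelRecording

#: default lag search ranges, generous relative to the tens-of-ms
#: propagation lags expected between cortex and hippocampus
DEFAULT_MAX_LAG_MS = {"SO": 500.0, "delta": 250.0}


@dataclass
class RegionScheme:
    """Channel -> anatomical region map derived from electrode depths."""

    regions: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_REGIONS)
    )
    #: fixed ordering (superficial to deep) so cross-regional latency
    #: signs are coherent across sessions
    order: tuple[str, ...] = ("L2/3", "L4/6", "CA1", "DG")

    def channels(self, depths: np.ndarray, region: str) -> np.ndarray:
        lo, hi = self.regions[region]
        return np.flatnonzero((depths >= lo - 1e-9) & (depths <= hi + 1e-9))


@dataclass
class ConnectivityResult:
    """All-pairs maximal envelope cross-correlation and signed latency.

    ``coeff`` is symmetric with unit diagonal; ``latency_ms`` is
    anti-symmetric with zero diagonal (``latency_ms[i, j] < 0``: channel
    i leads channel j).
    """

    coeff: np.ndarray
    latency_ms: np.ndarray
    band: str
    channel_depths: np.ndarray | None = None


def band_passed(rec: MultiChannelRecording, band: str | tuple[float, float],
                order: int = 5) -> MultiChannelRecording:
    """Zero-phase order-5 Butterworth band-pass of every channel."""
    edges = DEFAULT_BANDS[band] if isinstance(band, str) else tuple(band)
    if edges[1] >= rec.rate / 2:
        raise ValueError(
            f"band {edges} exceeds Nyquist ({rec.rate / 2} Hz)"
        )
    sos = butter(order, edges, btype="bandpass", fs=rec.rate, output="sos")
    return replace(rec, samples=sosfiltfilt(sos, rec.samples, axis=1))


def instantaneous_amplitude(rec: MultiChannelRecording,
                            band: str | tuple[float, float]
                            ) -> MultiChannelRecording:
    """Per-channel envelope: modulus of the analytic signal of the
    band-passed trace.  Non-negative, same length and clock."""
    bp = band_passed(rec, band)
    return replace(bp, samples=np.abs(hilbert(bp.samples, axis=1)))


def xcorr_max(env_a: np.ndarray, env_b: np.ndarray, rate: float,
              max_lag_ms: float) -> tuple[float, float]:
    """Maximal normalized cross-correlation and its signed lag.

    ``c(tau) = corr(env_a(t + tau), env_b(t))`` on the sample-lag grid;
    returns ``(max |c|, latency_ms)`` with the latency at the maximizing
    lag.  Negative latency: A leads B.
    """
    a = np.asarray(env_a, float)
    b = np.asarray(env_b, float)
    if a.shape != b.shape:
        raise ValueError("envelopes must have equal length")
    n = a.size
    max_lag = int(round(max_lag_ms / 1e3 * rate))
    if max_lag >= n // 2:
        raise ValueError("max_lag exceeds half the window")
    a = a - a.mean()
    b = b - b.mean()
    denom = n * a.std() * b.std()
    if denom == 0:
        return 0.0, 0.0
    c = correlate(a, b, mode="full", method="fft") / denom
    lags = correlation_lags(n, n, mode="full")
    keep = np.abs(lags) <= max_lag
    c, lags = c[keep], lags[keep]
    i = int(np.argmax(np.abs(c)))
    return float(np.abs(c[i])), float(lags[i] * 1e3 / rate)


def connectivity_matrices(rec: MultiChannelRecording,
                          band: str | tuple[float, float] = "SO",
                          max_lag_ms: float | None = None,
                          edge_trim_s: float | None = None) -> ConnectivityResult:
    """All-pairs envelope connectivity for one band.

    Computes the upper triangle and reflects, enforcing symmetry of the
    coefficients and anti-symmetry of the latencies by construction.
    ``edge_trim_s`` seconds are discarded at both ends of the envelopes
    before correlating: filter and Hilbert transients at the record
    boundaries sit at the same absolute time on every channel, i.e. they
    are a zero-lag correlated artifact that would bias latencies toward
    zero.
    """
    band_name = band if isinstance(band, str) else f"{band[0]}-{band[1]}Hz"
    if max_lag_ms is None:
        max_lag_ms = DEFAULT_MAX_LAG_MS.get(band_name, 500.0)
    env = instantaneous_amplitude(rec, band)
    if edge_trim_s is None:
        edge_trim_s = min(10.0, rec.duration / 10.0)
    trim = int(round(edge_trim_s * rec.rate))
    if 2 * trim >= rec.n_samples // 2:
        raise ValueError("edge_trim_s too large for this window")
    e = env.samples[:, trim:rec.n_samples - trim or None]
    e = e - e.mean(axis=1, keepdims=True)
    n_ch, n = e.shape
    rate = rec.rate
    max_lag = int(round(max_lag_ms / 1e3 * rate))
    if max_lag >= n // 2:
        raise ValueError("max_lag exceeds half the window")
    stds = e.std(axis=1)

    # one FFT per channel, one inverse per pair
    nfft = 1 << int(np.ceil(np.log2(2 * n - 1)))
    F = np.fft.rfft(e, n=nfft, axis=1)
    coeff = np.eye(n_ch)
    latency = np.zeros((n_ch, n_ch))
    lag_grid = np.arange(-max_lag, max_lag + 1)
    for i in range(n_ch):
        for j in range(i + 1, n_ch):
            cc = np.fft.irfft(F[i] * np.conj(F[j]), n=nfft)
            # lag tau of corr(a(t+tau), b(t)) lives at index tau (mod nfft)
            c = np.concatenate((cc[nfft - max_lag:], cc[:max_lag + 1]))
            c /= n * stds[i] * stds[j]
            k = int(np.argmax(np.abs(c)))
            coeff[i, j] = coeff[j, i] = abs(c[k])
            latency[i, j] = lag_grid[k] * 1e3 / rate
            latency[j, i] = -latency[i, j]
    return ConnectivityResult(coeff, latency, band_name, rec.channel_depths)


def regionalize(result: ConnectivityResult,
                scheme: RegionScheme | None = None) -> dict:
    """Average coefficients and latencies within and between regions.

    Intraregional means exclude the diagonal; cross-regional means run
    over ordered pairs (first region's channels as the leading index) so
    latency signs are coherent with ``scheme.order``.
    """
    scheme = scheme or RegionScheme()
    if result.channel_depths is None:
        raise ValueError("result carries no channel depths to regionalize")
    depths = np.asarray(result.channel_depths)
    chan = {r: scheme.channels(depths, r) for r in scheme.order}
    out: dict = {"intra": {}, "cross": {}}
    for r in scheme.order:
        ix = chan[r]
        if ix.size < 2:
            raise ValueError(f"region {r!r} has fewer than 2 channels")
        sub_c = result.coeff[np.ix_(ix, ix)]
        sub_l = result.latency_ms[np.ix_(ix, ix)]
        off = ~np.eye(ix.size, dtype=bool)
        # latency mean over unordered pairs is 0 by anti-symmetry; report
        # the coefficient mean only for intraregional summaries
        out["intra"][r] = {"coeff": float(sub_c[off].mean())}
    for a_i, ra in enumerate(scheme.order):
        for rb in scheme.order[a_i + 1:]:
            ia, ib = chan[ra], chan[rb]
            block_c = result.coeff[np.ix_(ia, ib)]
            block_l = result.latency_ms[np.ix_(ia, ib)]
            out["cross"][f"{ra}->{rb}"] = {
                "coeff": float(block_c.mean()),
                "latency_ms": float(block_l.mean()),
            }
    return out
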