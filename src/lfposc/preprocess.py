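"""Signal cleaning and decimation.

The chain applied to raw traces is: Gaussian comb notch at the line
frequency and its harmonics -> running-median baseline removal ->
zero-phase Butterworth low-pass -> integer decimation.  All filtering is
zero-phase so envelope and phase estimates downstream are not shifted.
Default low-pass cutoffs / target rates: LFP 190 Hz -> 500 Hz, ECG
25 Hz -> 50 Hz, respiration 10 Hz -> 20 Hz, with filter order 5.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Union

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .containers import MultiChannelRecording, PhysioTrace

Trace = Union[MultiChannelRecording, PhysioTrace]

#: per-kind defaults: (low-pass cutoff Hz, target rate Hz, median window s)
DEFAULT_CHAIN = {
    "lfp": (190.0, 500.0, 10.0),
    "ecg": (25.0, 50.0, 1.0),
    "respiration": (10.0, 20.0, 5.0),
}


@dataclass
class FilterSpec:
    """Butterworth filter specification for :func:`zero_phase_filter`."""

    kind: str  # "low-pass" or "band-pass"
    order: int = 5
    edges: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("low-pass", "band-pass"):
            raise ValueError(f"unsupported filter kind {self.kind!r}")
        if self.order < 1:
            raise ValueError("order must be >= 1")
        n_edges = 1 if self.kind == "low-pass" else 2
        if len(self.edges) != n_edges:
            raise ValueError(f"{self.kind} needs {n_edges} edge(s)")

    def sos(self, rate: float) -> np.ndarray:
        if any(not 0 < e < rate / 2 for e in self.edges):
            raise ValueError(
                f"filter edges {self.edges} outside (0, {rate / 2}) Hz"
            )
        btype = "lowpass" if self.kind == "low-pass" else "bandpass"
        edges = self.edges[0] if self.kind == "low-pass" else self.edges
        return butter(self.order, edges, btype=btype, fs=rate, output="sos")


def _apply(trace: Trace, fn) -> Trace:
    """Apply a 1-D sample transform to every channel of a trace."""
    if isinstance(trace, MultiChannelRecording):
        out = np.stack([fn(ch) for ch in trace.samples])
        return replace(trace, samples=out)
    return replace(trace, samples=fn(trace.samples))


def remove_line_noise(trace: Trace, center: float = 50.0, n_harmonics: int = 3,
                      sigma: float = 1.0) -> Trace:
    """Frequency-domain Gaussian comb notch at ``center`` and harmonics.

    Each notch multiplies the spectrum by ``1 - exp(-(f - k*center)^2 /
    (2 sigma^2))`` (full attenuation at the harmonic, width ``sigma``).
    Zero phase shift, length preserved.
    """
    rate = trace.rate
    if center * n_harmonics >= rate / 2:
        raise ValueError(
            f"harmonic {center * n_harmonics} Hz at or above Nyquist ({rate / 2})"
        )

    def notch(x: np.ndarray) -> np.ndarray:
        n = x.size
        freqs = np.fft.rfftfreq(n, d=1.0 / rate)
        gain = np.ones_like(freqs)
        for k in range(1, n_harmonics + 1):
            gain *= 1.0 - np.exp(-((freqs - k * center) ** 2) / (2.0 * sigma ** 2))
        return np.fft.irfft(np.fft.rfft(x) * gain, n=n)

    return _apply(trace, notch)


def zero_phase_filter(trace: Trace, spec: FilterSpec) -> Trace:
    """Forward-backward (zero group delay) Butterworth filtering.

    The effective magnitude response is the square of the single-pass
    Butterworth response.
    """
    sos = spec.sos(trace.rate)
    return _apply(trace, lambda x: sosfiltfilt(sos, x))


def remove_baseline(trace: Trace, window_s: float = 10.0) -> Trace:
    """Subtract a running median (window ``window_s`` s, edges shrink)."""
    w = int(round(window_s * trace.rate))
    if w < 3:
        raise ValueError("median window must span at least 3 samples")
    n = (trace.samples.shape[-1])
    if w > n:
        raise ValueError("median window longer than trace")

    # For long windows the median is estimated on a strided copy and
    # linearly interpolated back: the baseline it tracks is far slower
    # than the stride, so this is exact in practice and keeps the cost
    # linear in the trace length.
    stride = max(1, w // 2000)

    def debase(x: np.ndarray) -> np.ndarray:
        xs = x[::stride]
        med = (pd.Series(xs).rolling(max(w // stride, 3), center=True,
                                     min_periods=1).median().to_numpy())
        if stride > 1:
            med = np.interp(np.arange(x.size), np.arange(xs.size) * stride, med)
        return x - med

    return _apply(trace, debase)


def downsample(trace: Trace, target_rate: float) -> Trace:
    """Keep every (rate/target)-th sample; anti-alias filtering is the
    caller's responsibility (apply the low-pass first)."""
    factor = trace.rate / target_rate
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(
            f"rate {trace.rate} not an integer multiple of target {target_rate}"
        )
    step = int(round(factor))
    out = _apply(trace, lambda x: x[::step].copy())
    out.rate = float(target_rate)
    return out


def preprocess(trace: Trace, kind: str | None = None, line_freq: float = 50.0,
               n_harmonics: int = 3, notch_sigma: float = 1.0,
               filter_order: int = 5) -> Trace:
    """Full cleaning chain: notch -> baseline -> low-pass -> decimate.

    ``kind`` selects the per-signal defaults ("lfp", "ecg",
    "respiration"); inferred from the trace type when omitted.  The
    notch is only applied when its top harmonic is resolvable, so
    already-decimated or synthetic low-rate inputs pass through the
    remaining stages unchanged in semantics.
    """
    if kind is None:
        kind = trace.kind if isinstance(trace, PhysioTrace) else "lfp"
    cutoff, target, window_s = DEFAULT_CHAIN[kind]
    if line_freq * n_harmonics < trace.rate / 2:
        trace = remove_line_noise(trace, line_freq, n_harmonics, notch_sigma)
    trace = remove_baseline(trace, window_s)
    if cutoff < trace.rate / 2:
        trace = zero_phase_filter(
            trace, FilterSpec("low-pass", filter_order, (cutoff,))
        )
    if trace.rate != target:
        trace = downsample(trace, target)
    return trace
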