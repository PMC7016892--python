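"""Physiology-gated selection of a stable analysis window.

Anesthesia depth is standardized across sessions by analysing only a
five-minute LFP window during which both heart and respiration rates
stay within median +/- a fixed constant (2 Hz for heartbeats, 0.5 Hz for
respiration).  Three steps: (1) detect heartbeat / breath events and
convert inter-event intervals to instantaneous rates; (2) threshold the
rates to mark stable samples of each trace, and AND the two masks on a
common clock; (3) take the earliest contiguous stable run of sufficient
length, trimmed to exactly the window duration.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy.signal import find_peaks

from .containers import PhysioTrace

#: default rate constants (Hz) added/subtracted around the median rate
RATE_CONSTANTS = {"ecg": 2.0, "respiration": 0.5}
#: peak-detector refractory periods (s), sized for murine rates under
#: anesthesia (heart ~5 Hz, breathing ~2 Hz, transient excursions above
#: both must stay detectable)
REFRACTORY_S = {"ecg": 0.080, "respiration": 0.250}
#: peak-detector threshold factors (median + k * MAD).  ECG spikes stand
#: far above baseline so k = 4 is safe; the rectified-sine-like
#: respiration waveform has a high median and compressed MAD, so a lower
#: factor is needed for the threshold to sit below the breath peaks.
THRESHOLD_K = {"ecg": 4.0, "respiration": 1.0}


class NoStableWindowError(RuntimeError):
    """No contiguous stable run of the requested duration exists."""


@dataclass
class RateSeries:
    """Instantaneous event rate per inter-event interval.

    ``rates[i] = 1 / (times[i+1] - times[i])`` is attributed to the
    half-open interval ``[times[i], times[i+1])``.
    """

    times: np.ndarray  # event times, s, strictly increasing
    rates: np.ndarray  # Hz, one per interval (len(times) - 1)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("event times must be strictly increasing")
        if self.rates.size != self.times.size - 1:
            raise ValueError("need one rate per inter-event interval")


@dataclass
class StableWindow:
    """Selected analysis window on the recording clock, seconds."""

    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start


def detect_events(physio: PhysioTrace, threshold_k: float | None = None,
                  refractory_s: float | None = None) -> np.ndarray:
    """R-peak / breath-peak times from a preprocessed physiology trace.

    Peaks are local maxima above an adaptive threshold (median + k*MAD)
    separated by at least the refractory period.
    """
    kind = physio.kind
    k = THRESHOLD_K[kind] if threshold_k is None else threshold_k
    refr = REFRACTORY_S[kind] if refractory_s is None else refractory_s
    x = physio.samples
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    idx, _ = find_peaks(x, height=med + k * mad,
                        distance=max(1, int(round(refr * physio.rate))))
    if idx.size < 10:
        raise ValueError(
            f"fewer than 10 {kind} events detected ({idx.size}); "
            "trace too short, flat, or mis-scaled"
        )
    return physio.t0 + idx / physio.rate


def rate_series(event_times: np.ndarray) -> RateSeries:
    """Instantaneous rates (1/IEI) from event times."""
    times = np.asarray(event_times, dtype=float)
    return RateSeries(times, 1.0 / np.diff(times))


def rate_bounds(rates: np.ndarray, constant: float) -> tuple[float, float]:
    """Stability bounds: median rate -/+ the heuristic constant (Hz)."""
    rates = np.asarray(rates, dtype=float)
    if rates.size < 10:
        raise ValueError("need at least 10 rate values to set bounds")
    med = float(np.median(rates))
    lower, upper = med - constant, med + constant
    if lower <= 0:
        warnings.warn("non-positive lower rate bound clamped to 0")
        lower = 0.0
    return lower, upper


def stable_mask(series: RateSeries, bounds: tuple[float, float],
                duration: float, mask_rate: float,
                guard_intervals: int = 1) -> np.ndarray:
    """Boolean stability mask on a clock of ``mask_rate`` Hz.

    A sample is stable iff the rate of its enclosing inter-event
    interval lies within ``bounds``; the first/last interval's rate is
    extended to the trace edges.  Intervals within ``guard_intervals``
    of an out-of-bounds interval are also marked unstable, so that
    boundary intervals straddling a rate change (whose mixed 1/IEI rate
    can fall back inside the bounds) never leak into the stable set.
    """
    lower, upper = bounds
    ok = (series.rates >= lower) & (series.rates <= upper)
    if guard_intervals > 0:
        bad = ~ok
        for shift in range(1, guard_intervals + 1):
            bad[:-shift] |= ~ok[shift:]
            bad[shift:] |= ~ok[:-shift]
        ok = ~bad
    n = int(round(duration * mask_rate))
    t = np.arange(n) / mask_rate
    # interval index of each sample; values clipped so edge samples take
    # the first/last interval's rate
    idx = np.searchsorted(series.times, t, side="right") - 1
    idx = np.clip(idx, 0, series.rates.size - 1)
    return ok[idx]


def select_window(mask_ecg: np.ndarray, mask_resp: np.ndarray,
                  mask_rate: float, duration: float = 300.0) -> StableWindow:
    """Earliest run where both masks are stable for >= ``duration`` s.

    The masks must share one clock (``mask_rate``).  The run is trimmed
    to exactly ``duration`` seconds from its start; deterministic.
    """
    if mask_ecg.shape != mask_resp.shape:
        raise ValueError("masks must share the recording clock")
    both = mask_ecg & mask_resp
    need = int(round(duration * mask_rate))
    if need < 1:
        raise ValueError("window duration must be positive")
    # run-length scan over the AND-ed mask
    padded = np.concatenate(([False], both, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, ends = edges[::2], edges[1::2]
    for s, e in zip(starts, ends):
        if e - s >= need:
            return StableWindow(s / mask_rate, (s + need) / mask_rate)
    longest = int((ends - starts).max()) if starts.size else 0
    raise NoStableWindowError(
        f"no stable run of {duration} s (longest: {longest / mask_rate:.1f} s)"
    )


def find_stable_window(ecg: PhysioTrace, resp: PhysioTrace,
                       duration: float = 300.0, mask_rate: float = 20.0,
                       rate_constant_ecg: float = RATE_CONSTANTS["ecg"],
                       rate_constant_resp: float = RATE_CONSTANTS["respiration"],
                       ) -> tuple[StableWindow, dict]:
    """Full three-step selection; returns the window and a report dict."""
    total = min(ecg.duration, resp.duration)
    report: dict = {}
    masks = []
    for trace, const in ((ecg, rate_constant_ecg), (resp, rate_constant_resp)):
        events = detect_events(trace)
        series = rate_series(events)
        bounds = rate_bounds(series.rates, const)
        masks.append(stable_mask(series, bounds, total, mask_rate))
        report[trace.kind] = {
            "n_events": int(events.size),
            "median_rate_hz": float(np.median(series.rates)),
            "bounds_hz": [float(bounds[0]), float(bounds[1])],
        }
    window = select_window(masks[0], masks[1], mask_rate, duration)
    report["window_s"] = [window.start, window.end]
    return window, report
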