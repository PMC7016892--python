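"""Phase-amplitude coupling via a harmonic general linear model.

The coupling between a slow band's phase and a faster band's amplitude
is quantified by regressing the instantaneous amplitude on
``{1, cos(phase), sin(phase)}`` by least squares.  The GLM index is the
coefficient of determination (R^2) of that fit — the fraction of
amplitude variance explained by the first harmonic of the phase — in
[0, 1].  Because the design spans both quadratures, the index is
invariant to a constant phase rotation.  ``pac_index="r"`` reports the
square root instead (a monotone transform).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import hilbert

from .connectivity import band_passed, instantaneous_amplitude
from .containers import MultiChannelRecording


@dataclass
class PACEntry:
    phase_channel: int
    amp_channel: int
    phase_band: str
    amp_band: str
    index: float


@dataclass
class PACResult:
    """GLM coupling indices per (phase-source, amplitude-source, band)."""

    entries: list[PACEntry]
    mode: str  # "intra" or "cross"

    def index(self, phase_channel: int, amp_channel: int,
              amp_band: str) -> float:
        for e in self.entries:
            if (e.phase_channel, e.amp_channel, e.amp_band) == (
                    phase_channel, amp_channel, amp_band):
                return e.index
        raise KeyError((phase_channel, amp_channel, amp_band))


def instantaneous_phase(rec: MultiChannelRecording,
                        band: str | tuple[float, float]
                        ) -> MultiChannelRecording:
    """Per-channel phase: argument of the analytic signal of the
    band-passed trace, radians in (-pi, pi]."""
    bp = band_passed(rec, band)
    return replace(bp, samples=np.angle(hilbert(bp.samples, axis=1)))


def glm_pac(phase: np.ndarray, amplitude: np.ndarray,
            pac_index: str = "r2") -> float:
    """GLM coupling index of an amplitude series on a phase series.

    Least-squares fit of ``amplitude ~ 1 + cos(phase) + sin(phase)``;
    returns R^2 (or its square root for ``pac_index="r"``).  A constant
    amplitude has no variance to explain and yields 0.
    """
    phase = np.asarray(phase, float).ravel()
    amplitude = np.asarray(amplitude, float).ravel()
    if phase.shape != amplitude.shape:
        raise ValueError("phase and amplitude must share one clock")
    if pac_index not in ("r2", "r"):
        raise ValueError("pac_index must be 'r2' or 'r'")
    y = amplitude - amplitude.mean()
    sst = float(y @ y)
    if sst == 0.0:
        return 0.0
    X = np.column_stack((np.ones_like(phase), np.cos(phase), np.sin(phase)))
    beta, *_ = np.linalg.lstsq(X, amplitude, rcond=None)
    resid = amplitude - X @ beta
    r2 = 1.0 - float(resid @ resid) / sst
    r2 = min(max(r2, 0.0), 1.0)
    return float(np.sqrt(r2)) if pac_index == "r" else r2


def pac_matrix(rec: MultiChannelRecording,
               phase_band: str | tuple[float, float],
               amp_bands: list[str | tuple[float, float]],
               mode: str = "intra",
               pairs: list[tuple[int, int]] | None = None,
               pac_index: str = "r2") -> PACResult:
    """Coupling indices for requested (phase-channel, amp-channel) pairs.

    ``mode="intra"`` couples each channel's own phase and amplitude
    (``pairs`` defaults to all channels); ``mode="cross"`` requires
    explicit (phase_channel, amp_channel) pairs, e.g. deep cortical SO
    phase against hippocampal sr-lm fast-gamma amplitude.
    """
    if mode not in ("intra", "cross"):
        raise ValueError("mode must be 'intra' or 'cross'")
    if pairs is None:
        if mode == "cross":
            raise ValueError("cross mode requires explicit channel pairs")
        pairs = [(ch, ch) for ch in range(rec.n_channels)]
    if mode == "intra" and any(p != a for p, a in pairs):
        raise ValueError("intra mode requires phase and amplitude on one channel")
    for p, a in pairs:
        if not (0 <= p < rec.n_channels and 0 <= a < rec.n_channels):
            raise ValueError(f"pair ({p}, {a}) references invalid channels")

    phase_name = phase_band if isinstance(phase_band, str) else str(phase_band)
    phases = instantaneous_phase(rec, phase_band).samples
    entries = []
    for band in amp_bands:
        band_name = band if isinstance(band, str) else str(band)
        env = instantaneous_amplitude(rec, band).samples
        for p_ch, a_ch in pairs:
            entries.append(PACEntry(
                p_ch, a_ch, phase_name, band_name,
                glm_pac(phases[p_ch], env[a_ch], pac_index=pac_index),
            ))
    return PACResult(entries, mode)
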