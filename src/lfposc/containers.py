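"""Core in-memory containers for multichannel LFP and physiology traces.

A recording session consists of a laminar multichannel LFP array (channels
ordered deepest-first, matching a linear silicon probe lowered through
cortex into hippocampus) plus time-locked single-channel ECG and
respiration traces.  All traces carry their own sampling rate and share
the recording clock: sample ``i`` of a trace occurs at ``t0 + i / rate``
seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class MultiChannelRecording:
    """Laminar multichannel voltage recording.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Extracellular voltage in microvolts, channels ordered deepest-first.
    rate : float
        Sampling rate in Hz.
    channel_depths : ndarray, shape (n_channels,)
        Electrode depth below the cortical surface, micrometres.
        Strictly monotone (decreasing for deepest-first ordering).
    t0 : float
        Time of the first sample, seconds from recording start.
    """

    samples: np.ndarray
    rate: float
    channel_depths: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.channel_depths = np.asarray(self.channel_depths, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels x time) array")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if len(self.channel_depths) != self.n_channels:
            raise ValueError(
                f"channel_depths has {len(self.channel_depths)} entries for "
                f"{self.n_channels} channels"
            )
        d = np.diff(self.channel_depths)
        if len(d) and not ((d > 0).all() or (d < 0).all()):
            raise ValueError("channel_depths must be strictly monotone")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Length of the recording in seconds."""
        return self.n_samples / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.rate

    def crop(self, start: float, end: float) -> "MultiChannelRecording":
        """Return the sub-recording between ``start`` and ``end`` seconds."""
        i0 = int(round((start - self.t0) * self.rate))
        i1 = int(round((end - self.t0) * self.rate))
        if i0 < 0 or i1 > self.n_samples or i1 <= i0:
            raise ValueError(f"crop window [{start}, {end}] s outside recording")
        return MultiChannelRecording(
            self.samples[:, i0:i1].copy(), self.rate, self.channel_depths, start
        )


@dataclass
class PhysioTrace:
    """Single-channel physiological monitoring trace (ECG or respiration)."""

    samples: np.ndarray
    rate: float
    kind: str
    t0: float = 0.0

    VALID_KINDS = ("ecg", "respiration")

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.kind not in self.VALID_KINDS:
            raise ValueError(f"kind must be one of {self.VALID_KINDS}, got {self.kind!r}")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.rate

    def crop(self, start: float, end: float) -> "PhysioTrace":
        i0 = int(round((start - self.t0) * self.rate))
        i1 = int(round((end - self.t0) * self.rate))
        if i0 < 0 or i1 > self.n_samples or i1 <= i0:
            raise ValueError(f"crop window [{start}, {end}] s outside trace")
        return PhysioTrace(self.samples[i0:i1].copy(), self.rate, self.kind, start)


def default_channel_depths(n_channels: int = 24) -> np.ndarray:
    """Deepest-first laminar depths: 2300 um for channel 0, 100 um spacing."""
    return 2300.0 - 100.0 * np.arange(n_channels)
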