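"""PSD estimation, band power tables, and power-imbalance ratios.

Total power per channel is the integral of the Welch power spectral
density over the analysis range (0.1-190 Hz); relative band power is
each band's share of that total in percent.  Two scalar imbalance
indices are derived: the SO/delta ratio within the Low range and the
Low/High ratio across the 4.7 Hz split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import welch

from .bands import BandScheme
from .containers import MultiChannelRecording


@dataclass
class PowerSpectrum:
    """Welch PSD per channel: ``density[ch, i]`` in uV^2/Hz at ``freqs[i]``."""

    freqs: np.ndarray
    density: np.ndarray  # (n_channels, n_freqs)

    def band_power(self, lo: float, hi: float) -> np.ndarray:
        """Absolute power per channel over [lo, hi): trapezoidal integral
        of the density on the discrete frequency grid."""
        if lo < self.freqs[0] - 1e-9 or hi > self.freqs[-1] + 1e-9:
            raise ValueError(
                f"band [{lo}, {hi}) outside PSD support "
                f"[{self.freqs[0]}, {self.freqs[-1]}]"
            )
        # Both edge points are included: trapezoid segments of adjacent
        # bands are disjoint (they share only the edge ordinate), so a
        # contiguous tiling sums exactly to the Total integral.
        m = (self.freqs >= lo - 1e-9) & (self.freqs <= hi + 1e-9)
        return np.trapezoid(self.density[:, m], self.freqs[m], axis=1)


def compute_psd(rec: MultiChannelRecording, seg_s: float = 10.0,
                overlap: float = 0.5) -> PowerSpectrum:
    """Welch average of Hann-windowed periodograms.

    Default 10 s segments give 0.1 Hz resolution so the SO band's lower
    edge is resolvable; 50% overlap.  The integral of the density over
    [0, Nyquist] matches the (mean-removed) signal variance.
    """
    nperseg = int(round(seg_s * rec.rate))
    if rec.n_samples < 2 * nperseg:
        raise ValueError(
            f"window ({rec.duration:.1f} s) shorter than 2 Welch segments "
            f"({2 * seg_s:.1f} s)"
        )
    freqs, density = welch(rec.samples, fs=rec.rate, window="hann",
                           nperseg=nperseg,
                           noverlap=int(round(overlap * nperseg)), axis=1)
    return PowerSpectrum(freqs, density)


def band_powers(psd: PowerSpectrum, scheme: BandScheme | None = None,
                channel_depths: np.ndarray | None = None) -> pd.DataFrame:
    """Absolute (uV^2) and relative (% of Total) power per channel x band.

    Columns are a two-level index (band, {"abs", "rel"}); elementary
    relative powers sum to 100% per channel by construction (trapezoidal
    integration over a contiguous tiling).
    """
    scheme = scheme or BandScheme()
    n_ch = psd.density.shape[0]
    total = psd.band_power(*scheme.edges("Total"))
    cols: dict[tuple[str, str], np.ndarray] = {}
    for name in scheme.names + ["Low", "High", "Total"]:
        p = psd.band_power(*scheme.edges(name))
        cols[(name, "abs")] = p
        with np.errstate(invalid="ignore", divide="ignore"):
            cols[(name, "rel")] = 100.0 * p / total
    table = pd.DataFrame(cols, index=pd.RangeIndex(n_ch, name="channel"))
    if channel_depths is not None:
        table.insert(0, ("depth_um", ""), np.asarray(channel_depths, float))
    return table


def power_ratio(table: pd.DataFrame, a: str, b: str) -> pd.Series:
    """Per-channel ratio of absolute band powers a/b (dimensionless).

    A zero denominator yields NaN (flagged missing value), not an error.
    """
    for name in (a, b):
        if (name, "abs") not in table.columns:
            raise KeyError(f"band {name!r} not in table")
    num = table[(a, "abs")].to_numpy(float)
    den = table[(b, "abs")].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / den, np.nan)
    return pd.Series(out, index=table.index, name=f"{a}/{b}")
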