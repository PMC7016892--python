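"""Figure-style outputs: connectivity heatmaps and band-power rings."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .connectivity import ConnectivityResult


def plot_connectivity_matrices(result: ConnectivityResult):
    """Coefficients (upper-right) and latencies (lower-left) in one
    channel-by-channel heatmap, as conventionally displayed."""
    n = result.coeff.shape[0]
    combined = np.where(np.triu(np.ones((n, n), bool), 1),
                        result.coeff, np.nan)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    im1 = ax1.imshow(combined, vmin=0, vmax=1, cmap="viridis")
    ax1.set_title(f"max cross-correlation ({result.band})")
    fig.colorbar(im1, ax=ax1)
    lat = np.where(np.tril(np.ones((n, n), bool), -1),
                   result.latency_ms, np.nan)
    lim = np.nanmax(np.abs(lat)) if n > 1 else 1.0
    im2 = ax2.imshow(lat, vmin=-lim, vmax=lim, cmap="coolwarm")
    ax2.set_title("latency (ms)")
    fig.colorbar(im2, ax=ax2)
    for ax in (ax1, ax2):
        ax.set_xlabel("channel")
        ax.set_ylabel("channel")
    fig.tight_layout()
    return fig


def plot_band_power_ring(table: pd.DataFrame, channel: int):
    """Ring chart of one channel's relative band-power distribution."""
    bands = [b for (b, sub) in table.columns
             if sub == "rel" and b not in ("Low", "High", "Total")]
    vals = [table[(b, "rel")].iloc[channel] for b in bands]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.pie(vals, labels=bands, wedgeprops=dict(width=0.4),
           autopct="%.0f%%", pctdistance=0.8)
    ax.set_title(f"relative band power, channel {channel}")
    return fig
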