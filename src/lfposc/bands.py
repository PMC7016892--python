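"""Frequency-band scheme for anesthetized rodent LFP.

Under urethane anesthesia the slow-wave range dominates the spectrum, so
the low end is subdivided into slow oscillations (SO, 0.1-1.7 Hz) and
delta (1.7-4.7 Hz); the remaining elementary bands tile the spectrum up
to 190 Hz.  Composite ranges Low (0.1-4.7 Hz), High (4.7-190 Hz) and
Total (0.1-190 Hz) are derived from the elementary tiling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# Elementary bands, ordered low to high; half-open [low, high) except the
# last, which is closed at 190 Hz.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "SO": (0.1, 1.7),
    "delta": (1.7, 4.7),
    "theta": (4.7, 12.0),
    "beta": (12.0, 30.0),
    "slow-gamma": (30.0, 45.0),
    "fast-gamma": (45.0, 90.0),
    "epsilon": (90.0, 190.0),
}


@dataclass
class BandScheme:
    """Named frequency intervals tiling the analysis range.

    ``bands`` maps each elementary band name to its ``[low, high)`` edges
    in Hz.  The elementary bands must be contiguous and ordered;
    composites are exposed through :meth:`edges`:

    - ``Low``   — first edge up to the SO/delta block's upper edge (4.7 Hz)
    - ``High``  — from there to the top of the range
    - ``Total`` — the whole tiled range
    """

    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )
    low_high_split: float = 4.7

    def __post_init__(self) -> None:
        items = list(self.bands.items())
        if not items:
            raise ValueError("band scheme must contain at least one band")
        for name, (lo, hi) in items:
            if not lo < hi:
                raise ValueError(f"band {name!r} has empty interval [{lo}, {hi})")
        for (_, (_, hi_prev)), (name, (lo, _)) in zip(items, items[1:]):
            if abs(hi_prev - lo) > 1e-12:
                raise ValueError(
                    f"elementary bands must tile contiguously; gap before {name!r}"
                )

    @property
    def names(self) -> list[str]:
        return list(self.bands)

    @property
    def fmin(self) -> float:
        return next(iter(self.bands.values()))[0]

    @property
    def fmax(self) -> float:
        return list(self.bands.values())[-1][1]

    def edges(self, name: str) -> tuple[float, float]:
        """Edges of an elementary band or of Low/High/Total composites."""
        if name in self.bands:
            return self.bands[name]
        if name == "Low":
            return (self.fmin, self.low_high_split)
        if name == "High":
            return (self.low_high_split, self.fmax)
        if name == "Total":
            return (self.fmin, self.fmax)
        if name == "FG/epsilon":  # composite used for delta-phase coupling
            return (self.bands["fast-gamma"][0], self.fmax)
        raise KeyError(f"unknown band {name!r}")


# Depth-defined anatomical regions spanned by the 24-channel probe, from
# superficial cortex down to dentate gyrus (depths in micrometres).
DEFAULT_REGIONS: dict[str, tuple[float, float]] = {
    "L2/3": (100.0, 400.0),
    "L4/6": (500.0, 1000.0),
    "CA1": (1100.0, 1600.0),
    "DG": (1700.0, 2300.0),
}

# The seven analysis depths (um) used for power and statistics tables:
# DG lower/upper stratum granulare, CA1 sr-lm and stratum pyramidale,
# cortical L6, L4/5 and L2/3.
ANALYSIS_DEPTHS_UM: dict[str, float] = {
    "lo-sg": 2100.0,
    "up-sg": 1900.0,
    "sr-lm": 1500.0,
    "sp": 1200.0,
    "L6": 900.0,
    "L4/5": 600.0,
    "L2/3": 300.0,
}
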