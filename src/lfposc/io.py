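"""Reading and writing the recording container and derived tables.

The on-disk session container is an HDF5 file with datasets ``/lfp``,
``/ecg`` and ``/resp``; each dataset carries a ``rate`` attribute and
``/lfp`` additionally carries ``depths`` (um) and ``t0``.  Loaders never
resample or rescale, and a write/read round-trip is bit-exact on the
samples.  Small CSV fixtures (channels as columns) are accepted for
recordings; derived tables go to CSV/JSON elsewhere in the package.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import MultiChannelRecording, PhysioTrace


class MetadataError(KeyError):
    """Required rate/depth metadata missing from a container."""


def write_recording(rec: MultiChannelRecording, path: str | Path,
                    ecg: PhysioTrace | None = None,
                    resp: PhysioTrace | None = None) -> None:
    """Write a session container (LFP plus optional physiology)."""
    with h5py.File(path, "w") as f:
        d = f.create_dataset("lfp", data=rec.samples)
        d.attrs["rate"] = rec.rate
        d.attrs["depths"] = rec.channel_depths
        d.attrs["t0"] = rec.t0
        for name, trace in (("ecg", ecg), ("resp", resp)):
            if trace is not None:
                p = f.create_dataset(name, data=trace.samples)
                p.attrs["rate"] = trace.rate
                p.attrs["t0"] = trace.t0


def read_recording(path: str | Path) -> MultiChannelRecording:
    """Read the LFP from a session container.

    Missing rate or depth metadata raises :class:`MetadataError` rather
    than silently assuming defaults.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return _read_csv_recording(path)
    with h5py.File(path, "r") as f:
        if "lfp" not in f:
            raise MetadataError(f"{path}: no /lfp dataset")
        d = f["lfp"]
        for attr in ("rate", "depths"):
            if attr not in d.attrs:
                raise MetadataError(f"{path}: /lfp lacks required {attr!r} attribute")
        return MultiChannelRecording(
            d[()], float(d.attrs["rate"]), np.asarray(d.attrs["depths"]),
            float(d.attrs.get("t0", 0.0)),
        )


def read_physio(path: str | Path, kind: str) -> PhysioTrace:
    """Read an ECG or respiration trace from a session container."""
    name = {"ecg": "ecg", "respiration": "resp"}[kind]
    with h5py.File(path, "r") as f:
        if name not in f:
            raise MetadataError(f"{path}: no /{name} dataset")
        d = f[name]
        if "rate" not in d.attrs:
            raise MetadataError(f"{path}: /{name} lacks required 'rate' attribute")
        return PhysioTrace(d[()], float(d.attrs["rate"]), kind,
                           float(d.attrs.get("t0", 0.0)))


def _read_csv_recording(path: Path) -> MultiChannelRecording:
    """CSV fixture reader: one column per channel, named ``<depth>um``,
    with the rate on a ``# rate=<Hz>`` header comment line."""
    rate = None
    with open(path) as fh:
        first = fh.readline().strip()
    if first.startswith("#") and "rate=" in first:
        rate = float(first.split("rate=")[1])
    if rate is None:
        raise MetadataError(f"{path}: missing '# rate=<Hz>' header line")
    df = pd.read_csv(path, comment="#")
    try:
        depths = np.array([float(c.replace("um", "")) for c in df.columns])
    except ValueError as exc:
        raise MetadataError(
            f"{path}: column names must encode depths as '<um>um'"
        ) from exc
    return MultiChannelRecording(df.to_numpy().T, rate, depths)


def write_csv_recording(rec: MultiChannelRecording, path: str | Path) -> None:
    cols = {f"{d:g}um": rec.samples[i] for i, d in enumerate(rec.channel_depths)}
    with open(path, "w") as fh:
        fh.write(f"# rate={rec.rate:g}\n")
        pd.DataFrame(cols).to_csv(fh, index=False)


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default))
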