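"""End-to-end orchestration: input -> preprocess -> stable window ->
spectral / connectivity / PAC -> tables, plus cohort-level statistics.

`run` processes one session into a report bundle (CSV tables, regional
JSON summaries, and a manifest recording version, config hash, seed and
the selected window).  `run_cohort_study` generates a multi-animal
synthetic cohort per genotype group, extracts a per-animal scalar
metric, and applies the gatekept nonparametric comparison.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bands import ANALYSIS_DEPTHS_UM, BandScheme
from .connectivity import RegionScheme, connectivity_matrices, regionalize
from .containers import MultiChannelRecording, PhysioTrace
from .io import read_physio, read_recording, write_json
from .pac import pac_matrix
from .preprocess import preprocess
from .spectral import band_powers, compute_psd, power_ratio
from .stability import find_stable_window
from .stats import ComparisonResult, compare_metric
from .synth import SynthConfig, generate_lfp, generate_physio

log = logging.getLogger("lfposc")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything needed to process one session reproducibly."""

    synth: SynthConfig | None = None
    input_path: str | None = None
    out_dir: str = "lfposc_out"
    window_duration_s: float = 300.0
    use_stability: bool = True
    connectivity_bands: tuple[str, ...] = ("SO", "delta")
    pac_phase_band: str = "SO"
    pac_amp_bands: tuple[str, ...] = ("theta", "beta", "slow-gamma",
                                      "fast-gamma", "epsilon")
    #: canonical cross-regional PAC pair: SO phase in deep cortex (L4/5,
    #: 600 um) against amplitude in CA1 sr-lm (1500 um)
    pac_cross_depths_um: tuple[float, float] = (600.0, 1500.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.synth is None) == (self.input_path is None):
            raise ValueError("exactly one of synth / input_path must be set")


def _config_hash(config: PipelineConfig) -> str:
    def enc(o):
        if dataclasses.is_dataclass(o):
            return {k: enc(v) for k, v in dataclasses.asdict(o).items()}
        if isinstance(o, dict):
            return {str(k): enc(v) for k, v in o.items()}
        if isinstance(o, (list, tuple)):
            return [enc(v) for v in o]
        return o

    blob = json.dumps(enc(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _nearest_channel(depths: np.ndarray, depth_um: float) -> int:
    return int(np.argmin(np.abs(np.asarray(depths) - depth_um)))


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                log.error("stage %s failed: %s", name, exc)
                raise PipelineError(name, exc) from exc
            log.info("stage %s done in %.2f s", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


@_stage("input")
def _load(config: PipelineConfig):
    if config.synth is not None:
        rec, truth = generate_lfp(config.synth)
        ecg, resp = generate_physio(config.synth)
        return rec, ecg, resp
    rec = read_recording(config.input_path)
    ecg = read_physio(config.input_path, "ecg")
    resp = read_physio(config.input_path, "respiration")
    return rec, ecg, resp


@_stage("preprocess")
def _preprocess(rec, ecg, resp):
    return (preprocess(rec, "lfp"), preprocess(ecg), preprocess(resp))


@_stage("stability")
def _stable(rec, ecg, resp, duration):
    window, report = find_stable_window(ecg, resp, duration=duration)
    return rec.crop(window.start, window.end), report


@_stage("spectral")
def _spectral(rec, out_dir: Path):
    psd = compute_psd(rec)
    table = band_powers(psd, BandScheme(), rec.channel_depths)
    table.to_csv(out_dir / "band_powers.csv")
    ratios = pd.DataFrame({
        "depth_um": rec.channel_depths,
        "SO/delta": power_ratio(table, "SO", "delta"),
        "Low/High": power_ratio(table, "Low", "High"),
    })
    ratios.to_csv(out_dir / "power_ratios.csv", index=False)
    return table, ratios


@_stage("connectivity")
def _connectivity(rec, bands, out_dir: Path):
    regional = {}
    for band in bands:
        res = connectivity_matrices(rec, band)
        hdr = [f"{d:g}um" for d in rec.channel_depths]
        pd.DataFrame(res.coeff, index=hdr, columns=hdr).to_csv(
            out_dir / f"connectivity_coeff_{band.replace('/', '-')}.csv")
        pd.DataFrame(res.latency_ms, index=hdr, columns=hdr).to_csv(
            out_dir / f"connectivity_latency_{band.replace('/', '-')}.csv")
        regional[band] = regionalize(res, RegionScheme())
    write_json(regional, out_dir / "connectivity_regional.json")
    return regional


@_stage("pac")
def _pac(rec, config: PipelineConfig, out_dir: Path):
    depths = rec.channel_depths
    intra_channels = [_nearest_channel(depths, d)
                      for d in ANALYSIS_DEPTHS_UM.values()]
    intra = pac_matrix(rec, config.pac_phase_band,
                       list(config.pac_amp_bands), mode="intra",
                       pairs=[(c, c) for c in intra_channels])
    p_ch = _nearest_channel(depths, config.pac_cross_depths_um[0])
    a_ch = _nearest_channel(depths, config.pac_cross_depths_um[1])
    cross = pac_matrix(rec, config.pac_phase_band, ["fast-gamma"],
                       mode="cross", pairs=[(p_ch, a_ch)])
    rows = [{
        "mode": res.mode,
        "depth_phase_um": depths[e.phase_channel],
        "depth_amp_um": depths[e.amp_channel],
        "band_amp": e.amp_band,
        "index": e.index,
    } for res in (intra, cross) for e in res.entries]
    df = pd.DataFrame(rows)
    df.to_csv(out_dir / "pac_indices.csv", index=False)
    return df


def run(config: PipelineConfig) -> dict:
    """Process one session into a report bundle; idempotent for a fixed
    config and seed.  Returns a manifest dict (also written as JSON)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rec, ecg, resp = _load(config)
    rec, ecg, resp = _preprocess(rec, ecg, resp)
    if config.use_stability:
        rec, stability_report = _stable(rec, ecg, resp,
                                        config.window_duration_s)
    else:
        stability_report = {"window_s": [rec.t0, rec.t0 + rec.duration]}
    _spectral(rec, out_dir)
    _connectivity(rec, config.connectivity_bands, out_dir)
    _pac(rec, config, out_dir)
    manifest = {
        "version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stability": stability_report,
        "outputs": sorted({p.name for p in out_dir.iterdir()}
                          | {"manifest.json"}),
    }
    write_json(manifest, out_dir / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# cohort-level synthetic studies


def scale_band_amplitude(config: SynthConfig, band: str,
                         amp_scale: float) -> SynthConfig:
    """Return a config in which one band's component amplitude is scaled.

    Scaling an amplitude by ``s`` scales that band's absolute power by
    ``s**2`` while leaving every other band's absolute power (and the
    broadband remainder) unchanged; total power and the variance
    fractions are adjusted accordingly.
    """
    fr = dict(config.band_power_fractions)
    f_old = fr.get(band, 0.0)
    var_scale = 1.0 - f_old * (1.0 - amp_scale ** 2)
    fr = {b: (f * amp_scale ** 2 if b == band else f) / var_scale
          for b, f in fr.items()}
    return replace(config, band_power_fractions=fr,
                   total_std=config.total_std * np.sqrt(var_scale))


def animal_metric(config: SynthConfig, metric: str = "so_delta_ratio",
                  depth_um: float = ANALYSIS_DEPTHS_UM["sr-lm"],
                  window_duration_s: float | None = None,
                  use_stability: bool = False) -> float:
    """Generate one synthetic animal and extract a scalar power metric.

    The LFP is synthesized at the analysis rate; when ``use_stability``
    is set, physiology is generated too and the analysis window is
    gated on heart/respiration rate stability.
    """
    rec, _ = generate_lfp(config)
    if use_stability:
        ecg, resp = generate_physio(config)
        ecg, resp = preprocess(ecg), preprocess(resp)
        dur = window_duration_s or min(300.0, config.duration)
        window, _ = find_stable_window(ecg, resp, duration=dur)
        rec = rec.crop(window.start, window.end)
    seg = min(10.0, rec.duration / 4)
    table = band_powers(compute_psd(rec, seg_s=seg), BandScheme(),
                        rec.channel_depths)
    ch = _nearest_channel(rec.channel_depths, depth_um)
    if metric == "so_delta_ratio":
        return float(power_ratio(table, "SO", "delta").iloc[ch])
    if metric == "low_high_ratio":
        return float(power_ratio(table, "Low", "High").iloc[ch])
    if metric.startswith("rel_"):
        return float(table[(metric[4:], "rel")].iloc[ch])
    raise ValueError(f"unknown metric {metric!r}")


def run_cohort_study(base: SynthConfig,
                     groups: dict[str, dict],
                     n_per_group: int = 10,
                     metric: str = "so_delta_ratio",
                     depth_um: float = ANALYSIS_DEPTHS_UM["sr-lm"],
                     reference: str = "WT",
                     alpha: float = 0.05, k: int = 4,
                     seed: int = 0) -> tuple[pd.DataFrame, ComparisonResult]:
    """Synthetic multi-animal group comparison of one scalar metric.

    ``groups`` maps group label -> modifications, currently
    ``{"band_amplitude_scale": {band: s}}``; the reference group must be
    present.  Each animal gets an independent seed derived from ``seed``.
    Returns the per-animal metric table and the gatekept comparison.
    """
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} missing")
    rng = np.random.default_rng(seed)
    rows = []
    samples: dict[str, np.ndarray] = {}
    for gi, (label, mods) in enumerate(groups.items()):
        cfg_g = base
        for band, s in mods.get("band_amplitude_scale", {}).items():
            cfg_g = scale_band_amplitude(cfg_g, band, s)
        vals = []
        for a in range(n_per_group):
            cfg = replace(cfg_g, seed=int(rng.integers(0, 2 ** 31 - 1)))
            v = animal_metric(cfg, metric=metric, depth_um=depth_um)
            vals.append(v)
            rows.append({"group": label, "animal": a, metric: v})
        samples[label] = np.asarray(vals)
    result = compare_metric(samples, reference=reference, alpha=alpha, k=k)
    return pd.DataFrame(rows), result
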