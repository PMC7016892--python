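# lfposc

Analysis of laminar local field potential (LFP) recordings under
anesthesia, centred on slow oscillations (SO, 0.1–1.7 Hz): band-power
profiles and power-imbalance ratios, Hilbert-envelope functional
connectivity with signed propagation latencies, phase–amplitude coupling
(PAC) by a harmonic general linear model, physiology-gated selection of
a stable analysis window, and nonparametric group statistics — together
with a synthetic multichannel generator whose every feature is known
ground truth, so that each stage of the pipeline can be verified without
animal data.

## Who it is for

Electrophysiologists analysing multichannel extracellular recordings
from linear probes spanning cortex and hippocampus (e.g. 24 contacts at
100 µm spacing, posterior parietal cortex down to dentate gyrus), in
experiments that compare genotype or treatment groups of ~10 animals —
for instance resting-state studies of slow-wave dysfunction in
Alzheimer's-model mice.

## Methods at a glance

Let $x_c(t)$ be the channel-$c$ LFP after cleaning (Gaussian comb notch
at 50 Hz and harmonics, running-median baseline removal, zero-phase
order-5 Butterworth low-pass at 190 Hz, decimation to 500 Hz), restricted
to a five-minute window during which heart and respiration rates stay
within median ± a fixed constant (2 Hz and 0.5 Hz respectively).

* **Band power.** Welch PSD $S_c(f)$ (Hann, 10 s segments, 50 % overlap);
  total power $P_c = \int_{0.1}^{190} S_c(f)\,df$; relative band power
  $100\,\int_{band} S_c / P_c$; imbalance ratios $P_{SO}/P_{\delta}$
  and $P_{Low}/P_{High}$ with the Low/High split at 4.7 Hz.
* **Envelope connectivity.** $a_c(t) = |\mathcal{H}[x_c^{band}](t)|$,
  the modulus of the analytic signal of the band-passed trace. For each
  channel pair the maximal normalized cross-correlation
  $\max_\tau |{\rm corr}(a_i(t+\tau), a_j(t))|$ and its lag (the
  latency, in ms; negative = channel $i$ leads), averaged within and
  between depth-defined regions (L2/3, L4/6, CA1, DG).
* **PAC.** With $\phi(t)$ the phase of the slow band and $A(t)$ the
  amplitude of a faster band, least squares of
  $A \sim \beta_0 + \beta_1\cos\phi + \beta_2\sin\phi$; the GLM index is
  the $R^2$ of that fit, in $[0, 1]$, invariant to phase rotation.
* **Statistics.** Kruskal–Wallis omnibus across groups, gated at the
  Dunn–Šidák level $1-(1-\alpha)^{1/k}$ for $k$ planned comparisons;
  pairwise two-sided Mann–Whitney against wild type only when the gate
  passes (`*` p < 0.05, `**` p < 0.01).

The synthetic generator builds each channel as a sum of band-limited
Gaussian processes with prescribed variance fractions plus a $1/f$
background; the slow-wave components propagate across channels with
configurable millisecond lags, fast-band amplitudes can be nested on SO
phase with depth $m$ via $A \mapsto A\,(1 + m\cos\phi)$, and ECG /
respiration traces carry stable baseline rates with injectable
anomalous epochs.

## Worked example

```python
from lfposc import SynthConfig, generate_lfp
from lfposc.bands import BandScheme
from lfposc.connectivity import RegionScheme, connectivity_matrices, regionalize
from lfposc.pac import pac_matrix
from lfposc.spectral import band_powers, compute_psd, power_ratio

cfg = SynthConfig(n_channels=24, duration=300.0, rate=500.0, seed=42,
                  pac_depth={("SO", "fast-gamma"): 0.5})
rec, truth = generate_lfp(cfg)

table = band_powers(compute_psd(rec), BandScheme(), rec.channel_depths)
ch = 8  # 1500 um, CA1 stratum radiatum-lacunosum moleculare
print(table[("SO", "rel")].iloc[ch], power_ratio(table, "SO", "delta").iloc[ch])

conn = regionalize(connectivity_matrices(rec, "SO"), RegionScheme())
print(conn["cross"]["L4/6->DG"])

pac = pac_matrix(rec, "SO", ["fast-gamma"], mode="cross", pairs=[(17, 8)])
print(pac.entries[0].index)
```

prints (values from the run above):

```
relative SO power:    54.1 %
SO/delta power ratio: 3.03
L4/6 -> DG envelope correlation: 0.984
L4/6 -> DG latency: -38.6 ms  (negative: cortex leads)
cross-regional PAC (SO @L4/5 -> FG @sr-lm): 0.262
```

The SO band carries ~54 % of this channel's power (the generator's
default SO-dominated mixture), deep cortex leads the dentate gyrus by
~39 ms — matching the injected propagation ladder (true mean −38.0 ms
over those channel pairs) — and the injected SO→fast-gamma nesting at
depth 0.5 yields a clearly nonzero coupling index.

A command-line interface wraps the same functions:

```sh
lfposc synth --config cfg.yaml --out rec.h5 --seed 1   # + ground-truth sidecar
lfposc run --config pipeline.yaml                      # full report bundle
lfposc connect rec.h5 --band SO
lfposc pac rec.h5 --mode cross --phase-band SO --pair 17 8
lfposc stats metrics.csv --metric so_delta_ratio
```

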