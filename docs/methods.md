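# Methods

This note documents the models, estimators and numerical choices behind
`lfposc`, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the package's known
limitations.

## Signal model and preprocessing

Raw traces are modelled as band-structured stochastic processes on a
shared clock: a laminar LFP array (24 channels, deepest-first, 100 µm
spacing, native 10 kHz) plus single-channel ECG and respiration.
Cleaning follows a fixed order — line-noise notch, baseline removal,
anti-alias low-pass, decimation — all zero-phase so that envelope and
phase estimates downstream are not time-shifted:

* **Gaussian comb notch.** Applied in the frequency domain: the
  spectrum is multiplied by $1 - e^{-(f - k f_0)^2 / 2\sigma^2}$ at the
  line frequency $f_0 = 50$ Hz and harmonics. Defaults $\sigma = 1$ Hz
  and 3 harmonics (up to 150 Hz): narrow enough to spare the
  fast-gamma/epsilon bands, and the frequency-domain form is exactly
  zero-phase. A time-domain Gaussian smoothing kernel would instead act
  as a low-pass; the notch reading is the one consistent with removing
  a line component.
* **Baseline removal.** Subtraction of a centred running median
  (windows 10 s for LFP, 1 s for ECG, 5 s for respiration; edges handled
  by shrinking windows). The 10 s window suppresses drift below
  ~0.1 Hz while sparing the SO band. For long windows the median is
  computed on a strided copy and interpolated — the baseline it tracks
  is orders of magnitude slower than the stride, so the approximation
  is exact in practice and the cost stays linear.
* **Low-pass + decimation.** Order-5 Butterworth applied
  forward–backward (squared magnitude response, zero group delay) at
  190 / 25 / 10 Hz, then plain sample-picking decimation to 500 / 50 /
  20 Hz for LFP / ECG / respiration. Decimation never resamples or
  rescales; the anti-alias low-pass is a precondition, not part of the
  decimator.

## Stable-window selection

Anesthesia depth is standardized by analysing a five-minute window in
which both physiological rates are stable. Events (R-peaks, breath
peaks) are local maxima above median + $k$·MAD with a refractory
period; instantaneous rate is the reciprocal inter-event interval,
attributed to its interval and extended to the trace edges.
Stability bounds are median ± 2 Hz (heart) and ± 0.5 Hz (respiration),
read as Hz since the rates themselves are in Hz; a non-positive lower
bound is clamped to zero with a warning. The two stability masks are
ANDed on a common clock and the **earliest** contiguous run of at least
the window duration is taken, trimmed to exactly that duration — the
earliest-run rule is a determinism tie-break. Intervals adjacent to an
out-of-bounds interval are also marked unstable (a one-interval guard):
an interval straddling a rate change has a mixed 1/IEI rate that can
fall back inside the bounds, and the guard keeps such boundary samples
out of the stable set.

Detector constants are sized for murine physiology under anesthesia
(heart ~5 Hz, breathing ~2 Hz): refractory 80 ms (ECG) and 250 ms
(respiration), threshold factor $k = 4$ for the spike-like ECG but
$k = 1$ for respiration — a rectified-sine-like waveform has a median
near 0.7 of its peak and a compressed MAD, so a 4-MAD threshold would
sit above the signal maximum and never fire. Only event times matter
downstream; the detector is deliberately simple and is not a
clinical-grade QRS detector.

## Spectral analysis

Welch PSD with Hann windows, 10 s segments (0.1 Hz resolution, enough to
resolve the SO band's lower edge), 50 % overlap; the integral over
[0, Nyquist] matches the signal variance to within 2 %. Band powers are
trapezoidal integrals over the band scheme SO [0.1, 1.7), delta
[1.7, 4.7), theta [4.7, 12), beta [12, 30), slow-gamma [30, 45),
fast-gamma [45, 90), epsilon [90, 190] Hz — SO, delta, fast-gamma and
the 4.7 Hz Low/High split are the anchored edges; theta through epsilon
complete a contiguous tiling and are config-overridable. Adjacent bands
share their edge ordinate so the trapezoid segments tile exactly and
elementary relative powers sum to 100 % by construction. Ratios
(SO/delta, Low/High) are ratios of absolute powers; a zero denominator
yields NaN rather than an error.

## Envelope connectivity

For a chosen band, channels are band-passed (order-5 zero-phase
Butterworth) and the instantaneous amplitude taken as the modulus of the
analytic signal. Connectivity is the maximum of $|{\rm corr}(a_i(t+\tau),
a_j(t))|$ over $|\tau| \le$ 500 ms (SO) / 250 ms (delta) — generous
relative to the tens-of-ms physiological lags; $|c|$ rather than signed
$c$ is maximized to make the contract explicit, though envelope
correlations are expected positive. Latency is the maximizing lag with
the **leader-negative** convention: latency(A, B) < 0 means A leads B,
so a cortex that anticipates the dentate gyrus produces a negative
cortex→DG latency. Latencies are reported on the 500 Hz grid (2 ms)
without sub-sample interpolation; biological between-animal scatter is
an order of magnitude coarser.

Two numerical points matter. First, ten seconds (adaptive for short
windows) are trimmed from both envelope ends before correlating: filter
and Hilbert transients sit at the same absolute time on every channel
and constitute a zero-lag correlated artifact that otherwise biases all
latencies toward zero. Second, the matrices are filled by computing the
upper triangle and reflecting, so coefficient symmetry and latency
anti-symmetry hold exactly. Regional averages run over a fixed region
order (L2/3, L4/6, CA1, DG by depth) so cross-regional latency signs
are coherent; intraregional latency means vanish by anti-symmetry and
only coefficients are reported there.

## Phase–amplitude coupling

The coupling index is the $R^2$ of the least-squares fit of the
amplitude series on $\{1, \cos\phi, \sin\phi\}$. Because the design
spans both quadratures the index is invariant to constant phase
rotations, and it equals the explained-variance fraction, in [0, 1]; a
constant amplitude is defined to have index 0. The square-root variant
(`pac_index="r"`) is exposed as a monotone alternative normalization.
Intraregional mode couples each channel's own SO phase to its
higher-band amplitudes; cross-regional mode couples explicit channel
pairs, canonically deep-cortical SO phase (L4/5, 600 µm) against CA1
sr-lm fast-gamma amplitude (1500 µm). Delta-phase coupling reuses the
same machinery with the delta band and, when wanted, the composite
FG/epsilon (45–190 Hz) amplitude band. Optional pre-smoothing of the
amplitude series at the phase band's upper edge exists but is off by
default: it changes only the noise floor, not the harmonic structure
the regression captures.

## Group statistics

Per-animal scalar metrics are compared with a Kruskal–Wallis omnibus
test (tie-corrected, chi-square approximation) evaluated at the
Dunn–Šidák-adjusted level $1-(1-\alpha)^{1/k}$ with $k$ the number of
transgenic lines compared to wild type (default 4). The adjustment is
applied at the omnibus gate — the two-stage wording "where the omnibus
indicates a pair of different populations, pairwise tests follow" is
interpreted as gatekeeping, and the gate level is configurable if a
user prefers pairwise-stage adjustment. Pairwise Mann–Whitney tests are
two-sided, exact for min(n) ≤ 8 without ties and otherwise
normal-approximated with tie and continuity corrections. Under the
gate, the simulated family-wise type-I error is at or below nominal.

## The synthetic generator

Each channel is $\sum_b \sqrt{f_b}\,\sigma\, z_b(t) + \sqrt{1-\sum f_b}\,
\sigma\, \eta(t)$, where $z_b$ are unit-variance Gaussian processes
confined to band $b$, $f_b$ the prescribed variance fractions, and
$\eta$ a $1/f^{\chi}$ background ($\chi = 2$ by default, the steep
low-frequency slope seen under anesthesia). Defaults put 50 % of the
variance in SO and 15 % in delta, so with the low-frequency-weighted
background the Low range carries roughly 70 % of total power — the
regime in which slow oscillations dominate the anesthetized spectrum.
The overall scale (150 µV RMS) is arbitrary; every downstream method is
scale-free.

Design choices that implementation forced:

* **Exact-edge band synthesis.** Components are synthesized in the
  frequency domain with hard band edges rather than by Butterworth
  filtering of white noise. Filter skirts would push 5–7 % of each
  band's power into its neighbours, corrupting the power ground truth
  (delta recovered ~18 % high) and injecting per-channel-independent
  power into the SO analysis band that jitters envelope latencies by
  several milliseconds. The analysis side keeps its Butterworth
  band-passes; only the ground-truth synthesis needs exact tiling.
* **Coherent slow-wave propagation.** SO *and* delta components are a
  shared channel-0 master delayed per channel (exact fractional delay
  via an FFT phase ramp), since slow waves travel across the probe as
  one wavefront; faster bands and the background are independent across
  channels. Per-channel-independent delta would be unphysical and — via
  the analysis filter's skirt — was the residual jitter source in
  latency recovery.
* **Variance-preserving PAC injection.** Nesting multiplies the
  amplitude-band component by $1 + m\cos\phi_{SO}(t)$ and re-standardizes
  to the target band variance, so power ground truth and coupling
  ground truth stay orthogonal.
* **Physiology.** ECG is a 20 ms biphasic (Gaussian-derivative) spike
  train; respiration a rectified sine; baseline rates 5 Hz and 2 Hz with
  2 % interval jitter. The waveforms are conventional stand-ins — only
  event times matter downstream. Anomalous epochs offset the
  instantaneous rate of the named trace; epochs and rates are the
  ground truth for the stable-window stage.

What the generator does **not** emulate: volume conduction and spatially
correlated background across channels, spike trains, non-sinusoidal SO
waveform shape (down-states/up-states), non-stationary band power, or
realistic ECG morphology. Passing tests therefore demonstrate estimator
correctness against known structure, not robustness to every real-data
pathology.

## Verification experiment sizes and conditions

The verification suite and `scripts/acceptance.py` use problem sizes
chosen to exercise each stage meaningfully on a single core: 24-channel,
300 s sessions for latency recovery (lag ladder 0–100 ms, 10 seeds);
300 s single-channel sessions for PAC monotonicity (depths 0, 0.25,
0.5, 1); 100 randomized 900 s physiology configurations for the
stable-window check; 2000 replicates for the type-I simulation; and a
200-replicate cohort study (two groups of 10 animals, 3-channel 60 s
sessions) for end-to-end discrimination of a halved SO amplitude.

Two conditions deserve notice. The latency-recovery experiment uses
band fractions summing to one (no $1/f$ remainder): with the default
9 % independent background, in-band background power adds a stochastic
±3–6 ms to the argmax of the envelope cross-correlation — an
information limit of peak-picking on a slowly decorrelating envelope,
not an estimator defect — while the injected lags remain recoverable to
the 2 ms sample grid when the SO band contains only the propagating
source. Real tissue background is largely shared across neighbouring
contacts rather than independent, so the synthetic default is, if
anything, the harder case. Second, the cohort study halves SO
*amplitude* in one group by rescaling fractions and total variance so
every other band's absolute power is unchanged — the manipulation is
confined to the SO band by construction.

## Limitations

* Latency precision beyond ~1 sample requires the shared slow-wave
  component to dominate its analysis band; heavy independent in-band
  noise widens the envelope correlation peak and peak-picking degrades
  gracefully (still unbiased, scatter of a few ms).
* The Welch/trapezoid pipeline assumes band edges on the 0.1 Hz
  frequency grid; off-grid custom edges incur up to one grid cell of
  integration mismatch.
* The stable-window stage assumes the majority of the recording is at
  the baseline rate: bounds centre on the median, so if anomalous
  epochs cover more than half the recording they become the "stable"
  regime. This mirrors the median-based definition of the method
  itself.
* HDF5 containers and CSV fixtures are supported; native acquisition
  formats (e.g. Open Ephys continuous files) are expected to be
  converted upstream. No NWB compliance, no streaming, no
  current-source-density or spike analyses, no phase-based or directed
  connectivity measures.
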