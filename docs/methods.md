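# Methods

`poretrap` implements a multi-metric analysis of trap–release nanopore
recordings and a matching synthetic-recording generator. This note
documents the models, the numerical choices, and what the synthetic data
do and do not establish.

## Signal model and workflow

A solid-state nanopore smaller than the analyte particle operates as a
reversible trap: under positive bias a particle is captured at the pore
mouth ("gated" state, reduced current), and reversing the bias releases it
("open" state, baseline current). A recording is a sequence of
trap–release voltage cycles; each cycle contributes at most one gating
event.

The analysis chain per recording is:

1. **Analysis filter.** A 4-pole Bessel low-pass (default cutoff 50 kHz at
   200 kHz sampling) applied forward–backward (`sosfiltfilt`), i.e. zero
   phase, so threshold crossings are not delayed. The acquisition chain
   specifies only the cutoff; the digital realization (family, order,
   zero-phase) is a package choice. Consequence: the effective magnitude
   response is the *square* of the one-pass Bessel magnitude, and the
   white-noise variance transmitted at cutoff = fs/4 is ≈ 0.386 of the
   input (the one-pass figure would be ≈ 0.5). `filter_noise_bandwidth_factor`
   computes this factor from the realized response and is the oracle the
   tests compare against.
2. **Cycle splitting.** Cycle boundaries come from the voltage protocol
   (level, duration per phase), rounded to the nearest sample.
3. **Segmentation (3σ rule).** Within the trap phase, the open-pore mean
   `I0` and RMS `σ_open` are computed on the first 100 ms. Samples whose
   current magnitude falls below `I0 − 3σ_open` for at least 1 ms
   contiguously form gated runs; the longest run is the event's gated
   span (one particle per cycle is assumed). The minimum-run rule
   suppresses noise-triggered false positives; 1 ms was chosen as a
   physical dwell floor, independent of sampling rate. A baseline window
   whose RMS exceeds 10% of its mean is treated as contaminated
   (capture started inside it) and the event is rejected as `too_short`.
4. **QC and normalization.** A Gaussian mixture is fitted to the open
   segment's relative current; if more than one component is selected the
   event is rejected (`multi_component_baseline` — drift or an undetected
   early capture). If a blank-recording reference is supplied, an open
   mean deviating more than ±5% is rejected as `baseline_drift`. Finally
   all relative currents are rescaled by `1/(open relative mean)` so the
   corrected open mean is exactly 1. The operation is idempotent.
5. **Sub-level count.** Mixtures with k = 1…6 components are fitted to the
   gated relative-current histogram; k is selected by minimum BIC after
   pruning unphysical candidates: any component with weight < 2%, or
   adjacent means closer than 1.5× the larger of the two sigmas. Segments
   longer than 5×10⁴ samples are uniformly decimated to that size — at the
   level separations of interest (≳10σ) the selection is insensitive to
   this, and it keeps a six-candidate, five-restart fit around 2 s per
   event. R² of the mixture density against a Freedman–Diaconis histogram
   is recorded; R² < 0.9 flags the event "poor fit" but does not override
   BIC. Restart seeds derive deterministically from the event identity.
6. **Spectral metrics.** Welch PSDs (Hann windows, 1-s windows for 1 Hz
   resolution, 50% overlap, mean averaging) of the gated and the same
   cycle's open span. Segments shorter than 2 s (fewer than three
   averages) carry no spectral metrics. The low-frequency flicker fit over
   1–100 Hz is `S(f) = A f^(−α) + C`, least squares in log power with a
   soft-L1 loss, bounds α ∈ [0, 3], A, C ≥ 0; A lumps the Hooge-type
   magnitude (Hooge constant × I² / carrier number), which is not
   separately identifiable from one spectrum. `fit_ok` is false when the
   flicker term carries < 10% of the in-band power. Noise-increase
   factors (NIFs) are gated/open ratios of trapezoidal band powers over
   1–100 Hz, 100–1000 Hz and 1–10 kHz; band edges are interpolated so
   adjacent bands tile exactly.
7. **Fingerprint.** Six axes — blockade depth, sub-level count, α, and the
   three NIFs — aggregated as per-axis arithmetic mean and *population*
   SD over valid events (spectral axes may aggregate fewer events). Radar
   plots min–max co-normalize axes; exported JSON keeps raw values.

## Pore sizing

The conductance model is the cylindrical channel plus access resistance
form, `G = σ [4L/(πd²) + 1/d]⁻¹` (σ in S/m ≡ nS/nm, lengths in nm, G in
nS). Diameter estimation solves the quadratic `σ d² − G d − 4GL/π = 0`
for its positive root; the round trip with the forward model is exact.
The default 1 M KCl conductivity is 11.2 S/m at 25 °C (configurable);
with L = 8.7 nm, a 13.7 nA baseline at 300 mV gives d ≈ 9.1 nm, within
~10% of the 8.7 nm TEM-calibrated reference — the residual is set by the
conductivity assumed, which is not part of the model.

## The synthetic-recording generator

The generator is phenomenological: it reproduces the *statistical
signatures* the pipeline measures, not the electrokinetics (no EOF/EP
force fields or zeta potentials).

- **Baseline**: ±`G·V` per phase polarity from the conductance model.
- **Open-pore noise**: time-domain white noise (RMS 0.08 nA at full
  bandwidth, i.e. one-sided floor 2σ²/fs) plus 1/f flicker synthesized by
  FFT spectral shaping (exact target spectrum in expectation; chosen over
  Lorentzian-sum synthesis for seed determinism), 2×10⁻⁴ nA²/Hz at 1 Hz,
  α = 1.
- **Capture**: in each trap phase after a deterministic delay plus an
  exponential waiting time (`capture_rate`). Stability classes:
  `persistent` (gated until release), `intermittent`/`flickering`
  (alternating gated/open dwells), `none`.
- **Gated current**: `I0·(1 − depth(t))`, where `depth(t)` follows a
  telegraph chain over the preset's discrete levels (exponential dwells,
  next level drawn from the occupancy weights), optionally low-passed
  ("slew limit": docking-configuration changes take finite time),
  optionally with one or two Ornstein–Uhlenbeck wander terms, clipped to
  [0.05, 0.95]. The clip floor is deliberately above the 3σ detection
  band so that wander excursions do not chop gated runs.
- **Gated noise**: an elevated white floor (multiplier on the open RMS)
  plus a preset-specific flicker term — the "interaction noise" that makes
  every NIF exceed 1.

### Preset registry (version 1)

The published phenotypes constrain ranges and orderings, not generative
parameters, so the registry values are package design choices, fixed once
so that the full pipeline expresses the documented phenotypes:

| preset | levels (fraction) | weights | switch | wander | gated noise (white×, A@1 Hz, α) |
|---|---|---|---|---|---|
| `amine` | 0.10 | 1 | — | — | 1.4×, 8×10⁻⁴, 1.0 |
| `biotin` | 0.30/0.45/0.60 | .1/.8/.1 | 70 Hz | — | 1.6×, 10⁻³, 1.2 |
| `tween` (discrete) | 0.20/0.35/0.45/0.60 | equal | 7 Hz | — | 1.8×, 10⁻³, 1.3 |
| `tween_smeared` | 0.40 | 1 | — | OU(0.3 Hz, 0.15) + OU(300 Hz, 0.029) | 2.0×, 6×10⁻², 1.5 |

plus `biotin_tween` and the streptavidin stages `sa_1to1` (capture ×0.3,
intermittent), `sa_1to10` (×0.05, flickering) and `sa_excess` (no stable
trapping).

Design notes from the calibration:

- **Discrete levels must switch slowly.** A telegraph with corner
  frequency inside 1–100 Hz looks *flat* at the low end of the band and
  fits a small α; its f⁻² tails also dominate the mid/high NIF bands.
  Biotin's 70 Hz switch rate with strongly weighted middle level puts the
  effective correlation corner near 4 Hz, yielding α between the amine
  flicker exponent and the smeared-tween wander exponent.
- **Two tween variants.** The discrete variant (4 resolvable levels) is
  what sub-level count recovery uses; the smeared variant (single broad
  level, slow large OU wander, strongest interaction noise) is the
  published tween phenotype — broad, without well-defined levels — and is
  what the fingerprint-ordering checks use. The discrete variant's
  mid/high NIFs are *not* ordered against biotin (telegraph tails
  dominate); the smeared variant's are, by its fast OU term and noise
  multipliers.
- **Hardware filter stage.** The acquisition chain's 100 kHz anti-alias
  filter sits exactly at Nyquist for 200 kHz sampling, where no digital
  equivalent exists; the simulator records it in metadata and applies a
  digital hardware-stage filter only when the cutoff is below 0.45·fs.

### What the synthetic data do not show

Passing tests establish that the pipeline recovers *generator truth*
(counts, depths, exponents, orderings) under realistic noise. They do not
validate against instrument data: real recordings have drifting
baselines, capacitive transients at polarity reversal, finite-bandwidth
amplifier noise shaping, and pore-to-pore variability that the generator
only caricatures (drift is emulated only as rejected events; transients
not at all). Absolute fingerprint values from real devices are therefore
out of scope; orderings and recovery rates are the testable claims.

## Problem sizes

Default study conditions are 200 kHz sampling throughout. Event sets for
sub-level statistics use 21/15/21 events (amine/biotin/tween) with ≥ 2.5 s
gated segments; spectral checks use 6-s trap phases with 2.5-s open spans
so both segments support three 1-s Welch averages. Unit and property
tests run at reduced sampling rates (2–50 kHz) where the property under
test is rate-independent.

## Known limitations

- One trapped particle per cycle; no stacked-event deconvolution.
- No dwell-time (HMM) modeling of level switching — the sub-level
  statistic is the stationary mixture count.
- The α/NIF axes require ≥ 2 s segments; shorter events contribute only
  depth and sub-level axes.
- The drift screen needs a blank reference; without one it is disabled
  (logged).
- No vendor (ABF) reader; columnar CSV/TSV and HDF5 containers are the
  supported formats.
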