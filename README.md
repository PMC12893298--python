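# poretrap

Multi-metric fingerprinting of single-nanoparticle trap–release events on
solid-state nanopores.

A solid-state nanopore smaller than the analyte acts as a reversible
electrokinetic trap: a positive bias captures a particle at the pore mouth
(reducing the ionic current — the "gated" state), and reversing the bias
releases it, so one recording yields many independent single-particle
events. The character of the gated current depends on the particle's
surface functional layer: a rigid aminated coating blocks a stable ~10% of
the baseline, a PEG–biotin layer hops between a few discrete docking
configurations, and a physisorbed surfactant (Tween-20) produces broad,
noisy blockades. `poretrap` turns such recordings into quantitative
per-species fingerprints, for nanopore/single-particle researchers who
want a reproducible, scriptable version of this analysis plus a simulator
to test it against ground truth.

## The method

Per trap–release cycle:

1. **Segmentation (3σ rule).** From the trap phase's leading baseline,
   compute the open-pore mean `I₀` and RMS `σ_open`; samples below
   `I₀ − 3σ_open` for ≥ 1 ms form the gated segment. Open-baseline QC
   rejects drifting or multi-component baselines, and relative currents
   are renormalized so the open mean is exactly 1.
2. **Sub-level count.** Gaussian mixtures with k = 1…6 components fitted
   to the gated relative-current histogram; k selected by minimum BIC
   after pruning components with weight < 2% or mean separation < 1.5σ.
3. **Spectral signatures.** Welch PSDs (1-s Hann windows, 50% overlap) of
   gated and open spans; flicker fit `S(f) = A f^(−α) + C` over 1–100 Hz;
   noise-increase factors `NIF = ∫S_gated df / ∫S_open df` over 1–100 Hz,
   100–1000 Hz and 1–10 kHz.
4. **Fingerprint.** Mean ± SD over events on six axes — depth, sub-levels,
   α, NIF(low/mid/high) — exported as JSON and radar plots.

Pore sizing uses the channel-plus-access-resistance conductance model
`G = σ[4L/(πd²) + 1/d]⁻¹`, inverted in closed form.

The `poretrap.simulate` module generates seeded synthetic recordings —
conductance-model baseline, white + 1/f^α noise, telegraph/OU gated-state
dynamics per surface-coating preset — with sample-exact ground truth, so
every pipeline stage is testable without instrument data. See
`docs/methods.md` for models, parameter defaults and limitations.

## Worked example

```bash
python examples/02_sublevel_counts.py
```

```
   amine: k per event = [1, 1, 1, 1, 1], mean = 1.00, min R2 = 0.998
  biotin: k per event = [3, 3, 3, 3, 3], mean = 3.00, min R2 = 0.995
   tween: k per event = [4, 4, 4, 4, 4], mean = 4.00, min R2 = 0.890
```

Each line is one surface-coating preset: `k` is the BIC-selected mixture
component count of each simulated event's gated histogram — the number of
discrete conductance sub-levels the particle visits while docked (1 stable
level for the aminated coating, 3 metastable configurations for biotin,
4 for the discrete tween variant); `R2` is the advisory histogram-fit
quality. Spectral axes behave the same way
(`examples/03_spectral_nif.py`):

```
         amine: alpha=1.01 (fit_ok=True) NIF low/mid/high = 4.1 / 3.8 / 2.9
        biotin: alpha=1.39 (fit_ok=True) NIF low/mid/high = 653.3 / 110.5 / 7.4
 tween_smeared: alpha=2.10 (fit_ok=True) NIF low/mid/high = 1373.5 / 224.2 / 31.6
```

Every NIF exceeds 1 (trapping adds noise in every band) and both α and the
NIFs increase with coating complexity — the orderings that separate the
species on the radar fingerprint. And pore sizing
(`examples/05_pore_sizing.py`):

```
G = 45.7 nS  ->  d = 9.06 nm (round-trip G = 45.7 nS)
```

i.e. a 13.7 nA open baseline at 300 mV with an 8.7 nm effective pore
length in 1 M KCl implies a ~9 nm pore.

A thin CLI wraps the same library:

```bash
poretrap simulate --preset biotin --cycles 5 --seed 1 --out rec.h5
poretrap analyze --preset biotin --cycles 5 --seed 1 --outdir out/
poretrap pore-size --current-na 13.7 --voltage-mv 300
```

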