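# squant

Quantitative analysis of spontaneous postsynaptic currents (sPSCs) recorded
in whole-cell voltage clamp — for electrophysiologists who want objective,
threshold-light statistics on sEPSC/sIPSC recordings, and for method
developers who need a fully synthetic, ground-truthed test bed for such
analyses.

The package implements five linked analyses:

1. **Event detection and kinetics** — band-limited derivative detection of
   spontaneous events; per-event baseline-to-peak amplitude, 10–90% rise
   time (RT10–90), and rate of rise RR = 0.8·A / RT10–90 (the slope of the
   main rising phase, a signature of perisomatic PV-interneuron inputs when
   it is fast).
2. **Objective small/large separation** — the empirical cumulative
   distribution of a cell's event amplitudes is fitted by least squares with
   one or two cumulative normals, F(x) = Σᵢ wᵢ Φ((x−μᵢ)/σᵢ); the fits are
   compared with the nested-model F test

       F = [(RSS₁ − RSS₂)/(p₂ − p₁)] / [RSS₂/(n − p₂)],

   and the amplitude threshold A_th for "large" events is read off the
   fitted two-component CDF where the first component ends.
3. **Burstiness and memory** — for the inter-event intervals (IEIs),
   B = (σ − μ)/(σ + μ) (−1 regular, 0 Poisson, →1 bursty) and
   M = lag-1 Spearman rank autocorrelation of the IEI series; cells are
   placed in the (B, M) plane per event class.
4. **Threshold-free phasic E/I ratio** — all-point histograms (1 pA bins,
   Savitzky–Golay 2nd-order/17-point smoothing) of randomly sampled 15-s
   segments; a Gaussian fitted to the non-skewed side gives the holding
   current and baseline σ; mirroring it onto the skewed side and summing the
   excess mass × distance gives the phasic charge in pC with no detection
   threshold. With m = n = 10 segments per cell the driving-force-corrected
   ratios (7·E)/(6·I) give 100 E/I values, and Eq.
   t₀.₉₇₅,N₋₁·σ/(μ·√N) (the fractional deviation) justifies the sample
   size. A paired Wilcoxon test on baseline σ before/after picrotoxin
   checks for sIPSC contamination of sEPSC recordings.
5. **Group statistics** — Mann–Whitney and paired Wilcoxon rank tests (exact
   for small samples), and two-/three-level nested one-way ANOVA
   (group → animal → cell → observation) with unbalanced-design variance
   components as percent of total.

Because raw recordings are rarely shareable, the package ships a
first-class synthetic generator: bi-exponential PSC kernels, two-component
normal amplitude mixtures, configurable IEI point processes (Poisson,
gamma, lognormal, constant, AR(1)-copula with tunable Spearman memory),
10 kHz sampling with 1.5 kHz low-pass filtering, and exact ground truth
(event times, amplitudes, total charge) for every trace.

## Worked example

```python
import numpy as np
from squant import (SimConfig, synthesize_trace, detect_events,
                    AmplitudeMixtureModel, burstiness, memory)

cfg = SimConfig(duration=120.0, seed=17)        # WT-like sIPSC recording at 0 mV
trace, truth = synthesize_trace(cfg)
events = detect_events(trace, polarity="outward")
print(f"{len(events)} events, frequency {events.frequency:.2f} Hz, "
      f"mean amplitude {events.mean_amplitude:.1f} pA")

model = AmplitudeMixtureModel.from_event_table(events)
fit1, fit2 = model.fit(1), model.fit(2)
print(fit2.summary())
print(fit1.compare_to(fit2))
thr = fit2.amplitude_threshold()
print(f"A_th = {thr.a_th:.2f} pA")
print(f"B = {burstiness(events.ieis):.3f}, M = {memory(events.ieis):.3f}")
```

prints

```
1166 events, frequency 9.72 Hz, mean amplitude 48.2 pA
Cumulative-normal mixture fit (k=2, n=1166 points)
  RSS = 0.0272343  (free parameters: 5)
  component 1: w = 0.748, mu = 32.30 pA, sigma = 8.55 pA
  component 2: w = 0.252, mu = 94.96 pA, sigma = 29.88 pA
F(3, 1161) = 7.662e+04, p = 0
A_th = 49.39 pA
B = -0.035, M = -0.030
```

The detected frequency (9.7 Hz) and the fitted mixture (small events near
32 pA, large events near 95 pA, ~3:1 weight) recover the generator's ground
truth (10 Hz, 28/95 pA at 4:1); the F test overwhelmingly prefers two
components, and A_th ≈ 49 pA splits the classes where the first
distribution ends. B ≈ 0 and M ≈ 0 are exactly what a Poisson event train
should give.

The same session can continue into the phasic E/I analysis (10 + 10
random 15-s segments, 100 ratios):

```
mean E charge 18.43 pC, mean I charge 41.57 pC
100 E/I ratios: mean 0.525 +/- 0.084
fractional deviation at N=100: 0.032
```

Here the excitatory trace was synthesized with half the inhibitory
amplitude scale, so the true charge ratio is 0.5 and the expected corrected
ratio is (7/6)·0.5 ≈ 0.583; the measured 0.53 is within the method's
documented recovery tolerance, and the fractional deviation says the mean
of the 100 ratios sits within ±3% of the cell's population value.

A command-line interface mirrors the library
(`squant simulate/detect/mixture/bm/ei/nested-anova/run`); see
`squant --help`.

## Layout

```
src/squant/
  synthetic.py   trace & IEI generators with ground truth
  trace.py       HDF5/NPZ trace container
  detection.py   event detection, kinetics, per-cell summaries
  mixture.py     cumulative-normal mixture model, F test, A_th
  temporal.py    burstiness, memory, (B, M) tables
  phasic.py      all-point histogram, phasic charge, E/I, PTX check
  anova.py       rank tests, nested one-way ANOVA
  pipeline.py    end-to-end synthetic-cohort study
  cli.py         `squant` command-line interface
docs/methods.md  model, assumptions, parameter choices, limitations
```
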