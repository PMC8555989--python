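# optopace

Analysis of optogenetically paced cardiovascular recordings: ECG beat
classification under optical pacing, vessel-diameter videometry, and
retrospective cardiac gating of line-scanned fluorescence microscopy.

## What it does, and for whom

Intravital cardiac optogenetics experiments drive heartbeats with laser
pulses applied to channelrhodopsin-expressing cardiac tissue, dilate or
constrict vessels through light-activated receptors, and image Ca²⁺
indicators in the beating heart. This package implements the downstream
quantitative analysis such experiments need:

- **ECG pacing analysis** — preprocess the ECG (100 Hz lowpass, median-0 /
  max-1 normalization), detect R and P peaks, classify each beat as
  *stimulated* (R peak 10–38 ms after a pulse rising edge for ventricular
  pacing, or P peak 38–52 ms after a falling edge for sinoatrial-node
  pacing), *unstimulated* (before pacing onset) or *excluded*; measure
  R-wave duration (span between the zero crossings flanking the R peak)
  and PR interval (P peak to the first QRS zero crossing); compare groups
  with a Mann–Whitney U test (exact for small tie-free samples).
- **Vessel videometry** — stabilize brightfield video by masked
  normalized cross-correlation, extract band-averaged intensity profiles
  across the vessel, locate the two sidewall peaks with sub-pixel
  quadratic refinement, and summarize opto-responses as
  `((MAX − MIN)/MIN) × 100` with Holm–Šidák-corrected group comparisons.
- **Gated reconstruction** — assign each microscopy line a cardiac phase
  from the ECG, reject lines in a respiratory exclusion window, and
  average lines into 10% cardiac-cycle bins; detect pacing-locked Ca²⁺
  transients and report per-pulse latencies and the coupling fraction.
- **Synthetic data** — generators for all of the above with analytic
  ground truth (Ricker-wavelet R-waves whose zero crossings are exact by
  construction, commanded vessel width timecourses, phase-modulated line
  scans, pulse-locked transients), so every stage is testable without
  in vivo recordings.

## Worked example

Simulate a ventricular-pacing experiment — 115 autonomous beats at 5 Hz,
then 273 laser-driven beats whose R peaks follow each pulse rising edge by
20 ms, with driven R-waves broadened from 12 to 18 ms — and run the full
pipeline:

```python
from optopace.synth import EcgSimSpec, synth_ecg
from optopace.ecg import analyze_ecg
from optopace.stats import mann_whitney_u

spec = EcgSimSpec(duration=77.6, stim_onset_time=23.1, stim_latency=20.0, seed=1)
ecg, ttl, truth = synth_ecg(spec)

beats = analyze_ecg(ecg, ttl, mode="ventricular")
stim = beats.loc[beats.label == "stimulated", "r_duration_ms"].dropna()
unst = beats.loc[beats.label == "unstimulated", "r_duration_ms"].dropna()
u, p = mann_whitney_u(stim, unst)

print(f"unstimulated: n={len(unst)}  R duration {unst.mean():.2f} ± {unst.std():.2f} ms")
print(f"stimulated:   n={len(stim)}  R duration {stim.mean():.2f} ± {stim.std():.2f} ms")
print(f"Mann–Whitney U={u:.0f}  two-sided p={p:.3g}")
```

prints

```
unstimulated: n=115  R duration 11.88 ± 0.81 ms
stimulated:   n=273  R duration 17.74 ± 0.99 ms
Mann–Whitney U=31394  two-sided p=1.39e-54
```

Every beat the generator emitted was found, classified into the correct
group, and its R-wave duration recovered to a fraction of a millisecond
(11.88 vs 12 ms commanded, 17.74 vs 18 ms — the small shortfall is the
expected noise-induced bias at the zero crossings). The widening of the
driven R-waves is overwhelming at these sample sizes (p ≪ 0.0001).

The same stages are available from the shell:

```sh
optopace synth ecg --seed 1 --out run/
optopace ecg analyze --ecg run/ecg.csv --ttl run/ttl.csv --mode ventricular --out run/
optopace ecg compare --beats run/beats.csv
```

Each output directory receives a `provenance.json` recording the seed,
configuration hash, and every resolved parameter value.

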