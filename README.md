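# lamflow

Laminar analysis of multichannel V1 recordings: current-source-density
depth alignment, multi-unit response latencies, induced spectral power,
phase-triggered averaging, and band-integrated spectral Granger causality
with a time-reversal control — plus a synthetic laminar-session generator
with full ground truth, so every estimator in the chain is testable
without any recorded data.

## The problem

A 16-contact laminar probe (150 µm spacing) inserted perpendicular to the
cortical surface of primary visual cortex samples all cortical layers at
once.  Questions about inter-laminar communication — where gamma
oscillations arise, which layers drive which, how feedforward and
feedback signals differ spectrally — require a chain of delicate steps:
assigning each contact a cortical depth from the early layer-4c current
sink, separating locally generated signals from volume-conducted ones,
fitting response-onset latencies, quantifying stimulus-induced band
power, and inferring directed coupling while guarding against common-
noise artifacts.  `lamflow` implements that chain for anyone analyzing
laminar LFP/MUAe recordings with stimulus-event metadata, and provides a
generator whose sessions have known sinks, latencies, phase lags, and
directed-coupling graphs.

## The core quantities

* **CSD**: `CSD(z) = −σ·(Φ(z+h) − 2Φ(z) + Φ(z−h))/h²` with σ = 0.3 S/m,
  boundary contacts retained by duplicating the endpoint potentials
  (Vaknin).  Sinks are positive; the early granular sink (peak 35–55 ms)
  defines depth 0.
* **Latency**: the MUAe transient is fitted with
  `R(t) = G1·N(t;µ1,σ1) + G2·N(t;µ2,σ2) + ½·G3·(1+erf((t−µ3)/(√2σ3)))`;
  latency is the first 0.1 ms grid point with R(t) > 3 (z-units relative
  to the −300–0 ms baseline).
* **iSP**: spectrogram power (100 ms Hann windows, 10 ms step, FFT 1024)
  z-scored against pre-stimulus baseline, per frequency bin.
* **PTA**: broadband bipolar LFP averaged around troughs of a band-passed
  reference contact (θ/α/β/γ with ±120/80/80/25 ms windows).
* **Spectral GC**: Geweke's frequency-domain measure
  `f_{y→x}(ω) = ln S_xx/(S_xx − (Σ_yy − Σ_xy²/Σ_xx)|H_xy|²)` from a
  VAR(50) fitted to 256 samples from 200 ms post-onset; band value = mean
  over band bins; net GC = forward − backward; connections must pass the
  reverse-Granger test (dominant direction flips on time-reversed data
  and clears a trial-shuffled floor).

See `docs/methods.md` for assumptions, parameter defaults, and numerical
choices.

## Worked example

```python
from lamflow import SynthConfig, generate_session, AnalysisConfig, run_pipeline

rec, truth = generate_session(SynthConfig(seed=1))   # 6 diameters x 20 trials
bundle = run_pipeline(rec, AnalysisConfig(seed=1))

print("QC passed:", bundle.qc.passed,
      "| alignment contact:", bundle.depths.alignment_channel,
      "| sink peak:", f"{bundle.qc.sink_peak_ms:.0f} ms")

lat = bundle.latency_compartments
small = lat[lat.diameter_deg == 0.5].set_index("compartment").latency_ms
print("latency @0.5 deg: granular %.1f ms | infragranular %.1f ms | supragranular %.1f ms"
      % (small["granular"], small["infragranular"], small["supragranular"]))

gg = bundle.gc_graph.query("band == 'gamma' and diameter_deg == 15.0")
for (s, t) in truth.coupling_adjacency:
    row = gg[(gg.source == s) & (gg.target == t)].iloc[0]
    print(f"planted edge {s}->{t}: net gamma GC {row.net:+.3f}, "
          f"reverse-Granger pass: {row.rgt_pass}")
```

Output:

```
QC passed: True | alignment contact: 8 | sink peak: 44 ms
latency @0.5 deg: granular 44.0 ms | infragranular 52.2 ms | supragranular 58.2 ms
planted edge 11->14: net gamma GC +0.144, reverse-Granger pass: True
planted edge 14->5: net gamma GC +0.122, reverse-Granger pass: True
planted edge 8->5: net gamma GC +0.109, reverse-Granger pass: True
```

What these numbers mean: the session generator planted its granular sink
on contact 8 peaking 45 ms after stimulus onset — the quality control and
alignment recover contact 8 with a 44 ms peak (1 ms off, one spectrogram
sample).  The planted response-onset ordering (granular before
infragranular before supragranular, ground truth 42.9 / 50.7 / 57.7 ms
for the smallest grating) is recovered within ~1.5 ms by the transient
fits.  The planted gamma-band coupling chain — deep contact 11 driving
contact 14, contact 14 driving superficial contact 5, and granular
contact 8 driving contact 5 — appears as positive net Granger causality
in exactly those directions, and every planted edge survives the
time-reversal screen.

The same workflow is available from a shell:

```bash
lamflow synth --seed 1 -o session.h5
lamflow run --session session.h5 --seed 1 -o results/
lamflow summarize results/
```

## Layout

```
src/lamflow/
  containers.py   in-memory types + versioned HDF5 session container
  synth.py        synthetic laminar sessions with ground truth
  preprocess.py   LFP/MUAe conditioning, epoching, bipolar, z-scoring
  csd.py          inverse CSD, sink alignment, depths, session QC
  latency.py      transient-model fits and threshold latencies
  spectral.py     spectrograms, induced power, band profiles, γ peak
  pta.py          phase-triggered averaging
  gc.py           VAR fitting, Geweke spectra, net GC, reverse-Granger test
  stats.py        cluster-mass permutation test, BH-FDR, signed rank
  pipeline.py     end-to-end orchestration and size-tuning summaries
  cli.py          `lamflow synth / run / summarize`
```
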