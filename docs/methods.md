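# Methods

`lamflow` implements a complete analysis chain for laminar-probe
recordings from primary visual cortex — 16 contacts at 150 µm spacing
spanning the cortical depth, recorded while grating stimuli of six
diameters (0.5°–15°) are presented for 500 ms after a 500 ms blank — and a
synthetic session generator that provides ground truth for every stage.
This note documents the models, the parameters that matter, the numerical
choices, and what the synthetic tests do and do not establish.

## Signal conditioning

The raw broadband signal (default 8 kHz in the generator; the same chain
applies at 32 kHz) is split into two derived signals:

* **LFP** — 3rd-order Butterworth band-pass 0.75–300 Hz, then integer-
  factor decimation to 1 kHz.
* **MUAe** — 3rd-order Butterworth band-pass in the multi-unit range
  (default 600–3600 Hz at an 8 kHz raw rate; 600–9000 Hz is the
  conventional band when the raw rate supports it), full-wave
  rectification, 200 Hz low-pass, decimation to 1 kHz.  The envelope
  tracks aggregate local spiking.

All filtering is zero-phase (forward–backward, `sosfiltfilt`).  The
filters' group delay would otherwise bias latency estimates; the cost is a
doubled effective filter order, which is irrelevant at these bandwidths.
Decimation requires an integer factor (8000 → 1000); no resampling
interpolation is performed.  Epochs are cut as half-open windows
[−500, 500) ms around stimulus onset with 0-based sample indexing, so a
1 kHz epoch has exactly 1000 samples.  Baseline z-scoring uses the −300–0
ms window, pooling mean and SD across all trials per channel.

## Current source density and laminar alignment

The CSD is the discrete second spatial derivative of the trial-averaged
potential profile Φ,

    CSD(z) = −σ · (Φ(z+h) − 2Φ(z) + Φ(z−h)) / h²,

with σ = 0.3 S/m and h = 150 µm; the top and bottom contacts are retained
by duplicating the boundary potentials (Vaknin).  Potentials are held in
volts and spacing in meters internally, so CSD values are SI (A/m³).
**Sign convention: sinks are positive.**  Many toolboxes use the opposite
sign; exported tables state the convention.

Sessions are aligned at the early granular current sink: the contact whose
largest positive CSD peak falls in the 35–55 ms post-onset window defines
depth 0 (putative layer 4c); contacts above it get positive depths (+450
µm = three contacts up).  Ties break toward the more superficial contact
with a logged warning.  Session QC requires (1) an identifiable sink
peaking no later than 50 ms, (2) the sink on contacts 7–12 from the top
(guaranteeing coverage of layers 2–6), and (3) a manual pattern-
consistency flag that is recorded but never auto-decided.  Profile
normalization for cross-session averaging divides by the positive peak at
the alignment contact in the 40–70 ms window; both windows are
configurable because the sink-search and normalization conventions differ
legitimately between use cases.

The generator's forward volume-conduction model is the exact inverse of
this discrete operator rather than a physical line-source model: it is
chosen so the CSD stage has a bit-exact oracle.  One consequence is
structural: the operator annihilates depth-constant potentials, so its
range is the charge-balanced subspace (every realizable CSD profile sums
to zero over depth — which physical current conservation requires anyway).
The forward model therefore rejects unbalanced profiles unless asked to
project them, and the generator only plants balanced ones (a Gaussian sink
with its return current spread uniformly in depth).

## MUAe response latency

The transient response in the 0–200 ms window of the baseline-z-scored
MUAe is fitted with the sum of two normalized Gaussians and a cumulative
Gaussian,

    R(t) = G1·N(t; µ1, σ1) + G2·N(t; µ2, σ2)
           + ½·G3·(1 + erf((t − µ3)/(√2·σ3))),

by bounded nonlinear least squares.  The surface is multimodal, so the fit
starts from data-driven values (µ1 at the global peak, µ3 at the half-rise
time, σ = 10 ms, amplitudes from the peak and plateau heights) plus four
jittered restarts; the lowest residual sum of squares wins.  Means are
bounded to the window, widths to [1, 100] ms, amplitudes free-signed so
suppression transients remain representable.  Latency is the earliest time
on a 0.1 ms grid at which the fitted model exceeds z = 3 — an absolute
criterion, deliberately not amplitude-relative, so latencies are
comparable across stimulus sizes whose response amplitudes differ under
surround suppression.  Fits use trial-averaged traces per condition.
Laminar compartment summaries average two adjacent contacts for the
supragranular (+450/+600 µm) and infragranular (−450/−600 µm)
compartments; granular is the alignment contact.

## Induced spectral power

Spectrograms use 100 ms Hann-tapered windows stepped by 10 ms, demeaned
per window and zero-padded to a 1024-point FFT (bin spacing fs/1024
≈ 0.98 Hz at 1 kHz).  Window centers define timestamps.  Note the
resolution limit: a 100 ms window cannot resolve structure below ~10 Hz,
and per-window demeaning suppresses the lowest bins; θ-band (4–8 Hz)
values are therefore smoothed estimates, not line spectra.

Induced spectral power (iSP) is a z-score against the pre-stimulus
baseline, computed in paired form: per trial and frequency bin, the power
in each stimulus window minus that trial's mean baseline-window power;
z = across-trial mean difference / its standard error.  This choice (over
z-scoring against the across-trial spread of baseline power) is what makes
the null calibrated — on stimulus-identical data the statistic is close to
N(0, 1) per bin, with a slight heavy-tail inflation at small trial counts
because window power is skewed.  A single-trial variant is available
(`method="single-trial"`) for comparison with analyses that normalize each
trial separately.

Band power averages z over band bins (θ 4–8, α 8–13, β 14–25, γ 35–55 Hz)
and the sustained window 200–500 ms.  The γ peak frequency is the bin of
maximal sustained z in a 25–65 Hz search range, undefined when no bin is
positive.

## Phase-triggered averaging

For a chosen reference contact, the bipolar LFP is band-pass filtered
(zero-phase 3rd-order Butterworth; γ here is 30–55 Hz — the
phase-extraction band intentionally differs from the 35–55 Hz power band)
and its strict local minima inside the sustained window are the alignment
points.  No amplitude threshold is applied: spurious noise troughs carry
no consistent phase and average out.  The *broadband* bipolar LFP of every
contact is averaged in ±120/80/80/25 ms windows (θ/α/β/γ) around each
trough, pooled across a condition's trials; triggers whose window would
leave the epoch are discarded.  The per-channel lag is the time of the
trough nearest lag 0 (negative = target leads reference); at the
reference contact itself this sits at 0 by construction.

## Spectral Granger causality and the reverse-Granger test

For each ordered contact pair of the bipolar montage, a bivariate VAR is
fitted to 256-sample stretches starting 200 ms post-onset, with a fixed
order of 50 (≈ 50 ms at 1 kHz — long enough to capture a full γ cycle of
history).  Estimation is multi-trial ordinary least squares on per-trial
demeaned data via normal equations; stability of the companion matrix is
verified, and thin samples (fewer than ten observations per parameter)
warn.  Geweke's frequency-domain measure is computed from the transfer
function H(f) = (I − Σₖ Aₖ e^{−i2πfk/fs})⁻¹ and innovation covariance Σ
with the standard partialing of instantaneous correlation:

    f_{y→x}(ω) = ln S_xx(ω) / (S_xx(ω) − (Σ_yy − Σ_xy²/Σ_xx)|H_xy(ω)|²).

Band values are the *mean* GCI over the band's FFT bins (invariant to grid
density); net GC is forward minus backward and is antisymmetric under pair
swap by construction.  The frequency grid reuses the spectral module's
FFT bins (1–100 Hz).

Additive correlated noise mimics directed interaction, so every
connection is screened by the reverse-Granger test: the net GC is
recomputed on time-reversed trials.  A genuine lagged interaction flips
its dominant direction under reversal; a common-noise artifact does not.
A connection passes when the sign flips *and* both |net| values exceed a
floor, by default the maximum of 19 trial-shuffled surrogates (shuffling
the trial pairing destroys lagged dependence while preserving each
channel's dynamics; the max of 19 is an exact 95th percentile).  One
shuffled fit serves all four bands.

Conditional (multivariate) GC is out of scope; the pairwise measure can
attribute shared influence to both members of a pair, which is precisely
what the reversal screen and the net statistic mitigate.

## Cluster-mass permutation test, FDR, signed rank

Paired session × map comparisons (depth × time CSD differences,
depth × frequency power differences) use a cluster-mass permutation test:
the pixelwise one-sample t of the per-session difference is thresholded at
the two-sided p < 0.05 critical value, supra-threshold pixels form
4-connected clusters, cluster mass is the sum of |t|, and the null is the
permutation distribution of the maximal mass under per-session sign flips
(exhaustively enumerated when 2ⁿ ≤ 4096, else 1000 random flips including
the identity).  Ties between observed and permutation masses are counted
tolerantly, making p-values exactly invariant to session relabeling.  The
cluster-forming statistic is configurable in principle (t by default);
multiple-comparison control across independent tests uses
Benjamini–Hochberg FDR (statsmodels), and paired location tests use the
two-sided exact Wilcoxon signed rank (scipy), refusing n < 5 and returning
p = 1 for all-zero differences.

## The synthetic generator

The generator composes four signal families into a raw recording with the
study's protocol constants (16 × 150 µm contacts, six diameters, 500 ms
blank + 500 ms stimulus, ~1 s of padding at both ends):

1. **Evoked dipole.**  A charge-balanced CSD profile (Gaussian sink of
   width 0.9 contacts at the configured granular contact, default 8,
   peaking at 45 ms with an 8 ms Gaussian time course, peak 1500 A/m³)
   projected to potentials through the exact inverse operator.  Amplitude
   declines 30 % from smallest to largest stimulus.
2. **Coupled oscillations.**  Each contact named in the coupling
   specification carries a latent: a resonant AR(2) (pole radius 0.93)
   driven by band-passed innovations, so the latent is genuinely
   narrowband.  Directed edges add lagged copies of the source latent to
   the target (lagged-oscillator coupling), so the planted lag is exactly
   the peak of the latent cross-correlation and the planted direction is
   Granger-detectable.  The default network routes γ deep-to-superficial:
   contact 11 → 14 (0.8, 4 ms), 14 → 5 (0.7, 5 ms), 8 → 5 (0.5, 3 ms);
   γ center frequency falls from 45 to 38 Hz with stimulus size while
   amplitude grows.  Latents are mixed into the potentials with a dipolar
   ±0.5 footprint on the flanking contacts, giving unit gain in the
   centered-difference bipolar signal at the home contact.
3. **Multi-unit carrier.**  Band-limited noise whose envelope follows the
   per-channel, per-size transient profile R(t).  The envelope gain is
   calibrated from the rectify–low-pass chain statistics of a unit
   carrier, so the baseline-z-scored MUAe tracks the planted profile in
   expectation; the noiseless profile's first crossing of z = 3 on a 0.1
   ms grid is the latency ground truth, free of estimator noise.  Default
   profiles give granular onset ≈ 44 ms, infragranular ≈ 51 ms,
   supragranular ≈ 58 ms, with size-dependent transient shifts (+3 ms
   granular, −6 ms infragranular at the largest size) and suppression
   strongest superficially (45 % supragranular, 20 % infragranular).
4. **Noise.**  Per-channel AR(1) background (30 µV) plus white sensor
   noise (8 µV) and a shared AR(1) common-noise component with
   depth-varying gain (gain 0.5 by default) — the scenario the reversal
   test must reject when directed coupling is absent.

Determinism: one master seed spawns a named stream per family; identical
seeds give bit-identical sessions.  Sessions round-trip through a
versioned HDF5 container (`/samples`, `/events`, `/geometry`,
`/ground_truth`) with a CSV events sidecar.

**What the generator does not emulate:** spike waveforms (the MUA is an
amplitude-modulated noise carrier), eye movements and microsaccades,
line noise, non-stationary arousal drifts, electrode drift, realistic
volume-conduction geometry (the forward model is the discrete operator
inverse, not a physical medium), and cross-frequency coupling.  Passing
tests therefore establish that the estimators recover the quantities they
claim from signals with the stated statistical structure — not that real
recordings satisfy that structure.

## Problem sizes used in tests

The acceptance checks run the chain at sizes chosen to make the
statistical assertions decisive on a single workstation core: latency
recovery over 50 noisy fits; the iSP null over 1000 well-separated bins
from 200-trial null datasets; Geweke-spectrum accuracy at 400 trials ×
256 samples; reversal-test discrimination over 100 simulations per
scenario at 120 trials; cluster-test calibration over 500 null replicates
of 12-session 10 × 30 maps; and planted-direction recovery over 20
generated sessions at the default 6 × 20-trial size.

## Known limitations

* The VAR order of 50 is held fixed (matching the analysis convention)
  rather than selected by information criteria; at small trial counts this
  over-parameterizes and inflates GCI variance, which the shuffle floor
  absorbs but does not remove.
* The iSP null inherits a small heavy-tail inflation at low trial counts
  (window power is χ²-like; the paired t statistic is exact only
  asymptotically).
* Pairwise GC cannot distinguish a direct edge from a common driver with
  unequal lags; only the conditional extension (out of scope) could.
* The bipolar derivation assigns the centered difference Φ(i−1) − Φ(i+1)
  to contact i.  The successive-pair difference is a legitimate
  alternative convention; it shifts effective depth assignments by half a
  contact and is not implemented as a separate mode.
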