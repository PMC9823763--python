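# Methods

This document describes the signal model, algorithms and conventions
implemented in `emoradar`, in processing order. Notation: `c` is the speed of
light, `λ` the carrier wavelength, `S` the chirp slope (Hz/s), `T_c` the
chirp duration, `R(t)` the target range.

## 1. FMCW signal model and synthetic generator (`emoradar.synthgen`)

An FMCW radar transmits chirps whose frequency ramps linearly over a
bandwidth `B = S·T_c`. Mixing the transmitted and received chirps produces
the intermediate-frequency (IF) signal; for a point target at range `R` the
IF tone is

```
s(t_fast) = A · cos(2π f_IF t_fast + φ_IF),
f_IF = 2 S R / c,            (range → fast-time frequency)
φ_IF = 4π R / λ.             (sub-wavelength motion → phase)
```

Differentiating these gives the sensitivities checked by the analytic
acceptance test: at `S = 50 MHz/µs` a range step of 0.1 mm moves the IF tone
by `Δf = 2SΔR/c ≈ 33.3 Hz`, which over a 40 µs chirp is `Δf·T_c ≈ 0.0013`
cycles — unmeasurably small in frequency — while the same step rotates the
IF phase by `4πΔR/λ ≈ 18°` at 77 GHz. This asymmetry is why vital signs are
read from the phase, not the range bin.

The generator simulates the IF data cube `(frames, chirps, samples)`
directly from this model: a "chest" target at
`R(t) = R₀ + d(t)` plus optional static reflectors, optional per-chirp
oscillator phase noise, real (`cos`) or complex I/Q output. The chest
displacement is

```
d(t) = A_r sin(2π f_r t) + A_h sin(2π f_h t) + harmonics + white noise,
```

with respiration constrained to [0.1, 0.6] Hz and heartbeat to [0.8, 3.3] Hz
(the module's physiological bands), heart amplitude strictly below the
respiration amplitude, and a Nyquist guard on the highest harmonic.

Three radar profiles ship with the package: `default` (77 GHz, 4 GHz
bandwidth over a 60 µs chirp, 20 frames/s), `analytic` (40 µs chirp at
50 MHz/µs, used by the closed-form checks), and `reduced` (default timing
with 2 chirps × 64 samples per frame, for batch studies).

Emotion presets (`relaxed`, `happy`, `sad`, `angry`) are boxes in
(respiration rate, heart rate, amplitude) space plus a parametric face
renderer (mouth curvature, brow angle, eye openness, per-frame jitter). The
amplitude boxes are deliberately small enough that the worst-case per-frame
phase step stays below π (see §2 on unwrapping); a unit test asserts this
bound on every preset.

## 2. Radar processing chain (`emoradar.radar`)

1. **MTI (moving-target indication).** Sliding-window mean subtraction over
   slow time: each frame's output is the average, over all length-`w`
   windows covering it, of `x − mean(window)`. Static returns are removed
   exactly (a constant input maps to zero); moving returns keep their
   mean-removed waveform.
2. **Range FFT.** Fast-time FFT per frame (chirps reduced by `mean` or
   `first`), giving a range-profile stack. The target bin is the dominant
   non-DC bin of the MTI-filtered average profile; if no bin dominates the
   noise floor (`snr_threshold`), a `LowSNRWarning` is raised.
3. **Phase extraction and unwrapping.** The complex angle at the target bin
   over slow time, unwrapped by ±2π jumps. Unwrapping is only valid while
   the per-frame phase step stays below π: at 77 GHz / 20 frames/s this
   budget is ≈ 1.01 rad per mm·Hz of sinusoidal displacement, which bounds
   the usable amplitude × frequency product.
4. **Displacement conversion with dechirp sensitivity correction.** Naively
   `d = λ·φ/(4π)`, but on dechirped data the measured phase per metre is
   `4π/λ + 4π·S·t_c/c`, where `t_c` is the effective fast-time sampling
   instant (window centroid, `(N−1)/(2·f_ADC)` for a plain mean). The
   package multiplies by the closed-form correction
   `1/(1 + S·t_c·λ/c)`; skipping it biases amplitudes by ~2% at the default
   profile. The round trip (simulate → extract) is exact to <1e-6 relative
   on complex I/Q data.
5. **Low-pass filtering.** Zero-phase (forward-backward) 4th-order
   Butterworth with 3.3 Hz cutoff, removing out-of-band noise without
   phase distortion.

## 3. Variational mode decomposition (`emoradar.vmd`)

VMD decomposes the displacement into `k` band-limited intrinsic mode
functions (IMFs) by ADMM in the frequency domain. Per iteration, each mode
is re-estimated by a Wiener-filter update centred on its current centre
frequency,

```
û_k ← (f̂ − Σ_{i≠k} û_i + λ̂/2) / (1 + 2α(ω − ω_k)²),
ω_k ← ∫ ω |û_k(ω)|² dω / ∫ |û_k(ω)|² dω,
```

with dual ascent on the reconstruction constraint. The implementation is
vectorized over modes; a deliberately naive loop transcription
(`vmd_decompose_reference`) serves as the correctness oracle (< 1e-8
relative agreement). Signals are mirror-extended by half their length to
suppress boundary effects; centre frequencies are reported in Hz, sorted
ascending.

**Mode labelling and rates.** Each IMF's mean instantaneous frequency
(Hilbert transform, 5% edge trim) assigns it to the respiration
[0.1, 0.6] Hz or heartbeat [0.8, 3.3] Hz band; the per-band sums are the
vital-sign waveforms. Rates come from a zero-padded FFT of the band signal
with parabolic peak interpolation, reported per minute; a flat spectrum
(peak below `snr_threshold` × median) raises `LowSNRWarning`.

**Choice of k and α.** The solver defaults to `k=3, α=2000`. The batch
pipeline instead uses `k=4, α=50000`: chest respiration is ~20 dB stronger
than the heartbeat, and at low α the power-weighted centroid update drags
every mode onto the respiration peak (mode collapse). The narrower-band,
higher-k setting separates the components reliably on 60 s trials;
`select_k` (reversed-initialization stability + energy criteria) can
re-select k per signal.

## 4. Keyframe selection (`emoradar.video`)

Face detection is a pluggable contract (`detector(frame) → boxes`); the
package ships a colour-threshold detector for the synthetic faces and an
oracle detector for tests. Detected faces are cropped to the largest box.
Within each sliding window of 11 usable frames (stride 8), each frame is
scored by the chi-square distance between its per-channel colour histogram
(32 bins/channel) and those of its in-window neighbours; the
minimum-score (locally most stable) frame becomes the window's keyframe,
resized to 227×227. For `n` usable frames the keyframe count is
`floor((n−11)/8) + 1`; ties go to the earliest frame.

## 5. Recognition network (`emoradar.model`)

Pure-NumPy three-branch network (forward and backward passes implemented
from scratch):

- **1-D branches** (respiration and heartbeat, shared architecture,
  separate weights): four blocks of Conv1D('same') → BatchNorm → ELU →
  MaxPool1D; filters 16/32/32/64; a 1200-sample input yields a length-9
  sequence of 64-channel features.
- **2-D branch** (per keyframe): four blocks of Conv2D(3×3) → BatchNorm →
  ELU → MaxPool2D; filters 32/64/96/96; global average pooling gives one
  96-vector per keyframe (227 → 113 → 56 → 14 → 3 spatially).
- **Fusion**: per time step, concatenate [resp | heart | face] features
  (64+64+96 = 224), keyframes resampled to the temporal axis by nearest
  index.
- **GRU(64)** over the fused sequence, final hidden state → dense →
  softmax over the four classes. Total 251,012 parameters.

Convolutions are computed as sums over kernel offsets of strided-slice
matrix products (contiguous memory access, no gather); MaxPool2D is
repeated 2×2 elementwise-max halvings with boolean winner masks. All layers
pass float64 central-difference gradient checks at ~1e-9 relative error.
Training uses softmax cross-entropy with Adam; inputs are z-scored per
sample (series) and scaled to [−0.5, 0.5] (images); the best-validation
checkpoint is kept. A `zero_modalities` switch ablates any branch at
inference for modality-contribution probes.

## 6. Evaluation (`emoradar.evaluation`)

Multi-class confusion matrices are reduced one-vs-rest per class;
`precision = TP/(TP+FP)`, `recall = TP/(TP+FN)`, F is their harmonic mean
(defined as 0 when both are 0), accuracy is the diagonal mass. Empty
denominators give NaN, a warning, and exclusion from macro averages. ROC
curves and AUC are computed one-vs-rest per class (scikit-learn). LOOCV
reports per-fold one-hot MSE and 0/1 correctness.

Split protocols: `person_dependent` apportions validation/test quotas
across (label, subject) strata by largest remainder, so every subject is
seen in training; `person_independent` assigns whole subjects greedily to
test, then validation, so test subjects are never trained on. Validation
and test sizes are `round(0.1·n)` each; train takes the rest.

## 7. Pipeline and CLI (`emoradar.pipeline`, `emoradar.cli`)

`PipelineConfig` is a frozen, YAML-round-trippable record of every
processing knob with documented provenance (reference setting vs package
convention). `process_trial` runs a trial through both halves (radar →
vitals, frames → keyframes) and packs an `EmotionSample`;
`process_dataset` adds a rates table (estimated and true breaths/min and
beats/min) for error statistics and R² fits. The CLI exposes `simulate`,
`extract`, `keyframes`, `train`, `evaluate` and `e2e`, each logging stage
timings and writing its effective configuration next to its outputs so runs
are reproducible from the artifacts alone.
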