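# emoradar

Contactless multimodal emotion recognition from FMCW radar vital signs and
facial video keyframes — a complete, self-contained reference implementation
with a physics-based synthetic data generator, a pure-NumPy neural network,
and an end-to-end command-line pipeline.

## The idea

Emotions move the body. Respiration and heartbeat shift a person's chest by
millimetres and sub-millimetres, and a 77 GHz FMCW radar can read those
shifts without contact: the range of a reflector sets the frequency of the
radar's intermediate-frequency (IF) tone (`f_IF = 2·slope·R/c`), while
sub-wavelength motion rotates its phase (`φ = 4πR/λ`). The asymmetry is
dramatic — a 0.1 mm chest movement shifts the IF tone by only ~33 Hz
(~0.001 cycles over one 40 µs chirp, unmeasurable) but rotates the phase by
~18°, easily measurable. So vital signs are read from the slow-time phase at
the target's range bin.

The package implements the full chain:

1. **Radar processing** (`emoradar.radar`): sliding-window MTI clutter
   removal → range FFT → target-bin phase extraction and unwrapping →
   displacement in mm (with a closed-form dechirp sensitivity correction)
   → zero-phase low-pass filtering.
2. **Variational mode decomposition** (`emoradar.vmd`): frequency-domain
   ADMM splits the displacement into band-limited modes; modes are labelled
   respiration [0.1, 0.6] Hz or heartbeat [0.8, 3.3] Hz by mean
   instantaneous frequency (Hilbert), and per-minute rates come from
   parabolic-interpolated spectra. A naive reference implementation serves
   as a correctness oracle.
3. **Video keyframes** (`emoradar.video`): faces detected per frame
   (pluggable detector contract), then within each sliding 11-frame window
   (stride 8) the frame with the smallest chi-square histogram distance to
   its neighbours — the most stable one — becomes a 227×227 keyframe.
4. **Recognition network** (`emoradar.model`): two 1-D CNN branches
   (respiration, heartbeat) + a per-keyframe 2-D CNN, feature fusion, a
   GRU(64) and a 4-class softmax (relaxed / happy / sad / angry); 251k
   parameters, forward *and* backward passes in pure NumPy, verified by
   float64 gradient checks.
5. **Evaluation** (`emoradar.evaluation`): one-vs-rest
   precision/recall/F, confusion matrices, ROC/AUC, LOOCV, and
   person-dependent / person-independent split protocols.
6. **Synthetic generator** (`emoradar.synthgen`): simulates the IF data
   cube sample-by-sample from the signal model (chest target + static
   clutter + phase noise), renders parametric face frames per emotion, and
   packages balanced labelled datasets. Everything is seeded and
   deterministic.

See `docs/methods.md` for the mathematics and conventions.

## Worked example: from raw cube to heart rate

```python
import numpy as np
from emoradar import (DisplacementModel, StaticReflector,
                      extract_displacement, extract_vital_signs,
                      make_displacement, reduced_profile, simulate_if_cube,
                      VMDParams)

# 1. simulate a 60 s chest displacement: 0.30 Hz breathing, 1.20 Hz heartbeat
config = reduced_profile()
model = DisplacementModel(resp_amplitude=2.0, resp_freq=0.30,
                          heart_amplitude=0.3, heart_freq=1.20,
                          noise_sd=0.05)
disp = make_displacement(model, duration=60.0, rate=config.frame_rate, seed=7)

# 2. simulate the IF radar cube for that chest plus a static wall
cube = simulate_if_cube(config, disp, statics=[StaticReflector(0.9, 1.5)],
                        phase_noise_sd=0.02, seed=7)
print("cube:", cube.data.shape, cube.data.dtype)

# 3. radar chain: MTI -> range FFT -> phase -> displacement (mm)
recovered = extract_displacement(cube)
corr = np.corrcoef(recovered.values, disp.values - disp.values.mean())[0, 1]
print(f"displacement correlation with truth: {corr:.4f}")

# 4. VMD -> respiration / heartbeat waveforms and per-minute rates
vitals = extract_vital_signs(recovered, params=VMDParams(k=4, alpha=50000.0))
print(f"breathing rate: {vitals.breathing_rate:.2f} breaths/min (true 18.00)")
print(f"heart rate:     {vitals.heart_rate:.2f} bpm (true 72.00)")
```

Output (verbatim):

```
cube: (1200, 2, 64) float32
displacement correlation with truth: 0.9997
breathing rate: 17.99 breaths/min (true 18.00)
heart rate:     72.01 bpm (true 72.00)
```

## Command-line pipeline

```console
$ emoradar simulate --n-per-class 1 --seed 5 --duration 60.0 --out demo/data
wrote 4 trials to demo/data

$ emoradar extract --cube demo/data/happy_0000.h5 --out demo/vitals
wrote vitals to demo/vitals (rates: {'breathing_rate_bpm': 17.780361697566974,
'heart_rate_bpm': 78.32202970267461, 'low_snr': False})
```

(the manifest lists that trial's ground truth as 0.2964 Hz breathing =
17.78 breaths/min and 1.3051 Hz heartbeat = 78.30 bpm, so both estimates
land within 0.03 bpm.)

Other subcommands: `keyframes` (frame directory → keyframe PNGs), `train`
(dataset → checkpoint + history + splits), `evaluate` (checkpoint →
confusion matrix, metrics, ROC), and `e2e` (simulate + process + train +
evaluate in one run). Every command writes its effective configuration next
to its outputs; all randomness is seeded.

## Classification at a glance

With the four synthetic emotion presets (which encode the standard
physiology: arousal raises heart and breathing rate, valence mostly shows
in the face), a 200-trial dataset processed end-to-end and trained for 5
epochs reaches 100% test accuracy under the person-dependent protocol —
the synthetic classes are separable by design; the value of the exercise is
that every stage (radar phase → VMD → keyframes → fusion network) works on
nothing but raw simulated I/F samples and pixels. `scripts/acceptance.py
--seed <int> --out <path>` reproduces this plus all analytic checks and
writes the numbers as JSON.

## Repository layout

```
src/emoradar/        synthgen, radar, vmd, video, model, evaluation,
                     pipeline, cli
tests/               unit + property tests per module; test_acceptance.py
                     holds one test per acceptance criterion
scripts/acceptance.py  headline-quantity run (JSON output)
docs/methods.md      signal model, algorithms, conventions
```
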