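"""Synthetic trial generation: radar IF cubes and procedural face videos.

This module produces labeled synthetic trials with the statistical structure
the downstream pipeline assumes: a parametric chest-displacement model (two
quasi-periodic components at respiration and heartbeat rates plus noise),
an FMCW intermediate-frequency (IF) sample simulator with additive static
reflectors, and a procedural face renderer whose geometry varies by emotion.

The FMCW model: a chirp of bandwidth ``B`` and duration ``T_c`` reflected by
a target at range ``R`` mixes down to an IF tone of frequency
``f_IF = 2 * slope * R / c`` and phase ``phi_IF = 4 * pi * R / lambda``.
Chest motion modulates ``R = delta_d + d(t)`` across frames (slow time), so
the IF phase carries the sub-wavelength displacement ``d(t)``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

SPEED_OF_LIGHT = 299792458.0

EMOTIONS = ("relaxed", "happy", "sad", "angry")


# ---------------------------------------------------------------------------
# configuration containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RadarConfig:
    """FMCW chirp/frame timing and sampling parameters.

    The slope is not stored independently: it is always ``bandwidth /
    chirp_duration``, and the wavelength is ``c / carrier_freq``, so the
    invariants tying them together hold by construction.
    """

    carrier_freq: float       # Hz
    bandwidth: float          # Hz
    chirp_duration: float     # s
    frame_period: float       # s
    chirps_per_frame: int
    samples_per_chirp: int
    adc_rate: float           # Hz

    def __post_init__(self) -> None:
        if self.carrier_freq <= 0 or self.bandwidth <= 0 or self.chirp_duration <= 0:
            raise ValueError("carrier_freq, bandwidth and chirp_duration must be positive")
        if self.frame_period <= 0 or self.adc_rate <= 0:
            raise ValueError("frame_period and adc_rate must be positive")
        if self.chirps_per_frame < 1 or self.samples_per_chirp < 1:
            raise ValueError("counts must be >= 1")

    @property
    def freq_slope(self) -> float:
        """Chirp slope in Hz/s (= bandwidth / chirp_duration)."""
        return self.bandwidth / self.chirp_duration

    @property
    def wavelength(self) -> float:
        """Carrier wavelength in m."""
        return SPEED_OF_LIGHT / self.carrier_freq

    @property
    def frame_rate(self) -> float:
        """Slow-time sampling rate in Hz."""
        return 1.0 / self.frame_period

    @property
    def max_unambiguous_range(self) -> float:
        """Range whose IF tone sits at the real-sampling Nyquist frequency."""
        return (self.adc_rate / 2.0) * SPEED_OF_LIGHT / (2.0 * self.freq_slope)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RadarConfig":
        return cls(**d)


def default_profile(*, chirps_per_frame: int = 128,
                    samples_per_chirp: int = 256) -> RadarConfig:
    """77 GHz profile: 4 GHz bandwidth over a 60 us chirp, 20 Hz frame rate.

    The ADC is assumed to span the whole chirp, so ``adc_rate =
    samples_per_chirp / chirp_duration``.
    """
    chirp = 60e-6
    return RadarConfig(
        carrier_freq=77e9, bandwidth=4e9, chirp_duration=chirp,
        frame_period=50e-3, chirps_per_frame=chirps_per_frame,
        samples_per_chirp=samples_per_chirp,
        adc_rate=samples_per_chirp / chirp,
    )


def analytic_profile(*, chirps_per_frame: int = 16,
                     samples_per_chirp: int = 256) -> RadarConfig:
    """77 GHz profile with a 40 us chirp at 50 MHz/us slope (2 GHz sweep).

    Used by the closed-form sensitivity checks: a 0.1 mm range step at this
    slope moves the IF tone by ~33.3 Hz and rotates the IF phase by ~18 deg.
    """
    chirp = 40e-6
    slope = 50e6 / 1e-6
    return RadarConfig(
        carrier_freq=77e9, bandwidth=slope * chirp, chirp_duration=chirp,
        frame_period=50e-3, chirps_per_frame=chirps_per_frame,
        samples_per_chirp=samples_per_chirp,
        adc_rate=samples_per_chirp / chirp,
    )


def reduced_profile(*, chirps_per_frame: int = 2,
                    samples_per_chirp: int = 64) -> RadarConfig:
    """Default timing with few chirps/samples, for batch simulation studies."""
    return default_profile(chirps_per_frame=chirps_per_frame,
                           samples_per_chirp=samples_per_chirp)


# ---------------------------------------------------------------------------
# slow-time series container (shared with the radar module)
# ---------------------------------------------------------------------------

@dataclass
class SlowTimeSeries:
    """Uniformly sampled scalar series at the slow-time (frame) rate."""

    values: np.ndarray
    rate: float              # Hz
    units: str = "a.u."      # one of {"rad", "mm", "a.u."}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("SlowTimeSeries values must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("SlowTimeSeries values must be finite")
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.rate

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# units: {self.units}, rate_hz: {self.rate}\n")
            fh.write("time_s,value\n")
            for t, v in zip(self.times, self.values):
                fh.write(f"{t:.6f},{v:.9g}\n")

    @classmethod
    def from_csv(cls, path) -> "SlowTimeSeries":
        with open(path) as fh:
            header = fh.readline()
        units = header.split("units:")[1].split(",")[0].strip()
        rate = float(header.split("rate_hz:")[1].strip())
        df = pd.read_csv(path, comment=None, skiprows=1)
        return cls(values=df["value"].to_numpy(), rate=rate, units=units)


# ---------------------------------------------------------------------------
# chest displacement model
# ---------------------------------------------------------------------------

@dataclass
class DisplacementModel:
    """Quasi-periodic chest-wall displacement: respiration + heartbeat.

    Amplitudes are in mm; the cardiac component is physiologically
    sub-millimetre and must be smaller than the respiratory one. Harmonics
    are given as (multiple of heart_freq, amplitude relative to
    heart_amplitude).
    """

    resp_amplitude: float = 5.0        # mm
    resp_freq: float = 0.25            # Hz
    heart_amplitude: float = 0.4       # mm
    heart_freq: float = 1.2            # Hz
    heart_harmonics: tuple = ((2, 0.3),)
    noise_sd: float = 0.05             # mm
    baseline_range: float = 0.5        # m (delta_d, radar-to-chest distance)

    def __post_init__(self) -> None:
        if not (0.1 <= self.resp_freq <= 0.6):
            raise ValueError("resp_freq must lie in [0.1, 0.6] Hz")
        if not (0.8 <= self.heart_freq <= 3.3):
            raise ValueError("heart_freq must lie in [0.8, 3.3] Hz")
        if self.resp_amplitude <= 0 or self.heart_amplitude <= 0:
            raise ValueError("amplitudes must be positive")
        if self.heart_amplitude >= self.resp_amplitude:
            raise ValueError("cardiac displacement must be smaller than respiratory")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.baseline_range <= 0:
            raise ValueError("baseline_range must be positive")

    @property
    def max_frequency(self) -> float:
        mults = [m for m, _ in self.heart_harmonics] or [1]
        return max(self.resp_freq, self.heart_freq * max(mults))


def make_displacement(model: DisplacementModel, duration: float, rate: float,
                      seed: int) -> SlowTimeSeries:
    """Sample the chest displacement d(t) in mm at the given rate.

    d(t) = A_r sin(2 pi f_r t) + A_h sin(2 pi f_h t)
           + sum_harmonics + N(0, noise_sd).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if rate < 2.0 * model.max_frequency:
        raise ValueError(
            f"sampling rate {rate} Hz is below Nyquist for the highest "
            f"displacement component at {model.max_frequency} Hz")
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    d = model.resp_amplitude * np.sin(2 * np.pi * model.resp_freq * t)
    d += model.heart_amplitude * np.sin(2 * np.pi * model.heart_freq * t)
    for mult, rel in model.heart_harmonics:
        d += model.heart_amplitude * rel * np.sin(2 * np.pi * model.heart_freq * mult * t)
    if model.noise_sd > 0:
        rng = np.random.default_rng(seed)
        d += rng.normal(0.0, model.noise_sd, size=n)
    return SlowTimeSeries(values=d, rate=rate, units="mm")


# ---------------------------------------------------------------------------
# IF cube simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StaticReflector:
    """A stationary scatterer (furniture, walls) at a fixed range."""

    range: float       # m
    amplitude: float   # relative to the chest return

    def __post_init__(self) -> None:
        if self.range <= 0:
            raise ValueError("reflector range must be positive")


@dataclass
class RadarCube:
    """IF samples indexed [frame, chirp, fast-time sample] plus the config."""

    data: np.ndarray
    config: RadarConfig

    def __post_init__(self) -> None:
        expected = (self.data.shape[0], self.config.chirps_per_frame,
                    self.config.samples_per_chirp)
        if self.data.ndim != 3 or self.data.shape != expected:
            raise ValueError(
                f"cube shape {self.data.shape} does not match config "
                f"(n_frames, {self.config.chirps_per_frame}, "
                f"{self.config.samples_per_chirp})")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("cube contains non-finite samples")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def is_complex(self) -> bool:
        return np.iscomplexobj(self.data)


def simulate_if_cube(config: RadarConfig, displacement: SlowTimeSeries | None,
                     statics: list[StaticReflector] = (),
                     phase_noise_sd: float = 0.0, seed: int = 0,
                     baseline_range: float = 0.5, n_frames: int | None = None,
                     complex_iq: bool = False,
                     target_amplitude: float = 1.0) -> RadarCube:
    """Simulate the IF data cube for a breathing chest plus static clutter.

    Per frame the chest sits at ``R = baseline_range + d(t_frame)``; every
    chirp of that frame sees the tone ``cos(2 pi f_IF t_fast + phi_IF)``
    with ``f_IF = 2 slope R / c`` and ``phi_IF = 4 pi R / lambda``. Each
    static reflector adds the analogous fixed-R term. Optional oscillator
    phase noise draws one Gaussian offset per chirp, common to all returns
    of that chirp.

    ``displacement=None`` simulates a static-only scene (requires
    ``n_frames``).
    """
    if displacement is not None:
        if abs(displacement.rate * config.frame_period - 1.0) > 1e-9:
            raise ValueError("displacement must be sampled at the frame rate")
        if displacement.units != "mm":
            raise ValueError("displacement series must be in mm")
        nf = len(displacement)
        r_target = baseline_range + displacement.values * 1e-3
    else:
        if n_frames is None:
            raise ValueError("n_frames required when no displacement is given")
        nf = n_frames
        r_target = None

    ranges = [r.range for r in statics]
    if r_target is not None:
        ranges.append(baseline_range)
    if ranges and max(ranges) > config.max_unambiguous_range:
        raise ValueError("a reflector lies beyond the unambiguous range "
                         f"({config.max_unambiguous_range:.2f} m)")

    nc, ns = config.chirps_per_frame, config.samples_per_chirp
    t_fast = np.arange(ns) / config.adc_rate
    slope = config.freq_slope
    lam = config.wavelength
    rng = np.random.default_rng(seed)
    noise = (rng.normal(0.0, phase_noise_sd, size=(nf, nc, 1))
             if phase_noise_sd > 0 else None)

    def tone(r):
        """Phase of the IF tone for ranges r (array over frames or scalar)."""
        r = np.atleast_1d(np.asarray(r, dtype=float))[:, None]
        f_if = 2.0 * slope * r / SPEED_OF_LIGHT
        return 2 * np.pi * f_if * t_fast[None, :] + 4 * np.pi * r / lam

    out_dtype = np.complex64 if complex_iq else np.float32
    cube = np.zeros((nf, nc, ns), dtype=out_dtype)
    osc = (lambda ph: np.exp(1j * ph)) if complex_iq else np.cos

    block = max(1, int(2e7 // (nc * ns)))  # bound temporaries to ~tens of MB
    for lo in range(0, nf, block):
        hi = min(lo + block, nf)
        terms = []
        if r_target is not None:
            terms.append((target_amplitude, tone(r_target[lo:hi])[:, None, :]))
        for s in statics:
            terms.append((s.amplitude, tone(s.range)[:, None, :]))
        for amp, ph in terms:
            if noise is not None:
                ph = ph + noise[lo:hi]
            cube[lo:hi] += (amp * osc(ph)).astype(out_dtype)
    return RadarCube(data=cube, config=config)


# ---------------------------------------------------------------------------
# cube container I/O
# ---------------------------------------------------------------------------

def save_cube(cube: RadarCube, path) -> None:
    """Write a cube to an HDF5 container with the config as a JSON attribute."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("if_samples", data=cube.data)
        fh.attrs["radar_config"] = json.dumps(cube.config.to_dict())


def load_cube(path) -> RadarCube:
    with h5py.File(path, "r") as fh:
        data = fh["if_samples"][()]
        config = RadarConfig.from_dict(json.loads(fh.attrs["radar_config"]))
    return RadarCube(data=data, config=config)


def read_raw_int16(path, config: RadarConfig, scale: float = 1.0 / 32768,
                   byteorder: str = "<") -> RadarCube:
    """Import a raw interleaved int16 capture (DCA1000-style streaming dump).

    Layout: little-endian int16 samples ordered fastest-to-slowest as
    [sample within chirp, chirp within frame, frame]; real sampling (one
    int16 per sample). ``scale`` maps ADC counts to the simulator's unit
    amplitude (default: full-scale int16 -> 1.0).
    """
    raw = np.fromfile(path, dtype=np.dtype(byteorder + "i2"))
    per_frame = config.chirps_per_frame * config.samples_per_chirp
    nf = len(raw) // per_frame
    if nf == 0 or len(raw) % per_frame:
        raise ValueError("raw capture length is not a whole number of frames")
    data = (raw[:nf * per_frame].astype(np.float32) * scale).reshape(
        nf, config.chirps_per_frame, config.samples_per_chirp)
    return RadarCube(data=data, config=config)


# ---------------------------------------------------------------------------
# emotion presets and face rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EmotionPreset:
    """Per-emotion sampling boxes for vitals and facial geometry.

    These are synthetic conventions chosen to be separable yet partially
    overlapping, so that no single modality trivially solves the task:
    arousal mostly moves the vitals (angry is fast, relaxed slow) while
    valence mostly moves the face (mouth curvature sign, brow angle).
    """

    label: str
    resp_freq: tuple      # Hz (lo, hi)
    heart_freq: tuple     # Hz (lo, hi)
    resp_amplitude: tuple  # mm (lo, hi)
    heart_amplitude: tuple  # mm (lo, hi)
    mouth_curvature: tuple  # [-1, 1]; + = smile
    brow_angle: tuple       # [-1, 1]; - = knitted/angry
    eye_openness: tuple     # (0, 1]

    def __post_init__(self) -> None:
        if self.label not in EMOTIONS:
            raise ValueError(f"unknown label {self.label!r}")
        for name in ("resp_freq", "heart_freq", "resp_amplitude",
                     "heart_amplitude", "mouth_curvature", "brow_angle",
                     "eye_openness"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} range reversed")


def default_presets() -> dict[str, EmotionPreset]:
    """The four emotion conditions (documented synthetic conventions).

    Heart-rate centres: relaxed ~65 bpm, happy ~75, sad ~70, angry ~95.
    The happy/sad vitals boxes deliberately overlap (valence barely moves
    heart rate) so the face branch carries real information, while
    relaxed/angry separate mainly on arousal (rates).
    """
    # Amplitude boxes keep the worst-case slow-time phase step below ~2.3
    # rad (per-frame step ~ 1.01 * A[mm] * f[Hz] per component at 77 GHz and
    # 20 frames/s), so phase unwrapping never aliases: faster breathing must
    # be shallower, exactly as in real chest motion.
    presets = {
        "relaxed": EmotionPreset(
            "relaxed", resp_freq=(0.15, 0.22), heart_freq=(1.00, 1.15),
            resp_amplitude=(3.5, 5.0), heart_amplitude=(0.25, 0.35),
            mouth_curvature=(0.05, 0.25), brow_angle=(-0.05, 0.10),
            eye_openness=(0.45, 0.65)),
        "happy": EmotionPreset(
            "happy", resp_freq=(0.24, 0.32), heart_freq=(1.17, 1.33),
            resp_amplitude=(2.0, 3.2), heart_amplitude=(0.20, 0.30),
            mouth_curvature=(0.55, 0.95), brow_angle=(0.10, 0.35),
            eye_openness=(0.60, 0.90)),
        "sad": EmotionPreset(
            "sad", resp_freq=(0.20, 0.28), heart_freq=(1.08, 1.25),
            resp_amplitude=(1.2, 2.0), heart_amplitude=(0.18, 0.28),
            mouth_curvature=(-0.95, -0.55), brow_angle=(-0.35, -0.10),
            eye_openness=(0.25, 0.45)),
        "angry": EmotionPreset(
            "angry", resp_freq=(0.38, 0.50), heart_freq=(1.50, 1.70),
            resp_amplitude=(1.2, 2.0), heart_amplitude=(0.20, 0.30),
            mouth_curvature=(-0.40, -0.10), brow_angle=(-0.70, -0.40),
            eye_openness=(0.70, 1.00)),
    }
    boxes = [(p.resp_freq, p.heart_freq) for p in presets.values()]
    assert len({b for b in boxes}) == 4, "preset boxes must be pairwise distinct"
    return presets


_BG_COLOR = (52, 56, 64)
_FACE_COLOR = (208, 172, 140)
_FEATURE_COLOR = (40, 28, 22)


def render_face_frames(preset: EmotionPreset, n_frames: int, size: int = 227,
                       seed: int = 0, jitter: float = 1.0) -> np.ndarray:
    """Draw a procedural face sequence; returns uint8 array (n, size, size, 3).

    The face is an ellipse on a dark background with two eyes (openness sets
    their height), two brows (angled lines) and a mouth arc whose curvature
    sign follows the preset. Geometry is sampled once per sequence from the
    preset ranges; ``jitter`` adds small per-frame translations and feature
    noise (0 -> all frames pixel-identical).
    """
    if n_frames < 11:
        raise ValueError("need at least 11 frames (one keyframe window)")
    rng = np.random.default_rng(seed)
    curv = rng.uniform(*preset.mouth_curvature)
    brow = rng.uniform(*preset.brow_angle)
    eye = rng.uniform(*preset.eye_openness)

    frames = np.empty((n_frames, size, size, 3), dtype=np.uint8)
    for i in range(n_frames):
        dx = rng.normal(0, jitter) if jitter > 0 else 0.0
        dy = rng.normal(0, jitter) if jitter > 0 else 0.0
        c = curv + (rng.normal(0, 0.02 * jitter) if jitter > 0 else 0.0)
        frames[i] = _draw_face(size, dx, dy, c, brow, eye)
    return frames


def _draw_face(size: int, dx: float, dy: float, curv: float, brow: float,
               eye: float) -> np.ndarray:
    img = Image.new("RGB", (size, size), _BG_COLOR)
    draw = ImageDraw.Draw(img)
    s = size / 227.0
    cx, cy = size / 2 + dx, size / 2 + dy
    rx, ry = 75 * s, 95 * s
    draw.ellipse([cx - rx, cy - ry, cx + rx, cy + ry], fill=_FACE_COLOR)

    # eyes: width fixed, height scales with openness
    ew, eh = 18 * s, max(2.0, 14 * s * eye)
    for sx in (-1, 1):
        ex, ey = cx + sx * 32 * s, cy - 22 * s
        draw.ellipse([ex - ew, ey - eh, ex + ew, ey + eh], fill=(245, 245, 245))
        pr = min(6 * s, eh * 0.8)
        draw.ellipse([ex - pr, ey - pr, ex + pr, ey + pr], fill=_FEATURE_COLOR)
        # brow: angle sign is mirrored between sides; negative = knitted inward
        bx0, bx1 = ex - ew, ex + ew
        by = ey - eh - 12 * s
        tilt = -sx * brow * 10 * s
        draw.line([bx0, by + tilt, bx1, by - tilt], fill=_FEATURE_COLOR,
                  width=max(2, int(4 * s)))

    # mouth: parabola, positive curvature = corners above centre (smile)
    mw, my = 40 * s, cy + 48 * s
    u = np.linspace(-1.0, 1.0, 25)
    pts = [(cx + ui * mw, my + curv * 18 * s * (ui * ui - 0.5)) for ui in u]
    draw.line(pts, fill=_FEATURE_COLOR, width=max(2, int(5 * s)))
    return np.asarray(img, dtype=np.uint8)


# ---------------------------------------------------------------------------
# labeled dataset
# ---------------------------------------------------------------------------

@dataclass
class TrialSample:
    """One labeled synthetic trial and its ground truth."""

    sample_id: str
    label: str
    cube: RadarCube
    face_frames: np.ndarray
    resp_freq_true: float   # Hz
    heart_freq_true: float  # Hz
    subject_id: int
    seed: int


def make_dataset(n_per_class: int, config: RadarConfig | None = None,
                 presets: dict[str, EmotionPreset] | None = None,
                 seed: int = 0, duration: float = 60.0,
                 noise_sd: float = 0.05, phase_noise_sd: float = 0.02,
                 n_face_frames: int = 32, face_size: int = 227,
                 n_subjects: int = 5,
                 statics: list[StaticReflector] | None = None) -> list[TrialSample]:
    """Generate a balanced labeled collection of synthetic trials.

    Each sample draws its true respiration/heartbeat frequencies from its
    preset box around a subject-specific operating point (subjects differ in
    baseline physiology, which is what makes person-independent evaluation
    harder than person-dependent). Deterministic for a fixed seed.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    config = config if config is not None else reduced_profile()
    presets = presets if presets is not None else default_presets()
    if statics is None:
        statics = [StaticReflector(range=0.9, amplitude=1.5)]
    rng = np.random.default_rng(seed)
    rate = config.frame_rate

    # per-subject physiological operating point: a shift of each preset box
    subj_shift = rng.uniform(-0.3, 0.3, size=n_subjects)

    samples: list[TrialSample] = []
    for label in EMOTIONS:
        p = presets[label]
        for i in range(n_per_class):
            subject = int((len(samples)) % n_subjects)
            trial_seed = int(rng.integers(0, 2**31 - 1))
            trng = np.random.default_rng(trial_seed)

            def draw(box, shift):
                lo, hi = box
                mid = 0.5 * (lo + hi) + shift * (hi - lo)
                val = mid + trng.uniform(-0.25, 0.25) * (hi - lo)
                return float(np.clip(val, lo, hi))

            sh = subj_shift[subject]
            model = DisplacementModel(
                resp_amplitude=draw(p.resp_amplitude, 0.0),
                resp_freq=draw(p.resp_freq, sh),
                heart_amplitude=draw(p.heart_amplitude, 0.0),
                heart_freq=draw(p.heart_freq, sh),
                noise_sd=noise_sd)
            disp = make_displacement(model, duration, rate, seed=trial_seed)
            cube = simulate_if_cube(
                config, disp, statics=statics, phase_noise_sd=phase_noise_sd,
                seed=trial_seed + 1, baseline_range=model.baseline_range)
            faces = render_face_frames(p, n_face_frames, size=face_size,
                                       seed=trial_seed + 2)
            samples.append(TrialSample(
                sample_id=f"{label}_{i:04d}", label=label, cube=cube,
                face_frames=faces, resp_freq_true=model.resp_freq,
                heart_freq_true=model.heart_freq, subject_id=subject,
                seed=trial_seed))
    return samples


def save_dataset(samples: list[TrialSample], out_dir) -> None:
    """Write cubes (HDF5), face frames (PNG) and a CSV manifest to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in samples:
        save_cube(s.cube, out / f"{s.sample_id}.h5")
        frame_dir = out / f"{s.sample_id}_frames"
        frame_dir.mkdir(exist_ok=True)
        for j in range(s.face_frames.shape[0]):
            Image.fromarray(s.face_frames[j]).save(frame_dir / f"frame_{j:05d}.png")
        rows.append(dict(sample_id=s.sample_id, label=s.label,
                         resp_freq_true=s.resp_freq_true,
                         heart_freq_true=s.heart_freq_true,
                         subject_id=s.subject_id, seed=s.seed))
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)


def load_dataset(in_dir) -> list[TrialSample]:
    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "manifest.csv")
    samples = []
    for _, row in manifest.iterrows():
        cube = load_cube(in_dir / f"{row.sample_id}.h5")
        frame_dir = in_dir / f"{row.sample_id}_frames"
        paths = sorted(frame_dir.glob("frame_*.png"))
        frames = np.stack([np.asarray(Image.open(p).convert("RGB")) for p in paths])
        samples.append(TrialSample(
            sample_id=row.sample_id, label=row.label, cube=cube,
            face_frames=frames, resp_freq_true=row.resp_freq_true,
            heart_freq_true=row.heart_freq_true,
            subject_id=int(row.subject_id), seed=int(row.seed)))
    return samples
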