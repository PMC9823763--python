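"""Radar signal processing: from IF cube to chest-displacement series.

Processing chain: moving-target indication (MTI) to suppress static clutter,
fast-time FFT for range profiles, target-bin selection, per-frame phase
extraction and unwrapping, phase-to-displacement conversion, and a
fourth-order zero-phase Butterworth low-pass at 3.3 Hz (the upper edge of the
heartbeat band).

A note on phase sensitivity: the beat phase measured at the range-FFT peak
is referenced to the centroid of the (symmetric) fast-time window, so it
carries both the carrier term 4*pi*R/lambda and a dechirp term
2*pi*f_IF*t_c with t_c the window centroid time. Both are linear in R, so
the measured sensitivity is (4*pi/lambda) * (1 + slope*t_c*lambda/c).
``dechirp_sensitivity_factor`` computes the closed-form correction that
``phase_to_displacement`` can apply so recovered displacement is unbiased.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from .synthgen import SPEED_OF_LIGHT, RadarConfig, RadarCube, SlowTimeSeries

__all__ = [
    "RangeProfileStack", "LowSNRWarning", "mti_filter", "range_fft",
    "select_target_bin", "extract_phase", "unwrap_phase",
    "phase_to_displacement", "lowpass", "dechirp_sensitivity_factor",
    "extract_displacement", "SlowTimeSeries",
]


class LowSNRWarning(UserWarning):
    """Raised (as a warning) when a spectrum has no clear dominant peak."""


# ---------------------------------------------------------------------------
# MTI static clutter removal
# ---------------------------------------------------------------------------

def mti_filter(cube: RadarCube, window_n: int = 20) -> RadarCube:
    """Suppress slow-time-constant (static) content with sliding-window MTI.

    For each fast-time position, every window of ``window_n`` consecutive
    frames yields (sample - window mean) for the samples it covers; a
    sample's output is the average of those values over all windows that
    contain it. Static returns are constant over slow time and map to ~0,
    while a moving target keeps its zero-mean waveform.
    """
    nf = cube.n_frames
    if window_n < 2:
        raise ValueError("window_n must be >= 2")
    if window_n > nf:
        raise ValueError(f"window_n={window_n} exceeds the {nf}-frame cube")

    x = cube.data.reshape(nf, -1).astype(
        np.complex128 if cube.is_complex else np.float64)
    n_win = nf - window_n + 1
    # window means via cumulative sum along slow time
    csum = np.vstack([np.zeros((1, x.shape[1]), dtype=x.dtype), np.cumsum(x, axis=0)])
    wmeans = (csum[window_n:] - csum[:-window_n]) / window_n  # (n_win, ...)
    # sample i is covered by windows w in [max(0, i-window_n+1), min(i, n_win-1)]
    mcsum = np.vstack([np.zeros((1, x.shape[1]), dtype=x.dtype),
                       np.cumsum(wmeans, axis=0)])
    idx = np.arange(nf)
    w_lo = np.maximum(0, idx - window_n + 1)
    w_hi = np.minimum(idx, n_win - 1)
    cover = (w_hi - w_lo + 1).astype(float)[:, None]
    mean_of_means = (mcsum[w_hi + 1] - mcsum[w_lo]) / cover
    out = (x - mean_of_means).reshape(cube.data.shape)
    return RadarCube(data=out.astype(cube.data.dtype), config=cube.config)


# ---------------------------------------------------------------------------
# range FFT
# ---------------------------------------------------------------------------

@dataclass
class RangeProfileStack:
    """Complex range spectra per frame plus the bin-to-range scale."""

    spectra: np.ndarray     # (n_frames, n_range_bins), complex
    bin_scale: float        # m per bin
    config: RadarConfig
    window_centroid: float  # fast-time centroid of the FFT window, s

    @property
    def n_frames(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_bins(self) -> int:
        return self.spectra.shape[1]

    def bin_to_range(self, b: int) -> float:
        return b * self.bin_scale


def range_fft(cube: RadarCube, chirp_reduction: str = "mean",
              window: str = "hann") -> RangeProfileStack:
    """Per-frame fast-time FFT into range profiles.

    Chirps within a frame are reduced first (``mean`` raises SNR by the
    chirp count; ``first`` keeps a single chirp), a Hann window is applied
    along fast time, and the FFT is taken (one-sided for real input).
    """
    if chirp_reduction not in ("first", "mean"):
        raise ValueError("chirp_reduction must be 'first' or 'mean'")
    x = cube.data[:, 0, :] if chirp_reduction == "first" else cube.data.mean(axis=1)
    ns = cube.config.samples_per_chirp
    if window == "hann":
        w = sp_signal.windows.hann(ns, sym=True)
    elif window == "rect" or window is None:
        w = np.ones(ns)
    else:
        raise ValueError(f"unknown window {window!r}")
    xw = x * w
    spectra = np.fft.fft(xw, axis=1) if cube.is_complex else np.fft.rfft(xw, axis=1)
    # bin b sits at fast-time frequency b*adc_rate/ns -> range via f = 2*slope*R/c
    bin_scale = (cube.config.adc_rate / ns) * SPEED_OF_LIGHT / (2 * cube.config.freq_slope)
    centroid = (ns - 1) / (2.0 * cube.config.adc_rate)
    return RangeProfileStack(spectra=spectra, bin_scale=bin_scale,
                             config=cube.config, window_centroid=centroid)


def expected_target_bin(config: RadarConfig, r: float) -> int:
    """Closed-form range bin for a reflector at range r."""
    f_if = 2.0 * config.freq_slope * r / SPEED_OF_LIGHT
    return int(round(f_if / config.adc_rate * config.samples_per_chirp))


def select_target_bin(stack: RangeProfileStack, snr_threshold: float = 5.0) -> int:
    """Bin with the largest mean magnitude across frames (ties -> lowest bin).

    Run this on MTI-filtered data so static returns do not win. Emits a
    ``LowSNRWarning`` when the winning bin does not clearly dominate the
    median bin power (pure-noise or static-only input).
    """
    mag = np.abs(stack.spectra).mean(axis=0)
    mag = mag.copy()
    mag[0] = 0.0  # DC holds residual offsets, never a physical target here
    best = int(np.argmax(mag))
    med = np.median(mag[1:])
    if med <= 0 or mag[best] < snr_threshold * med:
        warnings.warn("no dominant range bin: low SNR or static-only scene",
                      LowSNRWarning, stacklevel=2)
    return best


# ---------------------------------------------------------------------------
# phase pipeline
# ---------------------------------------------------------------------------

def extract_phase(stack: RangeProfileStack, bin_index: int) -> SlowTimeSeries:
    """Per-frame complex argument at the chosen range bin, wrapped to (-pi, pi]."""
    if not (0 <= bin_index < stack.n_bins):
        raise ValueError("bin index out of range")
    ph = np.angle(stack.spectra[:, bin_index])
    return SlowTimeSeries(values=ph, rate=stack.config.frame_rate, units="rad")


def unwrap_phase(series: SlowTimeSeries) -> SlowTimeSeries:
    """Undo 2*pi wraps: successive jumps larger than pi are folded back."""
    if series.units != "rad":
        raise ValueError("unwrap expects a radian series")
    return SlowTimeSeries(values=np.unwrap(series.values), rate=series.rate,
                          units="rad")


def dechirp_sensitivity_factor(config: RadarConfig,
                               window_centroid: float | None = None) -> float:
    """Correction for the range-dependent dechirp term in the measured phase.

    Measured phase per metre = 4*pi/lambda + 4*pi*slope*t_c/c; dividing the
    naive lambda/(4*pi) conversion by (1 + slope*t_c*lambda/c) removes the
    bias exactly (the term is linear in R).
    """
    if window_centroid is None:
        window_centroid = (config.samples_per_chirp - 1) / (2.0 * config.adc_rate)
    return 1.0 / (1.0 + config.freq_slope * window_centroid
                  * config.wavelength / SPEED_OF_LIGHT)


def phase_to_displacement(series: SlowTimeSeries, wavelength: float,
                          sensitivity_correction: float = 1.0) -> SlowTimeSeries:
    """Convert unwrapped phase to relative displacement in mm.

    d = lambda * phi / (4*pi), mean removed. ``sensitivity_correction``
    (see ``dechirp_sensitivity_factor``) rescales for the dechirp term when
    the phase came from a fast-time FFT peak.
    """
    if series.units != "rad":
        raise ValueError("phase_to_displacement expects a radian series")
    d = wavelength * series.values / (4 * np.pi) * sensitivity_correction
    d = (d - d.mean()) * 1e3
    return SlowTimeSeries(values=d, rate=series.rate, units="mm")


def lowpass(series: SlowTimeSeries, order: int = 4,
            cutoff: float = 3.3) -> SlowTimeSeries:
    """Zero-phase (forward-backward) Butterworth low-pass."""
    nyq = series.rate / 2.0
    if cutoff >= nyq:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist {nyq} Hz")
    sos = sp_signal.butter(order, cutoff, btype="low", fs=series.rate,
                           output="sos")
    out = sp_signal.sosfiltfilt(sos, series.values)
    return SlowTimeSeries(values=out, rate=series.rate, units=series.units)


# ---------------------------------------------------------------------------
# convenience chain
# ---------------------------------------------------------------------------

def extract_displacement(cube: RadarCube, mti_window: int = 20,
                         chirp_reduction: str = "mean",
                         lowpass_cutoff: float | None = 3.3,
                         correct_dechirp: bool = True) -> SlowTimeSeries:
    """Full chain: MTI -> range FFT -> bin -> phase -> unwrap -> displacement.

    The target bin is chosen on the MTI-filtered stack; the phase is then
    read from the unfiltered stack at that bin (MTI would distort the
    complex rotation itself), which is safe because bin selection already
    rejected static-only bins.
    """
    filtered = mti_filter(cube, window_n=min(mti_window, cube.n_frames))
    stack_mti = range_fft(filtered, chirp_reduction=chirp_reduction)
    b = select_target_bin(stack_mti)
    stack = range_fft(cube, chirp_reduction=chirp_reduction)
    phase = unwrap_phase(extract_phase(stack, b))
    corr = (dechirp_sensitivity_factor(cube.config, stack.window_centroid)
            if correct_dechirp else 1.0)
    disp = phase_to_displacement(phase, cube.config.wavelength,
                                 sensitivity_correction=corr)
    if lowpass_cutoff is not None and lowpass_cutoff < disp.rate / 2:
        disp = lowpass(disp, cutoff=lowpass_cutoff)
    return disp
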