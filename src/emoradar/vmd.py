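"""Variational mode decomposition (VMD) and vital-sign reconstruction.

VMD decomposes a signal into k band-limited intrinsic mode functions (IMFs)
u_k with center frequencies omega_k by minimizing the summed bandwidth of
the analytic, baseband-demodulated modes subject to (soft) reconstruction.
The ADMM-style solver alternates, entirely in the frequency domain:

  u_hat_k <- (f_hat - sum_{i != k} u_hat_i + lambda_hat / 2)
             / (1 + 2 * alpha * (omega - omega_k)^2)          (Wiener filter)
  omega_k <- (integral omega |u_hat_k|^2) / (integral |u_hat_k|^2)
                                                  (power-weighted centroid)
  lambda_hat <- lambda_hat + tau * (f_hat - sum_k u_hat_k)      (dual ascent)

until the relative mode update falls below ``tol``. Respiration is then the
sum of modes whose mean instantaneous frequency lies in [0.1, 0.6] Hz,
heartbeat the sum over [0.8, 3.3] Hz, and rates come from the FFT peak of
each reconstruction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .synthgen import SlowTimeSeries

RESP_BAND = (0.1, 0.6)    # Hz, closed interval
HEART_BAND = (0.8, 3.3)   # Hz, closed interval


@dataclass
class VMDParams:
    """Solver parameters.

    alpha is the quadratic bandwidth penalty (larger -> narrower modes);
    tau the dual-ascent step (0 disables the exact-reconstruction constraint,
    which is the noise-robust choice); tol the convergence threshold on the
    summed relative mode update.
    """

    k: int = 3
    alpha: float = 2000.0
    tau: float = 0.0
    tol: float = 1e-7
    max_iter: int = 500
    dc_mode: bool = False

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.alpha <= 0 or self.tol <= 0 or self.max_iter < 1:
            raise ValueError("alpha, tol must be positive; max_iter >= 1")


@dataclass
class IMFSet:
    """VMD result: k modes, their center frequencies, and convergence info."""

    modes: np.ndarray          # (k, n) time-domain modes, ascending omega
    center_freqs: np.ndarray   # (k,) Hz, ascending
    rate: float                # Hz
    n_iterations: int
    final_update_norm: float
    converged: bool

    @property
    def k(self) -> int:
        return self.modes.shape[0]

    def reconstruction(self) -> np.ndarray:
        return self.modes.sum(axis=0)

    def to_csv(self, path) -> None:
        header = ("# center_freqs_hz: "
                  + ",".join(f"{f:.6g}" for f in self.center_freqs)
                  + f"\n# rate_hz: {self.rate}\n")
        cols = ",".join(f"imf{i + 1}" for i in range(self.k))
        with open(path, "w") as fh:
            fh.write(header)
            fh.write(cols + "\n")
            np.savetxt(fh, self.modes.T, delimiter=",", fmt="%.9g")


@dataclass
class VitalSigns:
    """Reconstructed waveforms and per-minute rates."""

    respiration: SlowTimeSeries
    heartbeat: SlowTimeSeries
    breathing_rate: float   # breaths/min
    heart_rate: float       # beats/min

    def __post_init__(self) -> None:
        if not (6.0 <= self.breathing_rate <= 36.0):
            raise ValueError(f"breathing rate {self.breathing_rate} outside [6, 36]")
        if not (48.0 <= self.heart_rate <= 198.0):
            raise ValueError(f"heart rate {self.heart_rate} outside [48, 198]")


# ---------------------------------------------------------------------------
# core solver
# ---------------------------------------------------------------------------

def _init_omegas(k: int, dc_mode: bool) -> np.ndarray:
    """Uniform initial centers over (0, 0.25] cycles/sample (rate/4 in Hz)."""
    om = (np.arange(1, k + 1) / k) * 0.25
    if dc_mode:
        om[0] = 0.0
    return om


def vmd_decompose(signal: SlowTimeSeries, params: VMDParams,
                  init_omegas: np.ndarray | None = None) -> IMFSet:
    """Decompose a slow-time series into k IMFs (see module docstring).

    The input is mirror-extended by half its length on both sides before the
    frequency-domain updates and cropped afterwards, the standard guard
    against edge ringing. Modes are returned sorted by ascending center
    frequency. Non-convergence at max_iter is reported via ``converged``,
    not an exception.
    """
    x = np.asarray(signal.values, dtype=float)
    n0 = len(x)
    if n0 < 8 * params.k:
        raise ValueError(f"signal length {n0} < 8*k = {8 * params.k}")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal must be finite")

    # mirror extension by half the length on each side
    half = n0 // 2
    xe = np.concatenate([x[:half][::-1], x, x[-half:][::-1]] if half else [x])
    n = len(xe)

    freqs = np.fft.fftfreq(n)            # cycles/sample, in (-0.5, 0.5]
    f_hat = np.fft.fft(xe)
    f_hat_plus = f_hat.copy()
    f_hat_plus[freqs < 0] = 0.0          # analytic signal spectrum

    k = params.k
    alpha, tau = params.alpha, params.tau
    u_hat = np.zeros((k, n), dtype=complex)
    lam_hat = np.zeros(n, dtype=complex)
    if init_omegas is None:
        omegas = _init_omegas(k, params.dc_mode)
    else:
        omegas = np.asarray(init_omegas, dtype=float).copy()
        if omegas.shape != (k,):
            raise ValueError("init_omegas must have shape (k,)")

    pos = freqs >= 0
    n_iter = 0
    update = np.inf
    for n_iter in range(1, params.max_iter + 1):
        u_prev = u_hat.copy()
        for i in range(k):
            others = np.zeros(n, dtype=complex)
            for i2 in range(k):
                if i2 != i:
                    others += u_hat[i2]
            u_hat[i] = (f_hat_plus - others + lam_hat / 2.0) / (
                1.0 + 2.0 * alpha * (freqs - omegas[i]) ** 2)
            u_hat[i, ~pos] = 0.0
            power = np.abs(u_hat[i, pos]) ** 2
            tot = power.sum()
            if tot > 0 and not (params.dc_mode and i == 0):
                omegas[i] = float((freqs[pos] * power).sum() / tot)
        if tau != 0.0:
            lam_hat = lam_hat + tau * (f_hat_plus - u_hat.sum(axis=0))
        num = np.abs(u_hat - u_prev) ** 2
        den = np.abs(u_prev) ** 2
        denom = den.sum(axis=1)
        denom[denom == 0] = np.finfo(float).eps
        update = float((num.sum(axis=1) / denom).sum())
        if update < params.tol:
            break
    converged = update < params.tol

    # back to time domain: restore Hermitian symmetry, invert, crop mirror
    modes = np.empty((k, n0))
    for i in range(k):
        full = u_hat[i] + np.conj(u_hat[i][np.r_[0, n - 1:0:-1]])
        full[freqs == 0] = u_hat[i][freqs == 0].real  # DC counted once
        m = np.fft.ifft(full).real
        modes[i] = m[half:half + n0]

    order = np.argsort(omegas)
    return IMFSet(modes=modes[order], center_freqs=omegas[order] * signal.rate,
                  rate=signal.rate, n_iterations=n_iter,
                  final_update_norm=update, converged=converged)


def vmd_decompose_reference(signal: SlowTimeSeries, params: VMDParams,
                            init_omegas: np.ndarray | None = None) -> IMFSet:
    """Naive loop transcription of the update equations (oracle, O(k n) per
    iteration with explicit Python loops over frequency bins).

    Kept deliberately un-vectorized and independent of ``vmd_decompose`` so
    the two can be compared; use only on short signals.
    """
    x = np.asarray(signal.values, dtype=float)
    n0 = len(x)
    half = n0 // 2
    xe = np.concatenate([x[:half][::-1], x, x[-half:][::-1]] if half else [x])
    n = len(xe)
    freqs = np.fft.fftfreq(n)
    f_hat = np.fft.fft(xe)
    f_hat_plus = np.array([0.0 if freqs[j] < 0 else f_hat[j] for j in range(n)],
                          dtype=complex)
    k = params.k
    u_hat = [[0j] * n for _ in range(k)]
    lam_hat = [0j] * n
    omegas = list(_init_omegas(k, params.dc_mode) if init_omegas is None
                  else np.asarray(init_omegas, float))

    n_iter = 0
    update = float("inf")
    for n_iter in range(1, params.max_iter + 1):
        u_prev = [row[:] for row in u_hat]
        for i in range(k):
            for j in range(n):
                if freqs[j] < 0:
                    u_hat[i][j] = 0j
                    continue
                others = 0j
                for i2 in range(k):
                    if i2 != i:
                        others += u_hat[i2][j]
                u_hat[i][j] = (f_hat_plus[j] - others + lam_hat[j] / 2.0) / (
                    1.0 + 2.0 * params.alpha * (freqs[j] - omegas[i]) ** 2)
            num = 0.0
            den = 0.0
            for j in range(n):
                if freqs[j] >= 0:
                    p = abs(u_hat[i][j]) ** 2
                    num += freqs[j] * p
                    den += p
            if den > 0 and not (params.dc_mode and i == 0):
                omegas[i] = num / den
        if params.tau != 0.0:
            for j in range(n):
                tot = 0j
                for i in range(k):
                    tot += u_hat[i][j]
                lam_hat[j] = lam_hat[j] + params.tau * (f_hat_plus[j] - tot)
        update = 0.0
        for i in range(k):
            num = 0.0
            den = 0.0
            for j in range(n):
                num += abs(u_hat[i][j] - u_prev[i][j]) ** 2
                den += abs(u_prev[i][j]) ** 2
            update += num / (den if den > 0 else np.finfo(float).eps)
        if update < params.tol:
            break

    modes = np.empty((k, n0))
    for i in range(k):
        row = np.asarray(u_hat[i], dtype=complex)
        full = row + np.conj(row[np.r_[0, n - 1:0:-1]])
        full[freqs == 0] = row[freqs == 0].real
        modes[i] = np.fft.ifft(full).real[half:half + n0]
    omegas = np.asarray(omegas)
    order = np.argsort(omegas)
    return IMFSet(modes=modes[order], center_freqs=omegas[order] * signal.rate,
                  rate=signal.rate, n_iterations=n_iter,
                  final_update_norm=update, converged=update < params.tol)


# ---------------------------------------------------------------------------
# mode-count selection
# ---------------------------------------------------------------------------

def select_k(signal: SlowTimeSeries, k_range=range(1, 7),
             params: VMDParams | None = None, ratio_limit: float = 0.9,
             stability_rtol: float = 0.1, min_energy: float = 0.05) -> int:
    """Choose the mode count k.

    A candidate k is rejected as over-decomposed when any adjacent
    (ascending) pair of center frequencies has min/max ratio above
    ``ratio_limit`` — two modes then share one spectral component. It is
    rejected as unstable when re-running the decomposition from a permuted
    (reversed) initialization moves any sorted center by more than
    ``stability_rtol`` relative, or when a mode carries less than
    ``min_energy`` of the total mode energy (a spurious mode fed only by
    spectral leakage). The largest surviving k is returned.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("k_range is empty")
    base = params if params is not None else VMDParams()

    def over_decomposed(freqs: np.ndarray) -> bool:
        for a, b in zip(freqs[:-1], freqs[1:]):
            hi = max(a, b)
            if hi > 0 and min(a, b) / hi > ratio_limit:
                return True
        return False

    floor = signal.rate * 1e-3
    best = None
    for k in ks:
        p = VMDParams(k=k, alpha=base.alpha, tau=base.tau, tol=base.tol,
                      max_iter=base.max_iter, dc_mode=base.dc_mode)
        res = vmd_decompose(signal, p)
        alt = vmd_decompose(signal, p,
                            init_omegas=_init_omegas(k, p.dc_mode)[::-1].copy())
        if over_decomposed(res.center_freqs) or over_decomposed(alt.center_freqs):
            continue
        ref = np.maximum(np.abs(res.center_freqs), floor)
        if np.any(np.abs(res.center_freqs - alt.center_freqs) / ref
                  > stability_rtol):
            continue
        energy = (res.modes ** 2).sum(axis=1)
        tot = energy.sum()
        if tot > 0 and np.any(energy / tot < min_energy):
            continue
        best = k
    if best is None:
        best = ks[0]
    return best


# ---------------------------------------------------------------------------
# IMF labeling and band reconstruction
# ---------------------------------------------------------------------------

def mean_instantaneous_frequency(mode: np.ndarray, rate: float,
                                 trim: float = 0.05) -> float:
    """Mean instantaneous frequency of one mode via the analytic signal.

    IF(t) = d(phase)/dt / (2*pi) from the unwrapped Hilbert phase; the mean
    is taken over the central (1 - 2*trim) of samples to discard Hilbert
    edge artefacts.
    """
    mode = np.asarray(mode, dtype=float)
    if np.allclose(mode, mode[0]):
        return 0.0
    phase = np.unwrap(np.angle(hilbert(mode)))
    inst = np.gradient(phase) * rate / (2 * np.pi)
    lo = int(len(mode) * trim)
    hi = len(mode) - lo
    return float(inst[lo:hi].mean())


def reconstruct_band(imfs: IMFSet, band: tuple[float, float],
                     rate: float | None = None) -> SlowTimeSeries:
    """Sum the modes whose mean instantaneous frequency lies in [lo, hi]."""
    rate = rate if rate is not None else imfs.rate
    lo, hi = band
    picked = [m for m in imfs.modes
              if lo <= mean_instantaneous_frequency(m, rate) <= hi]
    if not picked:
        warnings.warn(f"no IMF with mean instantaneous frequency in "
                      f"[{lo}, {hi}] Hz; returning zeros", UserWarning,
                      stacklevel=2)
        values = np.zeros(imfs.modes.shape[1])
    else:
        values = np.sum(picked, axis=0)
    return SlowTimeSeries(values=values, rate=rate, units="a.u.")


def estimate_rate(signal: SlowTimeSeries, search_band: tuple[float, float],
                  zero_pad: int = 8, snr_threshold: float = 4.0) -> float:
    """Per-minute rate from the zero-padded FFT magnitude peak in a band.

    The peak is refined by quadratic interpolation over the three bins
    around the maximum. A flat spectrum (no clear peak above the band's
    median) triggers a ``LowSNRWarning`` but still returns the peak.
    """
    from .radar import LowSNRWarning

    x = np.asarray(signal.values, dtype=float)
    x = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(max(len(x), 2))) * zero_pad)
    spec = np.abs(np.fft.rfft(x, n=nfft))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / signal.rate)
    lo, hi = search_band
    mask = (freqs >= lo) & (freqs <= hi)
    if not mask.any():
        raise ValueError("search band contains no FFT bins")
    idx = np.flatnonzero(mask)
    p = idx[np.argmax(spec[idx])]
    med = np.median(spec[idx])
    if med > 0 and spec[p] < snr_threshold * med:
        warnings.warn("no dominant spectral peak in the search band",
                      LowSNRWarning, stacklevel=2)
    # parabolic refinement around the peak
    f = freqs[p]
    if 0 < p < len(spec) - 1:
        a, b, c = spec[p - 1], spec[p], spec[p + 1]
        denom = a - 2 * b + c
        if denom != 0:
            delta = 0.5 * (a - c) / denom
            f = freqs[p] + np.clip(delta, -1, 1) * (freqs[1] - freqs[0])
    return float(f * 60.0)


def extract_vital_signs(displacement: SlowTimeSeries,
                        params: VMDParams | None = None,
                        k: int | None = None) -> VitalSigns:
    """Displacement -> VMD -> band reconstructions -> rates."""
    base = params if params is not None else VMDParams()
    if k is not None:
        base = VMDParams(k=k, alpha=base.alpha, tau=base.tau, tol=base.tol,
                         max_iter=base.max_iter, dc_mode=base.dc_mode)
    imfs = vmd_decompose(displacement, base)
    resp = reconstruct_band(imfs, RESP_BAND)
    heart = reconstruct_band(imfs, HEART_BAND)
    br = estimate_rate(resp, RESP_BAND)
    hr = estimate_rate(heart, HEART_BAND)
    return VitalSigns(respiration=resp, heartbeat=heart,
                      breathing_rate=br, heart_rate=hr)


def fit_r2(estimates, references) -> float:
    """Coefficient of determination of the OLS line of estimates on references."""
    y = np.asarray(estimates, dtype=float)
    x = np.asarray(references, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("estimates and references must be 1-D and equal length")
    if np.ptp(x) == 0:
        raise ValueError("references are constant; R^2 is undefined")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return 1.0 - ss_res / ss_tot
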