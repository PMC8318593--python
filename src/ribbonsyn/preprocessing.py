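"""Preprocessing of dual-colour fluorescence recordings.

Turns raw indicator-space traces into the model's calcium-input /
glutamate-target pair: linear baseline correction, z-scoring to the
UV-bright stimulus intervals (where calcium channels are closed, so the
bright-interval fluctuations define the noise scale), Butterworth denoising,
Wiener deconvolution of the calcium indicator, and a non-negativity shift of
the glutamate trace. Also provides exponential rise/decay quantification for
calcium-only recordings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.optimize import curve_fit

from .calcium import KernelSpec
from .traces import IntervalSet, Trace


def baseline_correct_linear(trace: Trace) -> Trace:
    """Remove a least-squares linear trend, preserving the mean."""
    if len(trace) < 10:
        raise ValueError("need at least 10 samples for baseline correction")
    x = trace.values
    if np.ptp(x) == 0:
        return trace.with_values(x.copy())
    t = trace.time
    slope, intercept = np.polyfit(t, x, 1)
    line = slope * t + intercept
    return trace.with_values(x - line + x.mean())


def zscore_to_bright(trace: Trace, intervals: IntervalSet) -> Trace:
    """Z-score with respect to the UV-bright stimulus intervals."""
    mask = intervals.bright_mask(trace)
    if mask.sum() < 20:
        raise ValueError("need >= 20 samples inside bright intervals")
    mu = trace.values[mask].mean()
    sd = trace.values[mask].std()
    if sd <= 0:
        raise ValueError("flat recording: zero variance in bright intervals")
    return trace.with_values((trace.values - mu) / sd)


def denoise_butterworth(trace: Trace, order: int = 3,
                        cutoff: float = 5.0) -> Trace:
    """Zero-phase Butterworth low-pass (applied forward-backward).

    Zero-phase filtering avoids introducing a lag between the paired calcium
    and glutamate traces, which the model would otherwise absorb into its
    kinetic parameters.
    """
    nyq = trace.fs / 2.0
    if cutoff >= nyq:
        raise ValueError(f"cutoff {cutoff} Hz >= Nyquist {nyq} Hz")
    sos = signal.butter(order, cutoff, fs=trace.fs, output="sos")
    return trace.with_values(signal.sosfiltfilt(sos, trace.values))


def indicator_kernel(tau: float, dt: float) -> KernelSpec:
    """Unit-area single-exponential indicator impulse response."""
    if tau <= 0 or dt <= 0:
        raise ValueError("tau and dt must be > 0")
    n = max(3, int(np.ceil(8.0 * tau / dt)))
    h = np.exp(-dt * np.arange(n) / tau)
    return KernelSpec(h / (h.sum() * dt), dt, "double_exponential")


def wiener_deconvolve_indicator(trace: Trace, kernel: KernelSpec,
                                snr_low: float = 10.0,
                                snr_high: float = 1.0 / 20.0,
                                f_cross: float = 1.0) -> Trace:
    """Wiener deconvolution of the indicator kernel.

    The filter is H*(f) / (|H(f)|^2 + 1/SNR(f)) with a piecewise-constant
    SNR profile: ``snr_low`` below ``f_cross`` (default 10 below 1 Hz) and
    ``snr_high`` above (default 1/20). Pass ``snr_low=snr_high=np.inf`` for
    exact inverse filtering of noiseless data.
    """
    if not np.any(kernel.values):
        raise ValueError("kernel is identically zero")
    n = len(trace)
    nfft = int(2 ** np.ceil(np.log2(n + len(kernel.values))))
    H = np.fft.rfft(kernel.values * kernel.dt, nfft)
    freqs = np.fft.rfftfreq(nfft, trace.dt)
    snr = np.where(freqs < f_cross, snr_low, snr_high)
    with np.errstate(divide="ignore"):
        G = np.conj(H) / (np.abs(H) ** 2 + 1.0 / snr)
    X = np.fft.rfft(trace.values, nfft)
    out = np.fft.irfft(X * G, nfft)[:n]
    return trace.with_values(out)


def shift_nonnegative(trace: Trace) -> Trace:
    """Shift so that the minimum is exactly zero."""
    return trace.with_values(trace.values - trace.values.min())


@dataclass
class ExpFit:
    """Parameters of f(t) = c + a*exp(-t/tau) fitted to a trace segment."""

    c: float
    a: float
    tau: float
    is_rise: bool
    residual: float

    def __call__(self, t):
        return self.c + self.a * np.exp(-np.asarray(t, float) / self.tau)


def fit_exponential(t: np.ndarray, x: np.ndarray,
                    tau_max: float = 100.0) -> ExpFit:
    """Least-squares fit of c + a*exp(-t/tau); t is re-zeroed internally.

    Falls back to a log-linear fit of the de-offset data when the nonlinear
    optimiser fails. ``is_rise`` is true when the fitted curve increases
    with time (a < 0).
    """
    t = np.asarray(t, float)
    x = np.asarray(x, float)
    t0 = t - t[0]
    span = x.max() - x.min()
    if span == 0:
        return ExpFit(float(x[0]), 0.0, tau_max, False, 0.0)
    rising = x[-1] > x[0]
    p0 = (x[-1], (x[0] - x[-1]), max(t0[-1] / 3.0, 1e-3))

    def f(tt, c, a, tau):
        return c + a * np.exp(-tt / tau)

    try:
        popt, _ = curve_fit(f, t0, x, p0=p0, maxfev=2000,
                            bounds=([-np.inf, -np.inf, 1e-4],
                                    [np.inf, np.inf, tau_max]))
        c, a, tau = popt
        resid = float(np.sqrt(np.mean((f(t0, *popt) - x) ** 2)))
    except RuntimeError:
        # log-linear fallback on the de-offset magnitude
        c = x[-1] if not rising else x[0]
        y = np.abs(x - c) + 1e-12
        slope, logb = np.polyfit(t0, np.log(y), 1)
        tau = min(tau_max, -1.0 / slope) if slope < 0 else tau_max
        a = (1.0 if not rising else -1.0) * np.exp(logb)
        resid = float(np.sqrt(np.mean((c + a * np.exp(-t0 / tau) - x) ** 2)))
    return ExpFit(float(c), float(a), float(tau), bool(a < 0), resid)


def smooth_boxcar(trace: Trace, window: float = 0.1) -> Trace:
    """Sliding-average smoothing with the given window length in seconds."""
    w = max(1, int(round(window / trace.dt)))
    kernel = np.ones(w) / w
    padded = np.pad(trace.values, (w // 2, w - 1 - w // 2), mode="edge")
    return trace.with_values(np.convolve(padded, kernel, mode="valid"))


def fit_rise_decay(trace: Trace, event_start: float, event_peak: float,
                   event_end: float):
    """Quantify rise/decay kinetics of a flash response.

    The trace is boxcar-smoothed (100 ms); an exponential is fitted to the
    rise segment [event_start, event_peak] and to the decay segment
    [event_peak, event_end]. The response delay is the first time the
    smoothed trace exceeds 3x the standard deviation of the whole trace;
    ``None`` if it never does.
    """
    sm = smooth_boxcar(trace, 0.1)
    thr = 3.0 * np.std(sm.values)
    above = np.flatnonzero(sm.values > thr)
    delay = float(sm.time[above[0]]) if above.size else None
    idx_r = sm.window_index(event_start, event_peak)
    idx_d = sm.window_index(event_peak, event_end)
    if idx_r.size < 3 or idx_d.size < 3:
        raise ValueError("event windows too short for exponential fits")
    fit_r = fit_exponential(sm.time[idx_r], sm.values[idx_r])
    fit_d = fit_exponential(sm.time[idx_d], sm.values[idx_d])
    return fit_r, fit_d, delay


def preprocess_pair(ca_raw: Trace, glu_raw: Trace, intervals: IntervalSet,
                    indicator_tau: float = 0.25,
                    model_dt: float = 0.01) -> tuple[Trace, Trace]:
    """Full chain from raw fluorescence to the model's (calcium, glutamate).

    Calcium: linear baseline correction -> bright-interval z-score ->
    Butterworth denoise -> Wiener deconvolution of the indicator kernel.
    Glutamate: bright-interval z-score -> Butterworth denoise ->
    non-negativity shift. Both are resampled to the (finer) model grid by
    linear interpolation before filtering.
    """
    ca = baseline_correct_linear(ca_raw)
    ca = zscore_to_bright(ca, intervals)
    ca = ca.resample(model_dt)
    ca = denoise_butterworth(ca)
    ca = wiener_deconvolve_indicator(
        ca, indicator_kernel(indicator_tau, model_dt))
    ca.kind = "calcium"

    glu = zscore_to_bright(glu_raw, intervals)
    glu = glu.resample(model_dt)
    glu = denoise_butterworth(glu)
    glu = shift_nonnegative(glu)
    glu.kind = "glutamate"
    return ca, glu
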