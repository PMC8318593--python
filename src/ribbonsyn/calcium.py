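"""Linear light-to-calcium cascade for the generalised ribbon model.

The calcium concentration evoked by a light stimulus s(t) is modelled as

    Ca(t) = gain * ( kappa2 * exp(kappa1 * s(t)) ) + offset

where ``*`` denotes causal convolution, kappa1 is a biphasic (band-pass)
phototransduction kernel and kappa2 a non-negative double-exponential kernel
describing the calcium kinetics (rise time fixed at 30 ms, decay time the
tunable parameter). With the OFF-polarity sign convention used for cone
photoreceptors, a light decrement increases calcium and hence release.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .traces import Trace


@dataclass(frozen=True)
class KernelSpec:
    """A discretised convolution kernel with its grid spacing."""

    values: np.ndarray
    dt: float
    kind: str  # "biphasic" | "double_exponential"

    @property
    def support(self) -> float:
        return self.dt * len(self.values)

    @property
    def area(self) -> float:
        return float(np.sum(self.values) * self.dt)


def make_double_exp_kernel(tau_decay: float, tau_rise: float = 0.030,
                           dt: float = 0.01) -> KernelSpec:
    """Unit-area double-exponential kernel exp(-t/tau_d) - exp(-t/tau_r).

    Non-negative and unimodal for tau_decay > tau_rise; in the limit
    tau_decay -> tau_rise it degenerates to the alpha function t*exp(-t/tau).
    Support is truncated at 8*tau_decay.
    """
    if not (tau_decay > 0 and tau_rise > 0 and dt > 0):
        raise ValueError("time constants and dt must be > 0")
    n = max(3, int(np.ceil(8.0 * max(tau_decay, tau_rise) / dt)))
    t = dt * np.arange(n)
    if abs(tau_decay - tau_rise) < 1e-9 * tau_rise:
        h = t * np.exp(-t / tau_rise)
    else:
        h = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
    h = np.clip(h, 0.0, None)
    area = h.sum() * dt
    if area <= 0:
        raise ValueError("degenerate kernel")
    return KernelSpec(h / area, dt, "double_exponential")


def _gamma_lobe(t: np.ndarray, tau: float, shape: int = 3) -> np.ndarray:
    # unit-area gamma-shaped lobe peaking near tau
    h = (t / tau) ** (shape - 1) * np.exp(-shape * (t / tau - 1.0))
    return h / h.sum()


def make_biphasic_kernel(tau_fast: float = 0.060, tau_slow: float = 0.180,
                         dt: float = 0.01, amplitude: float = 1.0,
                         off_polarity: bool = True) -> KernelSpec:
    """Zero-net-area biphasic phototransduction kernel.

    Built as the difference of two unit-area gamma-shaped lobes (fast and
    slow); the exact kernel of the upstream cone cascade is not prescribed
    here, so the lobe time constants are configurable and a measured kernel
    can be substituted via :class:`KernelSpec`. With ``off_polarity`` the
    fast lobe is negative so that light decrements drive the output up.
    """
    if not (0 < tau_fast < tau_slow):
        raise ValueError("require 0 < tau_fast < tau_slow")
    n = int(np.ceil(8.0 * tau_slow / dt))
    t = dt * np.arange(n)
    fast = _gamma_lobe(t, tau_fast)
    slow = _gamma_lobe(t, tau_slow)
    h = (slow - fast) if off_polarity else (fast - slow)
    h = amplitude * h / dt  # lobes normalised in discrete sum; net area 0
    return KernelSpec(h, dt, "biphasic")


def convolve_causal(x: np.ndarray, kernel: KernelSpec,
                    pad_initial: bool = False) -> np.ndarray:
    """Causal discrete convolution (zero-order hold), truncated to len(x).

    With ``pad_initial`` the input is extended into the past with its first
    value for the kernel support, so the output starts in the adapted state
    instead of carrying an onset transient.
    """
    if pad_initial:
        npad = len(kernel.values)
        xp = np.concatenate([np.full(npad, x[0]), x])
        return np.convolve(xp, kernel.values)[npad: npad + len(x)] * kernel.dt
    return np.convolve(x, kernel.values)[: len(x)] * kernel.dt


def light_to_calcium(stimulus: Trace, kappa1: KernelSpec,
                     kappa2: KernelSpec, gain: float = 1.0,
                     offset: float = 0.0,
                     pad_initial: bool = True) -> Trace:
    """Map a light stimulus to a calcium trace on the same grid.

    With ``pad_initial`` (default) the stimulus is assumed to have been at
    its initial value for all earlier times, so the cascade starts adapted;
    otherwise the first ``max(kernel support)`` seconds carry the
    convolution onset transient.
    """
    for kap in (kappa1, kappa2):
        if abs(kap.dt - stimulus.dt) > 1e-12:
            raise ValueError("kernel grid spacing must match the stimulus")
    drive = convolve_causal(stimulus.values, kappa1, pad_initial=pad_initial)
    ca = convolve_causal(np.exp(drive), kappa2, pad_initial=pad_initial)
    return Trace(gain * ca + offset, dt=stimulus.dt, t0=stimulus.t0,
                 kind="calcium")


def calibrate_affine(raw: np.ndarray, lo: float = 0.0,
                     hi: float = 1.0) -> tuple[float, float]:
    """(gain, offset) mapping the range of ``raw`` onto [lo, hi].

    The calcium-unit scale is arbitrary; this pins the span of a reference
    stimulus response to a conventional range so that x0 values are
    comparable across configurations.
    """
    rmin, rmax = float(np.min(raw)), float(np.max(raw))
    if rmax - rmin < 1e-12:
        return 1.0, lo - rmin
    gain = (hi - lo) / (rmax - rmin)
    return gain, lo - gain * rmin
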