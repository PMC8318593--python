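"""Standard light-stimulus protocols.

All stimuli are contrast traces in [0, 1] (0 = dark, 1 = full UV brightness)
on a uniform fine grid; noise stimuli are piecewise constant, updated at the
stated rate (zero-order hold).
"""

from __future__ import annotations

import numpy as np

from .traces import IntervalSet, Trace


def make_flash_protocol(n_flashes: int = 3, dt: float = 0.01,
                        adaptation: float = 5.0, on: float = 3.0,
                        off: float = 3.0, background: float = 0.5
                        ) -> tuple[Trace, IntervalSet]:
    """Adaptation at 50% contrast followed by 3 s ON / 3 s OFF full flashes.

    Returns the stimulus trace and the interval annotations (adaptation,
    UV-bright and UV-dark windows). With the defaults and ``n_flashes=3``
    the protocol lasts 5 + 3*6 = 23 s and the first dark onset is at 8 s.
    """
    if n_flashes < 1:
        raise ValueError("need at least one flash")
    total = adaptation + n_flashes * (on + off)
    n = int(round(total / dt)) + 1
    t = dt * np.arange(n)
    s = np.full(n, background)
    bright, dark = [], []
    for j in range(n_flashes):
        b0 = adaptation + j * (on + off)
        d0 = b0 + on
        bright.append((b0, d0))
        dark.append((d0, d0 + off))
        s[(t >= b0 - 1e-12) & (t < d0 - 1e-12)] = 1.0
        s[(t >= d0 - 1e-12) & (t < d0 + off - 1e-12)] = 0.0
    return (Trace(s, dt=dt, kind="stimulus"),
            IntervalSet((0.0, adaptation), bright, dark))


def _zoh_noise(draws: np.ndarray, rate: float, duration: float,
               dt: float) -> np.ndarray:
    hold = max(1, int(round(1.0 / (rate * dt))))
    n = int(round(duration / dt)) + 1
    return np.repeat(draws, hold)[:n]


def gaussian_noise_stimulus(duration: float = 150.0, rate: float = 2.0,
                            mu: float = 0.5, sigma: float = 0.3,
                            dt: float = 0.01, rng=None,
                            event_time: float | None = None,
                            event_amp: float = 0.0,
                            event_duration: float = 0.5) -> Trace:
    """Gaussian contrast noise, optionally with an embedded step event.

    The event replaces the noise with ``mu + event_amp`` for
    ``event_duration`` seconds starting at ``event_time`` (an off-event is
    ``event_amp = -4*sigma``, an on-event ``+4*sigma``).
    """
    rng = np.random.default_rng(rng)
    n_draws = int(np.ceil(duration * rate)) + 1
    vals = _zoh_noise(mu + sigma * rng.standard_normal(n_draws),
                      rate, duration, dt)
    if event_time is not None:
        t = dt * np.arange(vals.size)
        m = (t >= event_time) & (t < event_time + event_duration)
        vals[m] = mu + event_amp
    return Trace(vals, dt=dt, kind="stimulus")


def uniform_noise_stimulus(duration: float = 100.0, rate: float = 20.0,
                           dt: float = 0.01, rng=None) -> Trace:
    """Uniform [0, 1] contrast noise at the given update rate."""
    rng = np.random.default_rng(rng)
    n_draws = int(np.ceil(duration * rate)) + 1
    vals = _zoh_noise(rng.uniform(0.0, 1.0, n_draws), rate, duration, dt)
    return Trace(vals, dt=dt, kind="stimulus")
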