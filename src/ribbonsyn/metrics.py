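"""Response indices characterising synaptic tuning.

* max / sustain / transience of flash responses (90th / 50th percentiles of
  the first and last second of each dark period; transience =
  (max - sustain)/max, 0 for a fully sustained and ~1 for a fully transient
  response),
* off- and on-event detection indices (z-scored response amplitude to a
  +/-4 sigma, 500 ms contrast event embedded in 2 Hz Gaussian noise),
* the high-frequency index HFi (frequency-weighted sum of the Welch power
  spectrum below 25 Hz of the std-normalised response to 20 Hz uniform
  noise).

Indices that are undefined for a degenerate output (flat trace, max <= 0)
are reported as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .protocols import gaussian_noise_stimulus, uniform_noise_stimulus
from .traces import Trace

#: Welch settings used for HFi (segment length in seconds, overlap fraction).
WELCH_SEGMENT_S = 10.0
WELCH_OVERLAP = 0.5


@dataclass
class FlashIndices:
    max_per_flash: np.ndarray
    sustain_per_flash: np.ndarray

    @property
    def max(self) -> float:
        return float(self.max_per_flash.mean())

    @property
    def sustain(self) -> float:
        return float(self.sustain_per_flash.mean())

    @property
    def transience(self) -> float:
        if self.max <= 0:
            return float("nan")
        return (self.max - self.sustain) / self.max

    def transience_flash(self, j: int) -> float:
        """Transience of a single flash (the first is often analysed alone)."""
        m = self.max_per_flash[j]
        return float("nan") if m <= 0 else float(
            (m - self.sustain_per_flash[j]) / m)


def max_sustain_transience(x: Trace, dark_windows,
                           window: float = 1.0) -> FlashIndices:
    """Percentile-based flash-response indices.

    For each dark window, max is the 90th percentile over the first
    ``window`` seconds after dark onset and sustain the 50th percentile over
    the last ``window`` seconds of the dark period.
    """
    mx, su = [], []
    for (a, b) in dark_windows:
        first = x.slice(a, min(a + window, b))
        last = x.slice(max(b - window, a), b)
        if first.size == 0 or last.size == 0:
            raise ValueError("dark window outside trace span")
        mx.append(np.percentile(first, 90))
        su.append(np.percentile(last, 50))
    return FlashIndices(np.array(mx), np.array(su))


def detection_indices(model, seed: int, mu: float = 0.5, sigma: float = 0.3,
                      duration: float = 150.0, event_time: float = 120.0,
                      t0: float = 60.0, n_realisations: int = 1
                      ) -> tuple[float, float]:
    """Off- and on-event detection indices of a light-response model.

    Two runs of the same 2 Hz Gaussian noise stimulus are made, one with a
    -4 sigma (dark) and one with a +4 sigma (bright) 500 ms event at
    ``event_time``. With x the model output restricted to [t0, duration]:

        I_off = (max(x) - mean(x)) / std(x)   from the dark-event run,
        I_on  = |min(x) - mean(x)| / std(x)   from the bright-event run.

    A single stimulus realisation per seed is used by default;
    ``n_realisations > 1`` averages the indices over independent draws.
    """
    offs, ons = [], []
    for j in range(n_realisations):
        rng_seed = seed + 7919 * j
        vals = []
        for amp in (-4.0 * sigma, +4.0 * sigma):
            stim = gaussian_noise_stimulus(
                duration=duration, mu=mu, sigma=sigma,
                rng=np.random.default_rng(rng_seed),
                event_time=event_time, event_amp=amp)
            out = model(stim)
            seg = out.slice(t0, duration)
            sd = seg.std()
            if sd <= 0:
                vals.append(float("nan"))
            elif amp < 0:
                vals.append((seg.max() - seg.mean()) / sd)
            else:
                vals.append(abs(seg.min() - seg.mean()) / sd)
        offs.append(vals[0])
        ons.append(vals[1])
    return float(np.mean(offs)), float(np.mean(ons))


def high_frequency_index(model, seed: int, duration: float = 100.0,
                         f_max: float = 25.0) -> float:
    """Frequency-weighted spectral sum of the response to fast flicker.

    HFi = sum_i p_i * f_i over Welch power-spectrum bins with f_i < f_max,
    computed on the standard-deviation-normalised model response to 100 s of
    uniform noise updated at 20 Hz.
    """
    stim = uniform_noise_stimulus(duration=duration,
                                  rng=np.random.default_rng(seed))
    out = model(stim)
    sd = out.values.std()
    if sd <= 0:
        return float("nan")
    nperseg = int(round(WELCH_SEGMENT_S / out.dt))
    if len(out) < nperseg:
        raise ValueError("output shorter than one Welch segment")
    f, p = signal.welch(out.values / sd, fs=out.fs, nperseg=nperseg,
                        noverlap=int(WELCH_OVERLAP * nperseg),
                        window="hann")
    keep = f < f_max
    return float(np.sum(p[keep] * f[keep]))


@dataclass
class IndexReport:
    """All indices of one model configuration, with the windows used."""

    max_activation: float
    sustain: float
    transience: float
    I_off: float
    I_on: float
    HFi: float
    windows: dict

    def as_dict(self) -> dict:
        return {"max_activation": self.max_activation,
                "sustain": self.sustain, "transience": self.transience,
                "I_off": self.I_off, "I_on": self.I_on, "HFi": self.HFi,
                "windows": self.windows}


def index_report(model, dark_windows, flash_response: Trace,
                 seed: int = 0) -> IndexReport:
    """Convenience battery: flash indices plus stimulus-driven indices."""
    fi = max_sustain_transience(flash_response, dark_windows)
    i_off, i_on = detection_indices(model, seed)
    hfi = high_frequency_index(model, seed)
    return IndexReport(
        fi.max, fi.sustain, fi.transience, i_off, i_on, hfi,
        windows={"max": "first 1 s of dark", "sustain": "last 1 s of dark",
                 "detection": "[60 s, 150 s]",
                 "welch": f"{WELCH_SEGMENT_S:g} s Hann, 50% overlap"})
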