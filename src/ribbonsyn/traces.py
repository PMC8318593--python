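"""Uniformly sampled time series used throughout the package.

A :class:`Trace` is the common currency between the stimulus generator, the
light-to-calcium cascade, the release model and the preprocessing chain. It is
deliberately minimal: a value array, a grid spacing ``dt``, a start time and a
``kind`` tag (``stimulus``, ``calcium``, ``glutamate`` or ``release``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

KINDS = ("stimulus", "calcium", "glutamate", "release", "fluorescence")


@dataclass
class Trace:
    """A uniformly sampled time series.

    Parameters
    ----------
    values : ndarray
        Sample values (contrast, calcium units, vesicle units/s, ...).
    dt : float
        Grid spacing in seconds, > 0.
    t0 : float
        Time of the first sample in seconds.
    kind : str
        One of ``stimulus | calcium | glutamate | release | fluorescence``.
    """

    values: np.ndarray
    dt: float
    t0: float = 0.0
    kind: str = "stimulus"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("trace needs a 1-D value array of length >= 2")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")
        if not (self.dt > 0):
            raise ValueError("dt must be > 0")
        if self.kind not in KINDS:
            raise ValueError(f"unknown trace kind {self.kind!r}")

    @property
    def time(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.values.size)

    @property
    def duration(self) -> float:
        return self.dt * (self.values.size - 1)

    @property
    def fs(self) -> float:
        """Sampling rate in Hz."""
        return 1.0 / self.dt

    def __len__(self) -> int:
        return self.values.size

    def with_values(self, values: np.ndarray, kind: str | None = None) -> "Trace":
        """Copy of this trace with new values on the same grid."""
        return replace(self, values=np.asarray(values, float),
                       kind=self.kind if kind is None else kind)

    def slice(self, t_start: float, t_stop: float) -> np.ndarray:
        """Values with t_start <= t < t_stop (half-open window)."""
        idx = self.window_index(t_start, t_stop)
        return self.values[idx]

    def window_index(self, t_start: float, t_stop: float) -> np.ndarray:
        t = self.time
        return np.flatnonzero((t >= t_start - 1e-12) & (t < t_stop - 1e-12))

    def resample(self, dt: float) -> "Trace":
        """Linear-interpolation resample onto a new uniform grid."""
        n = int(np.floor(self.duration / dt)) + 1
        t_new = self.t0 + dt * np.arange(n)
        vals = np.interp(t_new, self.time, self.values)
        return Trace(vals, dt=dt, t0=self.t0, kind=self.kind)

    # -- I/O: two-column CSV plus a JSON sidecar with the metadata ---------
    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        pd.DataFrame({"time_s": self.time, "value": self.values}).to_csv(
            path, index=False)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(
            {"kind": self.kind, "dt": self.dt, "t0": self.t0}))

    @classmethod
    def from_csv(cls, path: str | Path) -> "Trace":
        path = Path(path)
        df = pd.read_csv(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            dt, t0, kind = meta["dt"], meta["t0"], meta["kind"]
        else:
            t = df["time_s"].to_numpy()
            dt, t0, kind = float(t[1] - t[0]), float(t[0]), "stimulus"
        return cls(df["value"].to_numpy(), dt=dt, t0=t0, kind=kind)


@dataclass
class IntervalSet:
    """Stimulus interval annotations of a flash protocol.

    ``adaptation`` is a single (start, stop) pair; ``bright`` and ``dark`` are
    lists of pairs, one per flash. All times are in seconds, half-open.
    """

    adaptation: tuple[float, float]
    bright: list[tuple[float, float]] = field(default_factory=list)
    dark: list[tuple[float, float]] = field(default_factory=list)

    def validate(self, trace: Trace) -> None:
        span = (trace.t0, trace.t0 + trace.duration + trace.dt)
        ivs = [self.adaptation, *self.bright, *self.dark]
        for a, b in ivs:
            if not (span[0] - 1e-9 <= a < b <= span[1] + 1e-9):
                raise ValueError(f"interval ({a}, {b}) outside trace span {span}")
        for i, (a, b) in enumerate(sorted(ivs)):
            if i and a < sorted(ivs)[i - 1][1] - 1e-9:
                raise ValueError("intervals overlap")

    def bright_mask(self, trace: Trace) -> np.ndarray:
        m = np.zeros(len(trace), dtype=bool)
        for a, b in self.bright:
            m[trace.window_index(a, b)] = True
        return m

    def to_json(self) -> str:
        return json.dumps({"adaptation": self.adaptation,
                           "bright": self.bright, "dark": self.dark})

    @classmethod
    def from_json(cls, s: str) -> "IntervalSet":
        d = json.loads(s)
        return cls(tuple(d["adaptation"]),
                   [tuple(x) for x in d["bright"]],
                   [tuple(x) for x in d["dark"]])
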