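"""Statistical linear baseline: ridge regression from lagged calcium.

Predicts the glutamate release at each time point from the past 0.5 s of the
calcium trace with L2-regularised least squares (alpha = 0.1). This is the
reference against which the biophysical model's fit quality is compared; a
purely linear read-out reproduces the broad shape of flash responses but
misses the transient components that the pool dynamics generate.
"""

from __future__ import annotations

import numpy as np
from sklearn.linear_model import Ridge
from sklearn.preprocessing import StandardScaler

from .traces import Trace


class RidgeBaseline:
    """Ridge fit of glutamate on a 0.5 s causal calcium history.

    Features are standardised before penalisation and the intercept is
    unpenalised. Columns of the design run oldest-to-newest, so
    ``self.kernel`` (original units, newest lag last) is directly comparable
    to a causal convolution kernel sampled on the trace grid.
    """

    def __init__(self, window: float = 0.5, alpha: float = 0.1):
        self.window = window
        self.alpha = alpha
        self.scaler: StandardScaler | None = None
        self.ridge: Ridge | None = None
        self.n_lags: int | None = None
        self.dt: float | None = None

    def _design(self, ca: Trace) -> np.ndarray:
        L = self.n_lags
        x = ca.values
        idx = np.arange(L - 1, x.size)
        return np.column_stack([x[idx - (L - 1 - j)] for j in range(L)])

    def fit(self, calcium: Trace, glutamate: Trace) -> "RidgeBaseline":
        if len(calcium) != len(glutamate) or \
                abs(calcium.dt - glutamate.dt) > 1e-12:
            raise ValueError("calcium and glutamate must share one grid")
        self.dt = calcium.dt
        self.n_lags = max(1, int(round(self.window / calcium.dt)) + 1)
        X = self._design(calcium)
        y = glutamate.values[self.n_lags - 1:]
        self.scaler = StandardScaler().fit(X)
        Xs = self.scaler.transform(X)
        self.ridge = Ridge(alpha=self.alpha).fit(Xs, y)
        return self

    def predict(self, calcium: Trace) -> Trace:
        if self.ridge is None:
            raise RuntimeError("fit before predict")
        if abs(calcium.dt - self.dt) > 1e-12:
            raise ValueError("grid spacing differs from the training grid")
        X = self.scaler.transform(self._design(calcium))
        yhat = self.ridge.predict(X)
        # the first window has no full history; hold the first prediction
        pad = np.full(self.n_lags - 1, yhat[0])
        return Trace(np.concatenate([pad, yhat]), dt=calcium.dt,
                     t0=calcium.t0, kind="glutamate")

    @property
    def kernel(self) -> np.ndarray:
        """Fitted weights in original units, oldest lag first."""
        return self.ridge.coef_ / self.scaler.scale_


def fit_ridge_baseline(calcium: Trace, glutamate: Trace,
                       window: float = 0.5,
                       alpha: float = 0.1) -> RidgeBaseline:
    return RidgeBaseline(window=window, alpha=alpha).fit(calcium, glutamate)
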