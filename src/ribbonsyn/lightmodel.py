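"""End-to-end light-to-release model used for index sweeps.

Composes the linear light-to-calcium cascade with the ribbon release model
into a single callable so the response indices (transience, detection
indices, high-frequency index) can be evaluated on arbitrary light stimuli.
The calcium gain/offset is calibrated once, on the flash protocol, so that
the reference response spans a conventional calcium range (default [0, 1]
c.u.); the same affine map is then applied to every stimulus, keeping the
model a fixed, causal system.
"""

from __future__ import annotations

import numpy as np

from .calcium import (calibrate_affine, convolve_causal, light_to_calcium,
                      make_biphasic_kernel, make_double_exp_kernel)
from .model import (RibbonParams, SimplifiedParams, expand_simplified,
                    simulate_release_batch)
from .protocols import make_flash_protocol
from .traces import Trace


class LightResponseModel:
    """Deterministic map from a light stimulus to a release trace."""

    def __init__(self, params: RibbonParams | SimplifiedParams,
                 tau_decay: float | None = None, dt: float = 0.01,
                 ca_range: tuple[float, float] = (0.0, 1.0)):
        if isinstance(params, SimplifiedParams):
            if tau_decay is None:
                tau_decay = params.tau_decay
            params = expand_simplified(params)
        elif tau_decay is None:
            tau_decay = 0.5
        self.params = params
        self.dt = dt
        self.kappa1 = make_biphasic_kernel(dt=dt)
        self.kappa2 = make_double_exp_kernel(tau_decay, dt=dt)
        # calibrate the arbitrary calcium scale on the flash protocol
        ref, _ = make_flash_protocol(n_flashes=2, dt=dt)
        raw = convolve_causal(
            np.exp(convolve_causal(ref.values, self.kappa1,
                                   pad_initial=True)),
            self.kappa2, pad_initial=True)
        settle = ref.window_index(3.0, ref.duration)
        self.gain, self.offset = calibrate_affine(raw[settle], *ca_range)

    def calcium(self, stimulus: Trace) -> Trace:
        return light_to_calcium(stimulus, self.kappa1, self.kappa2,
                                self.gain, self.offset)

    def __call__(self, stimulus: Trace) -> Trace:
        ca = self.calcium(stimulus)
        e = simulate_release_batch(self.params.free[None, :], ca,
                                   RP_max=self.params.RP_max,
                                   d_max=self.params.d_max)[0]
        return Trace(e, dt=ca.dt, t0=ca.t0, kind="release")
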