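"""Synthetic recordings emulating in vivo dual-colour two-photon data.

Generates fully specified "recordings" — stimulus, ground-truth calcium,
ground-truth release and noisy indicator-space fluorescence — so every
pipeline stage can be exercised and validated without the deposited data.
The forward model composes the light-to-calcium cascade and the ribbon
release model with an observation stage: indicator-kernel convolution, an
arbitrary affine scale/offset, a linear baseline drift, resampling to the
15.6 Hz acquisition grid and additive white Gaussian noise. The noise is
additive in fluorescence space because the preprocessing z-scores traces to
the bright-interval fluctuations, which treats those fluctuations as the
noise reference.

Three illustrative zone presets (``az``, ``nasal``, ``dorsal``) realise the
qualitative regional orderings reported for zebrafish UV-cones — the most
transient release dorsally, the largest sustained component and RRP in the
acute zone, and nasally a small RRP whose few vesicles are immediately
released, giving sustained low-amplitude output. They are constructed
parameter bundles, not fitted values.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .calcium import (calibrate_affine, convolve_causal,
                      make_biphasic_kernel, make_double_exp_kernel)
from .model import RibbonParams, simulate_release_batch
from .preprocessing import indicator_kernel
from .protocols import make_flash_protocol
from .traces import IntervalSet, Trace

ZONE_PRESETS: dict[str, RibbonParams] = {
    # acute zone: large RRP and fast refill from a well-stocked IP -> the
    # largest sustained component on top of a transient
    "az": RibbonParams(r_max=5.0, i_max=6.0, e_max=5.0, k=10.2, x0=0.45,
                       IP_max=14.0, RRP_max=8.0),
    # nasal: tiny RRP with the largest release rate and slow refill -> the
    # few releasable vesicles are dumped immediately and the output settles
    # at the refill-limited rate: sustained, low amplitude
    "nasal": RibbonParams(r_max=2.0, i_max=1.0, e_max=30.0, k=10.2, x0=0.6,
                          IP_max=12.0, RRP_max=0.4),
    # dorsal: high release rate draining a mid-sized RRP much faster than
    # the slow refill -> pronounced transient, weak sustain
    "dorsal": RibbonParams(r_max=2.8, i_max=1.0, e_max=12.0, k=10.2, x0=0.5,
                           IP_max=14.0, RRP_max=5.0),
}


@dataclass
class SyntheticStudy:
    """Configuration of a synthetic flash-protocol experiment.

    Defaults mirror the in vivo acquisition: >= 5 s adaptation at 50%
    contrast, 3 s ON / 3 s OFF full-contrast UV flashes, 15.6 Hz recording
    of indicator-convolved fluorescence with linear baseline drift and an
    arbitrary affine scale, while the model runs on a 100 Hz grid.
    """

    n_flashes: int = 3
    dt_model: float = 0.01
    fs_record: float = 15.6
    tau_ca_decay: float = 0.30       # calcium kernel decay [s]
    tau_ca_indicator: float = 0.25   # jRGeco-like indicator [s]
    tau_glu_indicator: float = 0.06  # iGluSnFR-like indicator [s]
    noise_sd: float = 0.1            # fluorescence noise SD
    drift_slope: float = -0.02       # linear baseline drift [1/s], calcium
    ca_affine: tuple[float, float] = (1.5, 0.3)
    glu_affine: tuple[float, float] = (0.8, 0.1)
    params: RibbonParams = field(
        default_factory=lambda: ZONE_PRESETS["dorsal"])
    n_replicates: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("observation noise SD must be > 0")

    def to_json(self) -> str:
        d = asdict(self)
        d["params"] = asdict(self.params)
        return json.dumps(d, indent=2)


@dataclass
class Recording:
    """One synthetic replicate with its lossless ground truth."""

    stimulus: Trace
    intervals: IntervalSet
    ca_true: Trace          # model grid, c.u.
    release_true: Trace     # model grid, v.u./s
    ca_fluo: Trace          # 15.6 Hz observed fluorescence
    glu_fluo: Trace
    params: RibbonParams
    seed: int


def ground_truth_calcium(stimulus: Trace, tau_decay: float,
                         ca_range=(0.0, 1.0)) -> Trace:
    """Light-to-calcium cascade calibrated so the response spans ca_range."""
    kap1 = make_biphasic_kernel(dt=stimulus.dt)
    kap2 = make_double_exp_kernel(tau_decay, dt=stimulus.dt)
    raw = convolve_causal(
        np.exp(convolve_causal(stimulus.values, kap1, pad_initial=True)),
        kap2, pad_initial=True)
    settle = stimulus.window_index(3.0, stimulus.duration)
    gain, offset = calibrate_affine(raw[settle], *ca_range)
    return Trace(gain * raw + offset, dt=stimulus.dt, kind="calcium")


def _observe(truth: Trace, tau_ind: float, affine, drift_slope: float,
             fs_record: float, noise_sd: float, rng) -> Trace:
    kern = indicator_kernel(tau_ind, truth.dt)
    fluo = convolve_causal(truth.values, kern)
    scale, offset = affine
    fluo = scale * fluo + offset + drift_slope * truth.time
    obs = Trace(fluo, dt=truth.dt, t0=truth.t0, kind="fluorescence")
    obs = obs.resample(1.0 / fs_record)
    obs.values = obs.values + noise_sd * rng.standard_normal(len(obs))
    return obs


def generate_recording(study: SyntheticStudy, replicate: int = 0,
                       seed: int | None = None) -> Recording:
    """Generate one replicate; byte-reproducible from (study, replicate)."""
    seed = study.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence((seed, replicate)))
    stim, intervals = make_flash_protocol(study.n_flashes, study.dt_model)
    ca = ground_truth_calcium(stim, study.tau_ca_decay)
    e = simulate_release_batch(study.params.free[None, :], ca,
                               RP_max=study.params.RP_max,
                               d_max=study.params.d_max)[0]
    release = Trace(e, dt=ca.dt, kind="release")
    ca_fluo = _observe(ca, study.tau_ca_indicator, study.ca_affine,
                       study.drift_slope, study.fs_record, study.noise_sd,
                       rng)
    glu_fluo = _observe(release, study.tau_glu_indicator, study.glu_affine,
                        0.0, study.fs_record, study.noise_sd, rng)
    return Recording(stim, intervals, ca, release, ca_fluo, glu_fluo,
                     study.params, seed)


def generate_replicates(study: SyntheticStudy) -> list[Recording]:
    return [generate_recording(study, r) for r in range(study.n_replicates)]
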