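"""Three-pool kinetic model of glutamate release at the ribbon synapse.

Vesicles move through a cascade of three pools — a reserve pool (RP), an
intermediate, ribbon-tethered pool (IP) and a readily releasable pool (RRP) —
before exocytosis. Transfer rates depend on the occupancy of the source pool
and the free capacity of the destination pool; release itself is gated by a
sigmoidal function of the intracellular calcium concentration:

    e(t) = e_max * f(Ca(t)) * RRP(t)/RRP_max,   f(Ca) = 1/(1 + exp(-k*(Ca-x0)))

    r(t) = r_max * (1 - IP/IP_max) * RP/RP_max
    i(t) = i_max * (1 - RRP/RRP_max) * IP/IP_max
    d(t) = d_max * Exo(t)

    dRP/dt = d - r,  dIP/dt = r - i,  dRRP/dt = i - e,  dExo/dt = e - d

Exocytosed vesicles (Exo) are recycled back to the reserve pool at a fixed
endocytosis rate, so the total vesicle count is conserved. The model is scale
invariant: multiplying all rates and capacities (but not the non-linearity
parameters k and x0) by a constant scales the release trace by the same
constant, which is why occupancies are expressed in arbitrary vesicle units
(v.u.) and calcium in calcium units (c.u.).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .traces import Trace

#: Default fixed parameters. The reserve-pool capacity and the endocytosis
#: rate do not affect the release output on tens-of-seconds timescales, so
#: they are held fixed and excluded from inference.
DEFAULT_RP_MAX = 138.0  # 10x the IP_max prior mode
DEFAULT_D_MAX = 0.1     # 1/s

_BOUND_TOL = 1e-6


@dataclass(frozen=True)
class RibbonParams:
    """Kinetic parameters of the release cascade.

    The seven free parameters are (r_max, i_max, e_max, k, x0, IP_max,
    RRP_max); RP_max and d_max are fixed.

    Units: rates in v.u./s, capacities in v.u., k in 1/c.u., x0 in c.u.,
    d_max in 1/s.
    """

    r_max: float
    i_max: float
    e_max: float
    k: float
    x0: float
    IP_max: float
    RRP_max: float
    RP_max: float = DEFAULT_RP_MAX
    d_max: float = DEFAULT_D_MAX

    def __post_init__(self) -> None:
        for name in ("r_max", "i_max", "e_max", "k", "x0", "IP_max",
                     "RRP_max", "RP_max", "d_max"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v}")

    @property
    def free(self) -> np.ndarray:
        """The seven free parameters in canonical order."""
        return np.array([self.r_max, self.i_max, self.e_max, self.k,
                         self.x0, self.IP_max, self.RRP_max])

    @classmethod
    def from_free(cls, theta: np.ndarray, RP_max: float = DEFAULT_RP_MAX,
                  d_max: float = DEFAULT_D_MAX) -> "RibbonParams":
        r, i, e, k, x0, ip, rrp = np.asarray(theta, float)
        return cls(r, i, e, k, x0, ip, rrp, RP_max, d_max)

    @property
    def total_capacity(self) -> float:
        return self.RP_max + self.IP_max + self.RRP_max


@dataclass(frozen=True)
class SimplifiedParams:
    """Reduced parameterisation used for the tuning-rule sweeps.

    The non-linearity slope is fixed (k = 10.2, the mean of the fitted values)
    and the maximal transfer rates are coupled to the pool sizes
    (r_max = 0.2*IP_max, i_max = 0.4*IP_max, e_max = e_tilde_max*RRP_max),
    leaving pool sizes, the release fraction e_tilde_max in [0, 1], the
    calcium offset x0 and the calcium decay time constant as the dials.
    """

    IP_max: float
    RRP_max: float
    e_tilde_max: float
    x0: float
    tau_decay: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.e_tilde_max <= 1.0):
            raise ValueError("e_tilde_max must lie in [0, 1]")
        for name in ("IP_max", "RRP_max", "x0", "tau_decay"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v}")


SIMPLIFIED_K = 10.2


def expand_simplified(sp: SimplifiedParams,
                      RP_max: float | None = None,
                      d_max: float = DEFAULT_D_MAX) -> RibbonParams:
    """Expand the reduced parameterisation to a full parameter set."""
    e_max = sp.e_tilde_max * sp.RRP_max
    if e_max <= 0:
        # RibbonParams requires strictly positive rates; represent "no
        # release" by a negligible rate instead.
        e_max = 1e-300
    return RibbonParams(
        r_max=0.2 * sp.IP_max,
        i_max=0.4 * sp.IP_max,
        e_max=e_max,
        k=SIMPLIFIED_K,
        x0=sp.x0,
        IP_max=sp.IP_max,
        RRP_max=sp.RRP_max,
        RP_max=10.0 * sp.IP_max if RP_max is None else RP_max,
        d_max=d_max,
    )


def scale_params(params: RibbonParams, lam: float) -> RibbonParams:
    """Scale all rates and capacities by ``lam``; k and x0 are untouched.

    By the model's scale invariance the release output of the scaled
    parameter set is ``lam`` times the original, pointwise.
    """
    if not np.isfinite(lam) or lam <= 0:
        raise ValueError("lam must be finite and > 0")
    return replace(params,
                   r_max=lam * params.r_max, i_max=lam * params.i_max,
                   e_max=lam * params.e_max, IP_max=lam * params.IP_max,
                   RRP_max=lam * params.RRP_max, RP_max=lam * params.RP_max)


def release_nonlinearity(ca, k: float, x0: float):
    """Sigmoidal calcium dependence of release, f(Ca) in (0, 1).

    f(x0) = 0.5, so x0 is the operating point: the smaller x0 the less
    additional calcium is needed to trigger release (an inverted baseline).
    """
    if k <= 0:
        raise ValueError("k must be > 0")
    ca = np.asarray(ca, dtype=float)
    if not np.all(np.isfinite(ca)):
        raise ValueError("calcium input must be finite")
    out = 1.0 / (1.0 + np.exp(np.clip(-k * (ca - x0), -700, 700)))
    return float(out) if out.ndim == 0 else out


def pool_fluxes(state, ca: float, params: RibbonParams):
    """Instantaneous fluxes (r, i, e, d) at a pool state (RP, IP, RRP, Exo).

    Raises if an occupancy is negative or above capacity beyond tolerance
    (this signals a solver blow-up rather than a modelling condition).
    """
    RP, IP, RRP, Exo = (float(v) for v in state)
    caps = (params.RP_max, params.IP_max, params.RRP_max, np.inf)
    for v, cap, name in zip((RP, IP, RRP, Exo), caps,
                            ("RP", "IP", "RRP", "Exo")):
        tol = _BOUND_TOL * (cap if np.isfinite(cap) else params.total_capacity)
        if v < -tol or v > cap + tol:
            raise ValueError(f"occupancy {name}={v} outside [0, {cap}]")
    r = params.r_max * (1.0 - IP / params.IP_max) * RP / params.RP_max
    i = params.i_max * (1.0 - RRP / params.RRP_max) * IP / params.IP_max
    e = params.e_max * release_nonlinearity(ca, params.k, params.x0) \
        * RRP / params.RRP_max
    d = params.d_max * Exo
    return r, i, e, d


@dataclass
class PoolTrajectory:
    """Simulated time courses of pool occupancies and fluxes."""

    time: np.ndarray
    RP: np.ndarray
    IP: np.ndarray
    RRP: np.ndarray
    Exo: np.ndarray
    r: np.ndarray
    i: np.ndarray
    e: np.ndarray
    d: np.ndarray
    params: RibbonParams

    @property
    def total(self) -> np.ndarray:
        return self.RP + self.IP + self.RRP + self.Exo

    def release_trace(self) -> Trace:
        dt = float(self.time[1] - self.time[0])
        return Trace(self.e, dt=dt, t0=float(self.time[0]), kind="release")


def steady_state(params: RibbonParams, ca: float,
                 total: float | None = None) -> np.ndarray:
    """Flux-balance fixed point (RP, IP, RRP, Exo) at constant calcium.

    At steady state all four fluxes equal a common throughput J. The solve
    is parameterised by the RRP occupancy fraction x = RRP/RRP_max (which
    stays numerically stable even for vanishing release drive): J = e_max *
    f(ca) * x determines IP, RP and Exo in closed form, and x is found by a
    bracketed root solve of the conservation constraint
    RP+IP+RRP+Exo = total. ``total`` defaults to the full-pool count
    RP_max+IP_max+RRP_max.
    """
    if total is None:
        total = params.total_capacity
    if total < params.IP_max + params.RRP_max:
        raise ValueError("total vesicle count below IP_max + RRP_max")
    f = release_nonlinearity(ca, params.k, params.x0)
    ef = params.e_max * f
    if ef <= 1e-12 * params.i_max:
        # release drive negligible: the RRP deficit at the true fixed point
        # is O(ef/i_max) of RRP_max, far below solver tolerance
        # no release: pools fill completely, surplus sits in the reserve pool
        return np.array([total - params.IP_max - params.RRP_max,
                         params.IP_max, params.RRP_max, 0.0])

    big = 1e18

    def occupancies(x: float) -> np.ndarray:
        J = ef * x
        RRP = x * params.RRP_max
        IP = J * params.IP_max / (params.i_max * (1.0 - x))
        if IP >= params.IP_max:
            return np.array([np.inf, IP, RRP, J / params.d_max])
        RP = J * params.RP_max / (params.r_max * (1.0 - IP / params.IP_max))
        return np.array([RP, IP, RRP, J / params.d_max])

    def residual(x: float) -> float:
        occ = occupancies(x)
        return min(float(occ.sum() - total), big)

    x = brentq(residual, 0.0, 1.0 - 1e-15, xtol=1e-16, rtol=8.9e-16)
    occ = occupancies(x)
    if not np.all(np.isfinite(occ)):
        raise RuntimeError("steady-state solve failed to converge")
    return occ


def _initial_state(params: RibbonParams, ca0: float, init) -> np.ndarray:
    if isinstance(init, str):
        if init == "steady":
            return steady_state(params, ca0)
        if init == "full":
            return np.array([params.RP_max, params.IP_max,
                             params.RRP_max, 0.0])
        raise ValueError(f"unknown init policy {init!r}")
    y0 = np.asarray(init, dtype=float)
    if y0.shape != (4,):
        raise ValueError("explicit initial state must have 4 entries")
    return y0


def _clip_state(y: np.ndarray, params: RibbonParams) -> np.ndarray:
    # numerical guard inside the RHS: keep occupancies physical
    out = np.empty(4)
    out[0] = min(max(y[0], 0.0), params.RP_max)
    out[1] = min(max(y[1], 0.0), params.IP_max)
    out[2] = min(max(y[2], 0.0), params.RRP_max)
    out[3] = max(y[3], 0.0)
    return out


def simulate_release(params: RibbonParams, calcium: Trace,
                     init="steady", rtol: float = 1e-6,
                     atol: float | None = None,
                     max_step: float | None = None) -> PoolTrajectory:
    """Integrate the pool ODEs driven by a calcium trace.

    Uses an explicit adaptive Runge-Kutta of order 3(2) (Bogacki-Shampine)
    with the maximal step size capped at the calcium grid spacing; calcium
    is linearly interpolated between samples. The trajectory is returned on
    the calcium time grid.

    ``atol`` defaults to 1e-11 times the total vesicle capacity: occupancies
    are in arbitrary vesicle units, so the absolute tolerance must follow
    the capacity scale (this also makes the step selection scale-free, so
    the model's scale invariance survives integration exactly).

    ``init`` is ``"steady"`` (default; flux-balance fixed point at the first
    calcium sample, the endpoint of an adaptation burn-in), ``"full"`` (all
    pools full, Exo = 0), or an explicit 4-vector.
    """
    if atol is None:
        atol = 1e-11 * params.total_capacity
    if calcium.kind not in ("calcium", "stimulus"):
        raise ValueError("simulate_release expects a calcium trace")
    t_grid = calcium.time
    ca_vals = calcium.values

    def ca_at(t: float) -> float:
        return float(np.interp(t, t_grid, ca_vals))

    def rhs(t, y):
        yc = _clip_state(y, params)
        r, i, e, d = pool_fluxes(yc, ca_at(t), params)
        return [d - r, r - i, i - e, e - d]

    y0 = _initial_state(params, ca_vals[0], init)
    sol = solve_ivp(rhs, (t_grid[0], t_grid[-1]), y0, method="RK23",
                    t_eval=t_grid, rtol=rtol, atol=atol,
                    max_step=calcium.dt if max_step is None else max_step)
    if not sol.success or not np.all(np.isfinite(sol.y)):
        t_bad = sol.t[-1] if sol.t.size else t_grid[0]
        raise RuntimeError(
            f"ODE integration failed near t={t_bad:.4f}s: {sol.message}")
    RP, IP, RRP, Exo = sol.y
    fCa = release_nonlinearity(ca_vals, params.k, params.x0)
    r = params.r_max * (1 - IP / params.IP_max) * RP / params.RP_max
    i = params.i_max * (1 - RRP / params.RRP_max) * IP / params.IP_max
    e = params.e_max * fCa * np.clip(RRP, 0, None) / params.RRP_max
    d = params.d_max * Exo
    return PoolTrajectory(t_grid, RP, IP, RRP, Exo, r, i, e, d, params)


def simulate_release_euler(params: RibbonParams, calcium: Trace,
                           dt: float = 1e-4, init="steady") -> Trace:
    """Fixed-step forward-Euler reference integration.

    A deliberately simple independent route used to validate the adaptive
    solver; returns the release rate subsampled onto the calcium grid.
    """
    n_sub = max(1, int(round(calcium.dt / dt)))
    h = calcium.dt / n_sub
    t_fine = calcium.t0 + h * np.arange((len(calcium) - 1) * n_sub + 1)
    ca_fine = np.interp(t_fine, calcium.time, calcium.values)
    f_fine = release_nonlinearity(ca_fine, params.k, params.x0)

    rp, ip, rrp, exo = (float(v) for v in
                        _initial_state(params, calcium.values[0], init))
    rmx, imx, emx = params.r_max, params.i_max, params.e_max
    ipm, rrpm, rpm, dmx = params.IP_max, params.RRP_max, params.RP_max, params.d_max
    e_out = np.empty(len(calcium))
    e_out[0] = emx * f_fine[0] * rrp / rrpm
    for j in range(1, t_fine.size):
        f = f_fine[j - 1]
        r = rmx * (1.0 - ip / ipm) * rp / rpm
        i = imx * (1.0 - rrp / rrpm) * ip / ipm
        e = emx * f * rrp / rrpm
        d = dmx * exo
        rp += h * (d - r)
        ip += h * (r - i)
        rrp += h * (i - e)
        exo += h * (e - d)
        if j % n_sub == 0:
            e_out[j // n_sub] = emx * f_fine[j] * rrp / rrpm
    return Trace(e_out, dt=calcium.dt, t0=calcium.t0, kind="release")


# ---------------------------------------------------------------------------
# Vectorised batch simulator
# ---------------------------------------------------------------------------

def simulate_release_batch(theta: np.ndarray, calcium: Trace,
                           RP_max: float = DEFAULT_RP_MAX,
                           d_max: float = DEFAULT_D_MAX,
                           init: str = "steady") -> np.ndarray:
    """Simulate many parameter sets at once on the calcium grid.

    ``theta`` has shape (n, 7) with columns (r_max, i_max, e_max, k, x0,
    IP_max, RRP_max). Integration is a fixed-step Bogacki-Shampine (third
    order) scheme with step equal to the calcium grid spacing, vectorised
    over the batch; pool states are clipped to their physical ranges after
    each step. Returns the release rates, shape (n, len(calcium)).

    This is the workhorse behind inference, sensitivity analysis and the
    parameter sweeps, where tens of thousands of simulations are needed; it
    agrees with :func:`simulate_release` to solver tolerance on the smooth
    inputs used there.
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    if theta.shape[1] != 7:
        raise ValueError("theta must have 7 columns")
    n = theta.shape[0]
    rmx, imx, emx, k, x0, ipm, rrpm = theta.T
    h = calcium.dt
    t = calcium.time
    ca = calcium.values
    # calcium at the RK stage times (linear interpolation, shared across batch)
    ca_half = np.interp(t[:-1] + 0.5 * h, t, ca)
    ca_34 = np.interp(t[:-1] + 0.75 * h, t, ca)

    def sig(c, kk, xx):
        return 1.0 / (1.0 + np.exp(np.clip(-kk * (c - xx), -700, 700)))

    # initial state per batch element
    state = np.empty((4, n))
    if init == "steady":
        for j in range(n):
            p = RibbonParams.from_free(theta[j], RP_max, d_max)
            state[:, j] = steady_state(p, ca[0])
    elif init == "full":
        state[0] = RP_max
        state[1] = ipm
        state[2] = rrpm
        state[3] = 0.0
    else:
        raise ValueError("init must be 'steady' or 'full'")

    def rhs(s, f_ca):
        rp = np.clip(s[0], 0.0, RP_max)
        ip = np.clip(s[1], 0.0, ipm)
        rrp = np.clip(s[2], 0.0, rrpm)
        exo = np.clip(s[3], 0.0, None)
        r = rmx * (1.0 - ip / ipm) * rp / RP_max
        i = imx * (1.0 - rrp / rrpm) * ip / ipm
        e = emx * f_ca * rrp / rrpm
        d = d_max * exo
        return np.stack([d - r, r - i, i - e, e - d])

    out = np.empty((n, t.size))
    out[:, 0] = emx * sig(ca[0], k, x0) * np.clip(state[2], 0, rrpm) / rrpm
    f0 = sig(ca[0], k, x0)
    for j in range(t.size - 1):
        f_half = sig(ca_half[j], k, x0)
        f_34 = sig(ca_34[j], k, x0)
        f1 = sig(ca[j + 1], k, x0)
        k1 = rhs(state, f0)
        k2 = rhs(state + 0.5 * h * k1, f_half)
        k3 = rhs(state + 0.75 * h * k2, f_34)
        state = state + h * (2.0 * k1 + 3.0 * k2 + 4.0 * k3) / 9.0
        # clip to the physical box to keep long runs well-behaved
        np.clip(state[0], 0.0, RP_max, out=state[0])
        np.clip(state[1], 0.0, ipm, out=state[1])
        np.clip(state[2], 0.0, rrpm, out=state[2])
        np.clip(state[3], 0.0, None, out=state[3])
        out[:, j + 1] = emx * f1 * state[2] / rrpm
        f0 = f1
    return out
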