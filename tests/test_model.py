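"""Core release-model behaviour: non-linearity, fluxes, conservation,
scale invariance, steady states and solver agreement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ribbonsyn.model import (RibbonParams, SimplifiedParams,
                             expand_simplified, pool_fluxes,
                             release_nonlinearity, scale_params,
                             simulate_release, simulate_release_batch,
                             simulate_release_euler, steady_state)
from ribbonsyn.traces import Trace


class TestNonlinearity:
    @given(k=st.floats(0.1, 50), x0=st.floats(-2, 2))
    @settings(max_examples=50, deadline=None)
    def test_half_activation_at_offset(self, k, x0):
        assert release_nonlinearity(x0, k, x0) == pytest.approx(0.5)

    def test_sigmoid_limits_and_monotonicity(self):
        ca = np.linspace(-50, 50, 2001)
        f = release_nonlinearity(ca, 10.2, 0.5)
        assert f[0] < 1e-12 and f[-1] > 1 - 1e-12
        assert np.all(np.diff(f) >= 0)
        interior = release_nonlinearity(np.linspace(-3, 3, 601), 10.2, 0.5)
        assert np.all((interior > 0) & (interior < 1))

    def test_closed_form_value(self):
        # direct scalar evaluation of 1/(1+exp(-k(ca-x0)))
        expected = 1.0 / (1.0 + np.exp(-10.2 * (0.7 - 0.5)))
        assert release_nonlinearity(0.7, 10.2, 0.5) == pytest.approx(
            expected, rel=1e-12)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            release_nonlinearity(np.nan, 10.2, 0.5)
        with pytest.raises(ValueError):
            release_nonlinearity(0.5, -1.0, 0.5)


class TestPoolFluxes:
    def test_saturated_boundaries(self, params):
        # full pools, no exocytosed vesicles, calcium far below x0
        state = (params.RP_max, params.IP_max, params.RRP_max, 0.0)
        r, i, e, d = pool_fluxes(state, params.x0 - 10.0, params)
        assert r == 0.0 and i == 0.0 and d == 0.0
        assert e == pytest.approx(0.0, abs=1e-12)

    def test_half_reserve_empty_downstream(self, params):
        state = (params.RP_max / 2, 0.0, 0.0, 0.0)
        r, i, e, d = pool_fluxes(state, 0.5, params)
        assert r == pytest.approx(params.r_max * 0.5)
        assert i == 0.0 and e == 0.0 and d == 0.0

    def test_generic_state_matches_formulas(self, params):
        RP, IP, RRP, Exo = 100.0, 6.0, 1.5, 3.0
        ca = 0.62
        r, i, e, d = pool_fluxes((RP, IP, RRP, Exo), ca, params)
        f = 1 / (1 + np.exp(-params.k * (ca - params.x0)))
        assert r == pytest.approx(
            params.r_max * (1 - IP / params.IP_max) * RP / params.RP_max)
        assert i == pytest.approx(
            params.i_max * (1 - RRP / params.RRP_max) * IP / params.IP_max)
        assert e == pytest.approx(params.e_max * f * RRP / params.RRP_max)
        assert d == pytest.approx(params.d_max * Exo)

    def test_rejects_blown_up_state(self, params):
        with pytest.raises(ValueError):
            pool_fluxes((-1.0, 0.0, 0.0, 0.0), 0.5, params)


class TestSimulate:
    def test_conservation_on_flash_protocol(self, params, flash_calcium):
        traj = simulate_release(params, flash_calcium)
        drift = np.ptp(traj.total) / traj.total[0]
        assert drift < 1e-6

    def test_boundedness(self, params, flash_calcium):
        traj = simulate_release(params, flash_calcium)
        tol = 1e-6
        assert traj.RP.min() > -tol * params.RP_max
        assert traj.RP.max() < params.RP_max * (1 + tol)
        assert traj.IP.max() < params.IP_max * (1 + tol)
        assert traj.RRP.max() < params.RRP_max * (1 + tol)
        assert traj.Exo.min() > -tol * params.total_capacity

    @pytest.mark.parametrize("lam", [0.5, 2.0, 10.0])
    def test_scale_invariance(self, params, flash_calcium, lam):
        e0 = simulate_release(params, flash_calcium).e
        e1 = simulate_release(scale_params(params, lam), flash_calcium).e
        assert np.max(np.abs(e1 - lam * e0)) / np.max(lam * e0) < 1e-6

    def test_scale_params_identity_and_rejection(self, params):
        assert scale_params(params, 1.0) == params
        with pytest.raises(ValueError):
            scale_params(params, 0.0)

    def test_adaptive_matches_euler_oracle(self, params, flash_calcium):
        # 10 s sub-segment, fixed-step Euler at dt=1e-4 as independent route
        ca = Trace(flash_calcium.values[:1001], dt=0.01, kind="calcium")
        e_ad = simulate_release(params, ca).e
        e_eu = simulate_release_euler(params, ca, dt=1e-4).values
        rel = np.max(np.abs(e_ad - e_eu)) / np.max(np.abs(e_eu))
        assert rel < 1e-3

    def test_batch_matches_adaptive(self, params, flash_calcium):
        e_ad = simulate_release(params, flash_calcium).e
        e_b = simulate_release_batch(params.free[None, :], flash_calcium,
                                     RP_max=params.RP_max,
                                     d_max=params.d_max)[0]
        assert np.max(np.abs(e_b - e_ad)) / np.max(e_ad) < 5e-3

    def test_step_calcium_transient_then_relaxation(self, params):
        # step from low to high calcium: RRP drains faster than refill,
        # so release peaks then relaxes
        n = 3001
        vals = np.concatenate([np.full(1000, 0.0), np.full(n - 1000, 1.0)])
        traj = simulate_release(params, Trace(vals, dt=0.01, kind="calcium"))
        post = traj.e[1000:]
        peak = np.argmax(post)
        assert peak < 200  # peak within 2 s of the step
        assert post[peak] > 1.5 * post[-1]  # relaxes well below the peak


class TestSteadyState:
    def test_constant_calcium_converges_to_fixed_point(self, params,
                                                       constant_calcium):
        # slowest relaxation mode is endocytotic recycling (tau = 1/d_max
        # = 10 s), so reach the fixed point needs a couple hundred seconds
        ca_level = 0.6
        fp = steady_state(params, ca_level)
        traj = simulate_release(params, constant_calcium(ca_level, 250.0),
                                init="full")
        final = np.array([traj.RP[-1], traj.IP[-1], traj.RRP[-1],
                          traj.Exo[-1]])
        assert np.max(np.abs(final - fp)) / params.total_capacity < 1e-6

    def test_fixed_point_balances_fluxes(self, params):
        for ca in (0.0, 0.3, 0.5, 0.9, 2.0):
            fp = steady_state(params, ca)
            r, i, e, d = pool_fluxes(fp, ca, params)
            assert max(r, i, e, d) - min(r, i, e, d) < 1e-9 * max(e, 1e-30)

    def test_scaling_halves_fixed_point(self, params):
        fp = steady_state(params, 0.6)
        fp_half = steady_state(scale_params(params, 0.5), 0.6)
        assert np.allclose(fp_half, 0.5 * fp, rtol=1e-9)

    def test_steady_release_monotone_in_calcium(self, params):
        levels = np.linspace(0.0, 1.5, 16)
        rates = []
        for ca in levels:
            fp = steady_state(params, ca)
            rates.append(pool_fluxes(fp, ca, params)[2])
        assert np.all(np.diff(rates) >= -1e-12)


class TestSimplified:
    def test_expansion_coupling(self):
        sp = SimplifiedParams(IP_max=10.0, RRP_max=4.0, e_tilde_max=0.5,
                              x0=0.5)
        p = expand_simplified(sp)
        assert p.r_max == pytest.approx(2.0)
        assert p.i_max == pytest.approx(4.0)
        assert p.e_max == pytest.approx(2.0)
        assert p.k == pytest.approx(10.2)
        assert p.r_max / p.IP_max == pytest.approx(0.2)
        assert p.i_max / p.IP_max == pytest.approx(0.4)

    def test_zero_release_fraction(self, flash_calcium):
        sp = SimplifiedParams(IP_max=10.0, RRP_max=4.0, e_tilde_max=0.0,
                              x0=0.5)
        e = simulate_release(expand_simplified(sp), flash_calcium).e
        assert np.max(np.abs(e)) < 1e-12

    def test_invalid_release_fraction_rejected(self):
        with pytest.raises(ValueError):
            SimplifiedParams(IP_max=10.0, RRP_max=4.0, e_tilde_max=1.5,
                             x0=0.5)
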