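"""Summary statistics and the weighted relevant loss."""

import numpy as np
import pytest

from ribbonsyn.features import (BASE_WEIGHTS, FEATURE_NAMES,
                                FeatureNormalisation, conditional_weights,
                                extract_features, fit_first_decay,
                                relevant_loss, trace_mse)
from ribbonsyn.model import simulate_release_batch
from ribbonsyn.protocols import make_flash_protocol
from ribbonsyn.synth import ground_truth_calcium
from ribbonsyn.traces import Trace


@pytest.fixture(scope="module")
def protocol():
    return make_flash_protocol(n_flashes=3, dt=0.01)


def release_trace(values, dt=0.01):
    return Trace(values, dt=dt, kind="release")


class TestExtractFeatures:
    def test_constant_trace(self, protocol):
        stim, iv = protocol
        f = extract_features(release_trace(np.full(len(stim), 2.0)), iv)
        d = f.as_dict()
        for name in ("baseline_adaptation", "baseline_bright", "mean_dark",
                     "mean_max_dark", "first_max", "first_min_p25",
                     "second_max", "second_min_p25"):
            assert d[name] == pytest.approx(2.0)
        # vesicle totals: integral of a constant over the 3 s dark window
        assert d["total_first"] == pytest.approx(2.0 * 3.0, rel=0.01)
        assert not f.decay_is_rise  # flat window fits a degenerate decay

    def test_constructed_integral(self, protocol):
        stim, iv = protocol
        vals = np.zeros(len(stim))
        t = stim.time
        a, b = iv.dark[0]
        # rectangle of height 4 over the first dark window: area 12 v.u.
        vals[(t >= a) & (t < b)] = 4.0
        f = extract_features(release_trace(vals), iv)
        assert f.as_dict()["total_first"] == pytest.approx(12.0, rel=0.01)

    def test_known_percentiles(self, protocol):
        stim, iv = protocol
        rng = np.random.default_rng(0)
        vals = np.zeros(len(stim))
        a, b = iv.dark[0]
        idx = stim.window_index(a, b)
        # samples whose p90 and p25 are known by construction
        seg = np.linspace(0.0, 1.0, idx.size)
        rng.shuffle(seg)
        vals[idx] = seg
        f = extract_features(release_trace(vals), iv)
        assert f.as_dict()["first_min_p25"] == pytest.approx(0.25, abs=0.01)

    def test_self_difference_zero(self, protocol, flash_calcium, params):
        stim, iv = protocol
        e = simulate_release_batch(params.free[None, :], flash_calcium,
                                   RP_max=params.RP_max)[0]
        f1 = extract_features(release_trace(e), iv)
        f2 = extract_features(release_trace(e.copy()), iv)
        assert np.array_equal(f1.values, f2.values)
        loss = relevant_loss(f1, f2, FeatureNormalisation.identity())
        assert loss.R == 0.0

    def test_too_few_dark_periods_rejected(self):
        stim, iv = make_flash_protocol(n_flashes=1)
        with pytest.raises(ValueError):
            extract_features(release_trace(np.ones(len(stim))), iv)


class TestFirstDecay:
    def test_recovers_constructed_tau(self, protocol):
        stim, iv = protocol
        a, b = iv.dark[0]
        vals = np.zeros(len(stim))
        t = stim.time
        m = (t >= a) & (t < b)
        vals[m] = 0.3 + 2.0 * np.exp(-(t[m] - a) / 1.2)
        tau, endpoint, is_rise = fit_first_decay(release_trace(vals), (a, b))
        assert tau == pytest.approx(1.2, rel=0.1)
        assert not is_rise
        assert endpoint == pytest.approx(0.3 + 2.0 * np.exp(-3.0 / 1.2),
                                         rel=0.05)

    def test_rising_window_flagged(self, protocol):
        stim, iv = protocol
        a, b = iv.dark[0]
        vals = np.zeros(len(stim))
        t = stim.time
        m = (t >= a) & (t < b)
        vals[m] = 1.0 - np.exp(-(t[m] - a) / 0.8)
        tau, _, is_rise = fit_first_decay(release_trace(vals), (a, b))
        assert is_rise

    def test_short_window_rejected(self, protocol):
        stim, iv = protocol
        with pytest.raises(ValueError):
            fit_first_decay(release_trace(np.ones(len(stim))), (8.0, 8.3))


class TestRelevantLoss:
    def test_single_component_weight_five(self):
        stim, iv = make_flash_protocol()
        base = np.ones(len(stim))
        f0 = extract_features(release_trace(base), iv)
        # a loss where only component 3 (weight 5) differs by 1 normalised
        # unit: R = 5/14
        f1 = extract_features(release_trace(base), iv)
        f1.values = f1.values.copy()
        f1.values[2] += 1.0
        norm = FeatureNormalisation.identity()
        R = relevant_loss(f1, f0, norm).R
        assert R == pytest.approx(5.0 / 14.0)

    def test_weight_linearity(self):
        stim, iv = make_flash_protocol()
        f0 = extract_features(release_trace(np.ones(len(stim))), iv)
        f1 = extract_features(release_trace(np.ones(len(stim))), iv)
        f1.values = f1.values.copy()
        f1.values[4] += 2.0
        w = np.zeros(14)
        w[4] = 3.0
        R = relevant_loss(f1, f0, FeatureNormalisation.identity(), w).R
        assert R == pytest.approx(3.0 * 4.0 / 14.0)

    def test_conditional_rise_penalty(self):
        stim, iv = make_flash_protocol()
        f = extract_features(release_trace(np.ones(len(stim))), iv)
        f.decay_is_rise = False
        assert conditional_weights(f)[13] == pytest.approx(0.01)
        f.decay_is_rise = True
        f.decay_tau = 1.3
        assert conditional_weights(f)[13] == pytest.approx(10.0 * (1 + 2))
        assert np.array_equal(conditional_weights(f)[:13], BASE_WEIGHTS)

    def test_affine_invariance_given_shared_normalisation(self, params,
                                                          flash_calcium):
        _, iv = make_flash_protocol()
        e = simulate_release_batch(params.free[None, :], flash_calcium,
                                   RP_max=params.RP_max)[0]
        rng = np.random.default_rng(3)
        reps_raw = [e + 0.05 * rng.standard_normal(e.size) for _ in range(6)]
        f_raw = [extract_features(release_trace(x), iv) for x in reps_raw]
        f_aff = [extract_features(release_trace(3.0 * x), iv)
                 for x in reps_raw]
        n_raw = FeatureNormalisation.from_replicates(f_raw)
        n_aff = FeatureNormalisation.from_replicates(f_aff)
        R_raw = relevant_loss(f_raw[0], f_raw[1], n_raw).R
        R_aff = relevant_loss(f_aff[0], f_aff[1], n_aff).R
        assert R_raw == pytest.approx(R_aff, rel=1e-6)

    def test_ranking_property(self, flash_calcium):
        # the generating parameters beat 2x single-parameter perturbations
        # of identifiable components
        _, iv = make_flash_protocol()
        theta = np.array([2.5, 2.5, 10.0, 14.0, 0.5, 13.8, 4.0])
        e = simulate_release_batch(theta[None, :], flash_calcium)[0]
        rng = np.random.default_rng(11)
        reps = [extract_features(
            release_trace(e + 0.1 * rng.standard_normal(e.size)), iv)
            for _ in range(6)]
        norm = FeatureNormalisation.from_replicates(reps)
        target = extract_features(release_trace(e), iv)
        R_true = relevant_loss(target, target, norm).R
        for j in (2, 4, 6):  # e_max, x0, RRP_max
            pert = theta.copy()
            pert[j] *= 2.0
            ep = simulate_release_batch(pert[None, :], flash_calcium)[0]
            Rp = relevant_loss(extract_features(release_trace(ep), iv),
                               target, norm).R
            assert Rp > R_true

    def test_trace_mse_requires_shared_grid(self):
        with pytest.raises(ValueError):
            trace_mse(Trace(np.ones(10), dt=0.01),
                      Trace(np.ones(11), dt=0.01))
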