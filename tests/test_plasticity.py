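"""BCPNN trace cascade: fixed points, closed forms, statistical nulls,
learning gate, and discretisation accuracy."""

import numpy as np
import pytest

from dbcnet.plasticity import (BcpnnParams, BcpnnState, bias_current,
                               compute_weight_bias, filter_traces, update_p,
                               update_z)

PRM = BcpnnParams(tau_z=5.0, tau_p=2000.0, f_max=20.0, eps=0.01,
                  t_spike=0.1, kappa=1.0)


def _step_train(pre, post, params, dt):
    """Stepwise reference: scalar update_z/update_p over spike arrays."""
    state = BcpnnState.initial(params, 1)
    zs, ps = [], []
    for s_pre, s_post in zip(pre, post):
        state = update_z(state, params, bool(s_pre), bool(s_post), dt)
        state = update_p(state, params, dt)
        zs.append((state.z_i[0], state.z_j[0]))
        ps.append((state.p_i[0], state.p_j[0], state.p_ij[0]))
    return np.array(zs), np.array(ps)


class TestZTraces:
    def test_eps_is_fixed_point(self):
        state = BcpnnState.initial(PRM, 1)
        for _ in range(500):
            state = update_z(state, PRM, False, False, 0.1)
        assert state.z_i[0] == pytest.approx(PRM.eps, rel=1e-9)

    def test_single_spike_increment_and_decay(self):
        # one spike raises Z by ~1/(f_max*tau_z) then decays with tau_z
        state = BcpnnState.initial(PRM, 1)
        state = update_z(state, PRM, True, False, 0.1)
        jump = 1.0 / (PRM.f_max * 1e-3 * PRM.tau_z)
        assert state.z_i[0] == pytest.approx(PRM.eps + jump, rel=0.03)
        z1 = state.z_i[0]
        for _ in range(50):   # 5 ms = one tau_z
            state = update_z(state, PRM, False, False, 0.1)
        assert (state.z_i[0] - PRM.eps) == pytest.approx(
            (z1 - PRM.eps) * np.exp(-1.0), rel=0.02)

    def test_poisson_train_time_average(self, rng):
        # stationary rate r gives mean Z ~ r/f_max + eps
        dt, rate_hz, t_ms = 0.5, 10.0, 200_000.0
        n = int(t_ms / dt)
        spikes = rng.random(n) < rate_hz * 1e-3 * dt
        tr = filter_traces(spikes, np.zeros(n), PRM, dt)
        assert tr["z_i"][n // 10:].mean() == pytest.approx(
            rate_hz / PRM.f_max + PRM.eps, rel=0.05)


class TestPTracesAndGate:
    def test_kappa_zero_freezes_exactly(self):
        frozen = BcpnnParams(tau_z=5.0, tau_p=2000.0, f_max=20.0, eps=0.01,
                             t_spike=0.1, kappa=0.0)
        state = BcpnnState.initial(frozen, 1)
        state.z_i[:] = 3.0   # arbitrary Z excursion
        before = (state.p_i[0], state.p_j[0], state.p_ij[0])
        for _ in range(1000):
            state = update_p(state, frozen, 0.1)
        assert (state.p_i[0], state.p_j[0], state.p_ij[0]) == before

    def test_constant_z_first_order_response(self):
        state = BcpnnState.initial(PRM, 1)
        state.z_i[:] = 1.0
        state.p_i[:] = 0.0
        for _ in range(20000):   # 2000 ms = one tau_p
            state = update_p(state, PRM, 0.1)
        assert state.p_i[0] == pytest.approx(1 - np.exp(-1.0), rel=0.01)


class TestWeightAndBias:
    def test_independence_gives_zero_weight(self):
        state = BcpnnState.initial(PRM, 1)
        state.p_i[:] = 0.2
        state.p_j[:] = 0.3
        state.p_ij[:] = 0.06
        w, _ = compute_weight_bias(state)
        assert w[0] == pytest.approx(0.0, abs=1e-12)

    def test_perfect_coactivation_weight(self):
        state = BcpnnState.initial(PRM, 1)
        p = 0.2
        state.p_i[:] = p
        state.p_j[:] = p
        state.p_ij[:] = p
        w, _ = compute_weight_bias(state)
        assert w[0] == pytest.approx(-np.log(p), rel=1e-12)

    def test_bias_values(self):
        state = BcpnnState.initial(PRM, 1)
        state.p_j[:] = 1.0
        _, beta = compute_weight_bias(state)
        assert beta[0] == 0.0
        state.p_j[:] = np.exp(-1.0)
        _, beta = compute_weight_bias(state)
        assert beta[0] == pytest.approx(-1.0)

    def test_nonpositive_p_rejected(self):
        state = BcpnnState.initial(PRM, 1)
        state.p_ij[:] = 0.0
        with pytest.raises(ValueError):
            compute_weight_bias(state)

    def test_bias_current_linearity(self):
        assert bias_current(0.0, 50.0) == 0.0
        assert bias_current(-1.0, 50.0) == -50.0
        assert bias_current(-1.0, 0.0) == 0.0


class TestStatisticalProperties:
    def test_independent_poisson_trains_null_weight(self, rng):
        """Independent 10 Hz trains over 100 s leave the weight at zero.

        At low rates only ~1 coincidence per second enters the coactivation
        trace, so the instantaneous log-odds readout of any single pair has
        heavy-tailed fluctuations; the null is read in expectation, from
        the long-run average P traces over an ensemble of pairs.
        """
        dt, n = 0.5, 200_000
        vals = []
        for _ in range(12):
            pre = rng.random(n) < 10.0 * 1e-3 * dt
            post = rng.random(n) < 10.0 * 1e-3 * dt
            tr = filter_traces(pre, post, PRM, dt)
            h = slice(n // 4, None)
            vals.append(np.log(tr["p_ij"][h].mean()
                               / (tr["p_i"][h].mean() * tr["p_j"][h].mean())))
        assert abs(np.mean(vals)) < 0.1

    def test_cofiring_sign(self, rng):
        dt, n = 0.5, 100_000
        driver = rng.random(n) < 15.0 * 1e-3 * dt
        # shared driver: both fire on the same steps -> positive weight
        tr = filter_traces(driver, driver, PRM, dt)
        assert tr["w"][-1] > 0.5
        # alternating activity: anti-correlated -> negative weight
        half = n // 2
        block = (np.arange(n) // 2000) % 2   # 1 s alternation
        pre = driver & (block == 0)
        post = (rng.random(n) < 15.0 * 1e-3 * dt) & (block == 1)
        tr = filter_traces(pre, post, PRM, dt)
        assert tr["w"][-1] < -0.1

    def test_stepwise_matches_filter_recursion(self, rng):
        dt, n = 0.1, 2000
        pre = rng.random(n) < 0.01
        post = rng.random(n) < 0.01
        zs, ps = _step_train(pre, post, PRM, dt)
        tr = filter_traces(pre, post, PRM, dt)
        np.testing.assert_allclose(zs[:, 0], tr["z_i"], rtol=1e-10)
        np.testing.assert_allclose(ps[:, 2], tr["p_ij"], rtol=1e-10)

    def test_discrete_update_matches_fine_dt_oracle(self, rng):
        # dt = 0.1 ms update vs a dt/10 oracle of the same pulse dynamics
        dt, n = 0.1, 5000
        pre = rng.random(n) < 0.008
        post = rng.random(n) < 0.008
        _, ps_coarse = _step_train(pre, post, PRM, dt)
        fine_prm = BcpnnParams(tau_z=5.0, tau_p=2000.0, f_max=20.0, eps=0.01,
                               t_spike=0.1, kappa=1.0)
        pre_f = np.zeros(n * 10, dtype=bool)
        post_f = np.zeros(n * 10, dtype=bool)
        pre_f[np.flatnonzero(pre) * 10] = True
        post_f[np.flatnonzero(post) * 10] = True
        _, ps_fine = _step_train(pre_f, post_f, fine_prm, dt / 10)
        np.testing.assert_allclose(ps_coarse[-1], ps_fine[-1], rtol=0.01)


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        BcpnnParams(tau_p=1.0)   # tau_p must exceed tau_z
    with pytest.raises(ValueError):
        BcpnnParams(eps=0.0)
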