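"""Shunting activation dynamics: input terms, Euler stepping, bounds,
equilibria, wake/sleep time rescaling, and kernel/reference agreement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seqreplay import (ModelParams, NetworkState, PlasticityGates,
                       excitatory_input, inhibitory_input, reset_transients,
                       step_network, update_salience, update_weights,
                       instantiate_links)
from seqreplay.engine import SegmentRun
from seqreplay.state import RegionState


def make_net(n=1, labels="ABCDEFGHIJ"):
    net = NetworkState()
    net.add_items(labels[:n])
    return net


# ----------------------------------------------------------------------
class TestInputTerms:
    def test_silent_network_has_zero_drive(self, params):
        net = make_net(3)
        zero = np.zeros(3)
        E = excitatory_input(net.ctx, zero, zero, params)
        I = inhibitory_input(net.ctx, params)
        assert np.all(E == 0) and np.all(I == 0)

    def test_self_excitation_half_maximum_at_threshold(self, params):
        net = make_net(1)
        net.ctx.a[0] = params.t_a
        E = excitatory_input(net.ctx, np.zeros(1), np.zeros(1), params)
        assert E[0] == pytest.approx(params.alpha / 2)

    def test_feedforward_plus_spreading(self, params):
        # one active neighbor (a=0.5, w=0.4) plus register drive 0.1:
        # E = 1*0.1 + 0.9*0.4*0.5 = 0.28
        net = make_net(2)
        net.ctx.a[0] = 0.5
        net.ctx.exists[0, 1] = net.ctx.exists[1, 0] = True
        net.ctx.W[0, 1] = 0.4
        E = excitatory_input(net.ctx, np.array([0.0, 0.1]), np.zeros(2), params)
        assert E[1] == pytest.approx(0.28)

    def test_inactivation_half_maximum_at_threshold(self, params):
        net = make_net(1)
        net.ctx.g[0] = params.t_h
        I = inhibitory_input(net.ctx, params)
        assert I[0] == pytest.approx(params.theta / 2)

    def test_lateral_inhibition(self, params):
        net = make_net(2)
        net.ctx.a[0] = 0.1
        I = inhibitory_input(net.ctx, params)
        assert I[1] == pytest.approx(params.beta * 0.1)
        assert I[0] == pytest.approx(0.0)

    def test_shape_mismatch_rejected(self, params):
        net = make_net(2)
        with pytest.raises(ValueError):
            excitatory_input(net.ctx, np.zeros(3), np.zeros(2), params)


# ----------------------------------------------------------------------
class TestStepping:
    def test_zero_state_is_fixed_point(self, params):
        net = make_net(3)
        step_network(net, np.zeros(3), params)
        assert np.all(net.ctx.a == 0) and np.all(net.hc.a == 0)
        assert np.all(net.ctx.g == 0) and np.all(net.hc.g == 0)

    def test_single_euler_step_from_rest(self, params):
        # a <- 0 + dt * E / sigma_a = 0.001 * 0.1 / 2 = 5e-5
        net = make_net(1)
        _, dadt_c, _ = step_network(net, np.array([0.1]), params)
        assert net.ctx.a[0] == pytest.approx(5e-5)
        assert dadt_c[0] == pytest.approx(0.05)

    def test_equilibrium_matches_closed_form(self):
        # constant E (self-excitation and inactivation disabled): the
        # shunting ODE settles at a* = E / (1/tau_a + E + I)
        p = ModelParams(alpha=1e-12, theta=1e-12, zeta=0.0)
        net = make_net(1)
        drive = np.array([0.5])
        for _ in range(20000):
            step_network(net, drive, p)
        a_star = 0.5 / (1 / p.tau_a + 0.5)
        assert net.ctx.a[0] == pytest.approx(a_star, abs=1e-3)

    def test_equilibrium_with_constant_inhibition(self):
        # pin g at the inactivation threshold (I = theta/2 = 5) by freezing
        # its dynamics; then a* = E / (1/tau_a + E + I)
        p = ModelParams(alpha=1e-12, zeta=0.0, kappa=1e-12, tau_g=1e12)
        net = make_net(1)
        net.ctx.g[0] = p.t_h
        drive = np.array([1.0])
        for _ in range(40000):
            step_network(net, drive, p)
        a_star = 1.0 / (1 / p.tau_a + 1.0 + p.theta / 2)
        assert net.ctx.a[0] == pytest.approx(a_star, abs=1e-3)

    def test_monotone_passive_decay(self, params):
        net = make_net(1)
        net.ctx.a[0] = 0.004   # below the self-ignition point
        net.ctx.g[0] = 0.5
        prev_a, prev_g = 1.0, 1.1
        for _ in range(3000):
            step_network(net, np.zeros(1), params)
            assert net.ctx.a[0] <= prev_a and net.ctx.g[0] <= prev_g
            prev_a, prev_g = net.ctx.a[0], net.ctx.g[0]
        assert net.ctx.a[0] < 1e-3
        # g decays on the slower sigma_g*tau_g = 12 s scale
        assert net.ctx.g[0] == pytest.approx(0.5 * np.exp(-3.0 / 12.0),
                                             rel=0.02)

    def test_sleep_dynamics_are_time_rescaled_wake_dynamics(self):
        # identical drives: time to reach a fixed level scales with the
        # speed factor ratio (inactivation shares the sleep speed-up);
        # a fine grid keeps quantization below the tolerance
        p = ModelParams(dt=1e-4)
        times = {}
        for mode, dur in (("wake", 2.0), ("sleep", 0.05)):
            net = make_net(1)
            net.mode = mode
            t, n = None, 0
            while t is None and n < int(dur / p.dt):
                step_network(net, np.array([0.1]), p)
                n += 1
                if net.ctx.a[0] >= 0.015:
                    t = n * p.dt
            assert t is not None
            times[mode] = t
        ratio = times["wake"] / times["sleep"]
        expected = p.sigma_a_wake / p.sigma_a_sleep
        assert ratio == pytest.approx(expected, rel=0.05)

    def test_reset_transients(self, params):
        net = make_net(2)
        net.ctx.a[:] = 0.5
        net.hc.g[:] = 0.3
        net.ctx.W[0, 1] = 0.7
        net.ctx.exists[0, 1] = True
        net.salience[:] = 2.0
        reset_transients(net)
        assert np.all(net.ctx.a == 0) and np.all(net.hc.g == 0)
        assert net.ctx.W[0, 1] == 0.7 and np.all(net.salience == 2.0)
        before = net.copy()
        reset_transients(net)   # idempotent
        assert np.array_equal(before.ctx.a, net.ctx.a)


# ----------------------------------------------------------------------
@settings(max_examples=15, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_state_bounds_hold_under_random_driving(seed):
    """a, g, w, s stay in their ranges under arbitrary admissible drives."""
    rng = np.random.default_rng(seed)
    params = ModelParams()
    net = make_net(int(rng.integers(1, 6)))
    n = net.n
    net.mode = "sleep" if rng.random() < 0.3 else "wake"
    mask = ~np.eye(n, dtype=bool) & (rng.random((n, n)) < 0.5)
    for region in (net.ctx, net.hc):
        region.exists[:] = mask
        region.W[:] = np.where(mask, rng.random((n, n)), 0.0)
        region.a[:] = rng.random(n)
        region.g[:] = rng.random(n)
    gates = PlasticityGates()
    for _ in range(5):
        drive = np.zeros(n)
        drive[rng.integers(0, n)] = rng.choice([0.0, 0.1, 0.2])
        for _ in range(40):
            a_pre_c, a_pre_h = net.ctx.a.copy(), net.hc.a.copy()
            _, dadt_c, dadt_h = step_network(net, drive, params)
            update_weights(net.ctx, a_pre_c, dadt_c, params)
            update_weights(net.hc, a_pre_h, dadt_h, params)
            instantiate_links(net, params, True)
            update_salience(net, params)
        net.validate()


def test_kernel_matches_reference_stepper(params):
    """The compiled segment kernel reproduces the reference path exactly:
    step + weight update from the pre-update snapshot + link instantiation
    + salience update, in that order."""
    rng = np.random.default_rng(123)
    for trial in range(4):
        n = int(rng.integers(2, 6))
        mode = "sleep" if trial % 2 else "wake"
        ref = make_net(n)
        ref.mode = mode
        mask = ~np.eye(n, dtype=bool) & (rng.random((n, n)) < 0.6)
        for region in (ref.ctx, ref.hc):
            region.exists[:] = mask
            region.W[:] = np.where(mask, 0.8 * rng.random((n, n)), 0.0)
        ref.salience[:] = rng.random(n)
        fast = ref.copy()
        drive_idx = int(rng.integers(0, n))
        amp = 0.1
        steps = 400
        gates = PlasticityGates()

        drive = np.zeros(n)
        drive[drive_idx] = amp
        for _ in range(steps):
            a_pre_c, a_pre_h = ref.ctx.a.copy(), ref.hc.a.copy()
            _, dadt_c, dadt_h = step_network(ref, drive, params)
            update_weights(ref.ctx, a_pre_c, dadt_c, params)
            update_weights(ref.hc, a_pre_h, dadt_h, params)
            instantiate_links(ref, params, True)
            if mode == "wake":
                update_salience(ref, params)

        run = SegmentRun(fast, params, gates)
        run.run(steps * params.dt, drive_label=fast.catalog.label(drive_idx),
                drive_amp=amp, allow_links=True)

        for attr in ("a", "g", "W"):
            np.testing.assert_allclose(
                getattr(fast.ctx, attr), getattr(ref.ctx, attr),
                rtol=1e-9, atol=1e-12, err_msg=f"ctx {attr} trial {trial}")
            np.testing.assert_allclose(
                getattr(fast.hc, attr), getattr(ref.hc, attr),
                rtol=1e-9, atol=1e-12, err_msg=f"hc {attr} trial {trial}")
        np.testing.assert_allclose(fast.salience, ref.salience, rtol=1e-9)
        assert np.array_equal(fast.ctx.exists, ref.ctx.exists)
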