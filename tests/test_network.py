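"""Unit and property tests of the plastic Kuramoto controller."""

import cmath

import numpy as np
import pytest

from kurasoc.network import (
    NetworkParams,
    NetworkState,
    plasticity_level,
    relational_phase,
    step_network,
    weight_mapping,
    wrap_angle,
    WEIGHT_PERIOD,
)


def make_params(omega=(1.0, 1.0, 1.0), phi0=(0.0, 0.0, 0.0), eta=0.0, alpha=1.0, **kw):
    eta_m = np.full((3, 3), float(eta))
    np.fill_diagonal(eta_m, 0.0)
    return NetworkParams(
        omega=np.asarray(omega, float),
        phi0=np.asarray(phi0, float),
        eta=eta_m,
        alpha=np.broadcast_to(np.asarray(alpha, float), (3,)),
        **kw,
    )


# -- relational phase -------------------------------------------------------

class TestRelationalPhase:
    def test_equal_phases_give_zero(self):
        k = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float)
        phi = relational_phase(np.array([1.3, 1.3, 1.3]), k)
        assert np.allclose(phi, 0.0)

    def test_single_incoming_link_returns_phase_difference(self):
        k = np.zeros((3, 3))
        k[0, 1] = 1.0
        theta = np.array([0.0, np.pi / 2, 0.0])
        phi = relational_phase(theta, k, fallback=np.zeros(3))
        assert phi[0] == pytest.approx(np.pi / 2)

    def test_matches_direct_complex_summation(self):
        theta = np.array([0.0, np.pi / 3, -np.pi / 3])
        k = np.ones((3, 3))
        np.fill_diagonal(k, 0.0)
        # independent brute-force evaluation with scalar complex arithmetic
        expected = []
        for i in range(3):
            z = sum(k[i, j] * cmath.exp(1j * (theta[j] - theta[i])) for j in range(3))
            expected.append(cmath.phase(z))
        assert np.allclose(relational_phase(theta, k), expected)

    def test_degenerate_sum_keeps_previous_value(self):
        k = np.zeros((3, 3))
        prev = np.array([0.4, -0.2, 1.0])
        phi = relational_phase(np.array([0.0, 1.0, 2.0]), k, fallback=prev)
        assert np.array_equal(phi, prev)

    def test_rejects_nonfinite_phases(self):
        with pytest.raises(ValueError):
            relational_phase(np.array([np.nan, 0, 0]), np.zeros((3, 3)))

    def test_range_is_wrapped(self, rng):
        for _ in range(20):
            theta = rng.uniform(0, 2 * np.pi, 3)
            k = rng.uniform(0, 2, (3, 3))
            np.fill_diagonal(k, 0)
            phi = relational_phase(theta, k)
            assert np.all(phi >= -np.pi) and np.all(phi <= np.pi)


# -- plastic function -------------------------------------------------------

class TestPlasticityLevel:
    H = 0.2 * np.pi

    @pytest.mark.parametrize(
        "x, expected",
        [(0.0, 0.0), (np.pi, 1.0), (0.19 * np.pi, 0.0), (0.21 * np.pi, 1.0)],
    )
    def test_step_at_equal_thresholds(self, x, expected):
        assert plasticity_level(x, self.H, self.H) == expected

    def test_linear_ramp_midpoint(self):
        assert plasticity_level(0.2, 0.1, 0.3) == pytest.approx(0.5)
        assert plasticity_level(-0.2, 0.1, 0.3) == pytest.approx(0.5)

    def test_invalid_threshold_order(self):
        with pytest.raises(ValueError):
            plasticity_level(0.1, 0.3, 0.1)

    def test_symmetric_in_sign(self, rng):
        x = rng.uniform(-np.pi, np.pi, 50)
        assert np.allclose(plasticity_level(x, 0.1, 0.5), plasticity_level(-x, 0.1, 0.5))


# -- weight mapping ---------------------------------------------------------

class TestWeightMapping:
    def test_dense_sweep_bounds_and_continuity(self):
        x = np.linspace(0, 2 * WEIGHT_PERIOD, 200001)
        f = weight_mapping(x, gain=1.0)
        assert f.max() == pytest.approx(1.0, abs=1e-6)
        assert f.min() == 0.0
        # exactly zero on half of the domain (the gated lobes)
        assert np.mean(f == 0.0) == pytest.approx(0.5, abs=0.01)
        # continuous: no jumps beyond the dense-grid resolution
        assert np.max(np.abs(np.diff(f))) < 1e-3

    def test_gated_lobe_is_exactly_zero(self):
        assert weight_mapping(3.0 * np.pi) == 0.0
        assert weight_mapping(2.5 * np.pi) == 0.0

    def test_zero_gain_disconnects(self, rng):
        x = rng.uniform(-20, 20, 100)
        assert np.all(weight_mapping(x, gain=0.0) == 0.0)

    def test_periodicity(self, rng):
        x = rng.uniform(0, WEIGHT_PERIOD, 100)
        assert np.allclose(weight_mapping(x), weight_mapping(x + WEIGHT_PERIOD))


# -- integration ------------------------------------------------------------

class TestStepNetwork:
    def test_uncoupled_drift(self):
        params = make_params(omega=(0.5, 1.0, 2.0), alpha=0.0)
        state = NetworkState(theta=np.array([0.1, 0.2, 0.3]), dk=np.zeros((3, 3)))
        dt, n = 0.05, 400
        for _ in range(n):
            state = step_network(state, params, np.zeros(3), dt)
        expected = (np.array([0.1, 0.2, 0.3]) + params.omega * dt * n) % (2 * np.pi)
        assert np.allclose(state.theta, expected, atol=1e-10)

    def test_pair_phase_locks_at_arcsin_fixed_point(self):
        # oscillators 1, 2 coupled symmetrically with K = alpha (weights at a
        # lobe peak); oscillator 3 disconnected.  |omega1 - omega2| < 2K.
        k_str = 1.0
        params = make_params(omega=(1.2, 1.0, 0.0), alpha=k_str)
        dk = np.full((3, 3), 3.0 * np.pi)  # gated zone: K = 0
        dk[0, 1] = dk[1, 0] = np.pi  # lobe peak: F = 1
        state = NetworkState(theta=np.array([0.3, 0.0, 0.0]), dk=dk)
        for _ in range(4000):
            state = step_network(state, params, np.zeros(3), 0.05)
        expected = np.arcsin((1.2 - 1.0) / (2.0 * k_str))
        assert wrap_angle(state.theta[0] - state.theta[1]) == pytest.approx(expected, abs=1e-3)

    def test_weight_derivative_zero_at_preferred_relation(self):
        # theta_2 - theta_1 = pi with phi0_1 = 0: relational phase error is pi
        # (p = 1 > 0) but sin((theta_j - theta_i) - phi0_i) = 0, so dK freezes.
        params = make_params(omega=(0, 0, 0), eta=0.5, alpha=1.0)
        dk = np.full((3, 3), 3.0 * np.pi)
        dk[0, 1] = np.pi
        state = NetworkState(theta=np.array([0.0, np.pi, 0.0]), dk=dk.copy())
        new = step_network(state, params, np.zeros(3), 0.05)
        assert new.p[0] == 1.0
        assert new.dk[0, 1] == dk[0, 1]

    def test_weights_frozen_in_homeostatic_region(self):
        # equal phases, phi0 = 0: phase error 0 everywhere, p = 0, weights
        # must stay bitwise constant over a long segment
        params = make_params(omega=(1.0, 1.0, 1.0), eta=0.9, alpha=2.0)
        dk0 = np.full((3, 3), np.pi)
        state = NetworkState(theta=np.array([0.7, 0.7, 0.7]), dk=dk0.copy())
        for _ in range(200):
            state = step_network(state, params, np.zeros(3), 0.05)
            assert np.all(state.p == 0.0)
        assert np.array_equal(state.dk, dk0)

    def test_invariant_to_adding_two_pi(self):
        params = make_params(omega=(1.0, 2.0, 0.5), eta=0.3, alpha=1.5, phi0=(0.2, -0.3, 0.1))
        dk = np.full((3, 3), 1.0)
        s1 = NetworkState(theta=np.array([0.1, 1.0, 2.0]), dk=dk.copy())
        s2 = NetworkState(theta=np.array([0.1 + 2 * np.pi, 1.0, 2.0]), dk=dk.copy())
        for _ in range(100):
            s1 = step_network(s1, params, np.zeros(3), 0.05)
            s2 = step_network(s2, params, np.zeros(3), 0.05)
        assert np.allclose(s1.theta, s2.theta, atol=1e-9)
        assert np.allclose(s1.dk, s2.dk, atol=1e-9)

    def test_euler_convergence_under_dt_halving(self):
        params = make_params(omega=(1.0, 1.4, 0.7), eta=0.4, alpha=1.0, phi0=(0.3, -0.2, 0.0))
        dk0 = np.full((3, 3), np.pi)

        def run(dt):
            state = NetworkState(theta=np.array([0.5, 1.5, 2.5]), dk=dk0.copy())
            for _ in range(int(round(10.0 / dt))):
                state = step_network(state, params, np.zeros(3), dt)
            return state.theta

        diff = np.abs(wrap_angle(run(0.05) - run(0.025)))
        assert np.max(diff) < 1e-2

    def test_order_parameter_approaches_one_with_strong_coupling(self):
        params = make_params(omega=(1.0, 1.2, 0.8), alpha=5.0)
        dk = np.full((3, 3), np.pi)  # F = 1 -> K = 5
        state = NetworkState(theta=np.array([0.0, 2.0, 4.0]), dk=dk)
        for _ in range(2000):
            state = step_network(state, params, np.zeros(3), 0.05)
        r = np.abs(np.mean(np.exp(1j * state.theta)))
        assert r > 0.99

    def test_rejects_bad_inputs(self):
        params = make_params()
        state = NetworkState(theta=np.zeros(3), dk=np.zeros((3, 3)))
        with pytest.raises(ValueError):
            step_network(state, params, np.array([0.0, 0.0, 1.0]), 0.05)  # I3 != 0
        with pytest.raises(ValueError):
            step_network(state, params, np.array([np.inf, 0.0, 0.0]), 0.05)
        with pytest.raises(ValueError):
            step_network(state, params, np.zeros(3), -0.1)
        with pytest.warns(UserWarning):
            step_network(state, params, np.zeros(3), 0.5)


class TestParamsValidation:
    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            make_params(omega=(6.0, 1.0, 1.0))
        with pytest.raises(ValueError):
            make_params(eta=1.5)

    def test_rejects_bad_thresholds(self):
        with pytest.raises(ValueError):
            make_params(h1=0.5, h2=0.1)

    def test_six_entry_eta_expands_to_offdiagonal(self):
        p = NetworkParams(
            omega=np.ones(3), phi0=np.zeros(3),
            eta=np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6]), alpha=np.ones(3),
        )
        assert p.eta.shape == (3, 3)
        assert np.all(np.diag(p.eta) == 0)
        assert sorted(p.eta[~np.eye(3, dtype=bool)]) == [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]
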