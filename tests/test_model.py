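import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lileychaos import (
    find_equilibrium,
    jacobian,
    rhs,
    sigmoid_rate,
    simulate,
    synaptic_weight,
)
from lileychaos.model import DivergenceError

POTENTIALS = st.floats(min_value=-120.0, max_value=60.0)


class TestSigmoid:
    def test_midpoint_and_saturation(self, standard_params):
        p = standard_params
        assert sigmoid_rate(p.mu_e, "e", p) == pytest.approx(p.S_e_max / 2)
        assert sigmoid_rate(-1e6, "e", p) == pytest.approx(0.0, abs=1e-300)
        assert sigmoid_rate(1e6, "i", p) == pytest.approx(p.S_i_max)

    @settings(derandomize=True, max_examples=50)
    @given(h=POTENTIALS, d=st.floats(min_value=0.01, max_value=40.0))
    def test_monotone_and_symmetric_about_threshold(self, standard_params, h, d):
        p = standard_params
        assert sigmoid_rate(h + d, "e", p) > sigmoid_rate(h, "e", p)
        total = sigmoid_rate(p.mu_e + d, "e", p) + sigmoid_rate(p.mu_e - d, "e", p)
        assert total == pytest.approx(p.S_e_max, rel=1e-12)

    def test_rejects_non_finite_input(self, standard_params):
        with pytest.raises(DivergenceError):
            sigmoid_rate(float("nan"), "e", standard_params)


class TestSynapticWeight:
    def test_unit_values_at_rest(self, standard_params):
        p = standard_params
        assert synaptic_weight(p.h_e_rest, "e", "e", p) == pytest.approx(1.0)
        assert synaptic_weight(p.h_e_rest, "i", "e", p) == pytest.approx(-1.0)

    def test_zero_at_reversal(self, standard_params):
        p = standard_params
        assert synaptic_weight(p.h_e_eq, "e", "e", p) == 0.0
        assert synaptic_weight(p.h_i_eq, "i", "i", p) == 0.0

    @settings(derandomize=True, max_examples=50)
    @given(h=POTENTIALS)
    def test_sign_flips_exactly_at_reversal(self, standard_params, h):
        p = standard_params
        w = synaptic_weight(h, "i", "e", p)
        assert math.copysign(1.0, w) == math.copysign(1.0, p.h_i_eq - h) or w == 0.0


class TestRhs:
    def test_resting_equilibrium_when_decoupled(self, standard_params):
        # Gamma cannot be zero (invariant), but a vanishing drive gives the
        # same decoupling: no connections, no external input.
        p = standard_params.replace(
            N_ee=0, N_ei=0, N_ie=0, N_ii=0, p_ee=0, p_ei=0, p_ie=0, p_ii=0,
            S_e_max=1e-300, S_i_max=1e-300,
        )
        dy = rhs(p.resting_state, p)
        assert np.max(np.abs(dy)) < 1e-250

    def test_alpha_function_peak_normalization(self, standard_params):
        # isolated synaptic block: drive frozen at zero, impulse J(0) = e*Gamma*gamma
        p = standard_params.replace(
            N_ee=0, N_ei=0, N_ie=0, N_ii=0, p_ee=0, p_ei=0, p_ie=0, p_ii=0,
            S_e_max=1e-300, S_i_max=1e-300,
        )
        y0 = p.resting_state
        y0[3] = math.e * p.Gamma_ee * p.gamma_ee  # J_ee impulse
        t_peak = 1.0 / p.gamma_ee
        traj = simulate(p, y0, (0.0, t_peak), t_eval=np.array([0.0, t_peak]),
                        rtol=1e-10, atol=1e-12)
        assert traj.states[-1, 2] == pytest.approx(p.Gamma_ee, rel=1e-3)

    def test_shape_and_finiteness_checks(self, standard_params):
        with pytest.raises(ValueError):
            rhs(np.zeros(9), standard_params)
        bad = np.zeros(10)
        bad[4] = np.inf
        with pytest.raises(DivergenceError):
            rhs(bad, standard_params)


class TestJacobian:
    def test_matches_central_finite_differences(self, standard_params):
        p = standard_params
        rng = np.random.default_rng(42)
        scale = np.array([20, 20, 10, 1, 10, 1, 10, 1, 10, 1], float)
        center = np.array([-60, -60, 10, 0, 10, 0, 5, 0, 5, 0], float)
        for _ in range(100):
            y = center + scale * rng.standard_normal(10)
            J = jacobian(y, p)
            Jfd = np.empty((10, 10))
            for j in range(10):
                h = 1e-6 * max(1.0, abs(y[j]))
                e = np.zeros(10)
                e[j] = h
                Jfd[:, j] = (rhs(y + e, p) - rhs(y - e, p)) / (2 * h)
            assert np.max(np.abs(J - Jfd)) <= 1e-6 * max(1.0, np.max(np.abs(J)))

    def test_definitional_entries(self, standard_params):
        J = jacobian(standard_params.resting_state, standard_params)
        for m in range(4):
            assert J[2 + 2 * m, 3 + 2 * m] == 1.0  # dI/dt = J rows

    def test_decoupled_membrane_eigenvalues(self, standard_params):
        p = standard_params.replace(
            N_ee=0, N_ei=0, N_ie=0, N_ii=0, p_ee=0, p_ei=0, p_ie=0, p_ii=0,
            S_e_max=1e-300, S_i_max=1e-300,
        )
        ev = np.linalg.eigvals(jacobian(p.resting_state, p))
        for target in (-1.0 / p.tau_e, -1.0 / p.tau_i):
            assert np.min(np.abs(ev - target)) < 1e-10


class TestEquilibrium:
    def test_residual_postcondition(self, standard_params):
        y = find_equilibrium(standard_params)
        assert np.max(np.abs(rhs(y, standard_params))) < 1e-10

    def test_synaptic_block_closed_form(self, standard_params):
        p = standard_params
        y = find_equilibrium(p)
        S_e = sigmoid_rate(y[0], "e", p)
        expected_I_ee = math.e * p.Gamma_ee * (p.N_ee * S_e + p.p_ee) / p.gamma_ee
        assert y[2] == pytest.approx(expected_I_ee, rel=1e-9)
        assert np.allclose(y[3::2], 0.0)

    def test_decoupled_gives_resting_state(self, standard_params):
        p = standard_params.replace(
            N_ee=0, N_ei=0, N_ie=0, N_ii=0, p_ee=0, p_ei=0, p_ie=0, p_ii=0,
            S_e_max=1e-300, S_i_max=1e-300,
        )
        y = find_equilibrium(p)
        assert np.allclose(y, p.resting_state, atol=1e-9)

    def test_continuity_under_small_input_perturbation(self, standard_params):
        y0 = find_equilibrium(standard_params)
        deltas = [1e-2, 1e-4, 1e-6]
        shifts = []
        for d in deltas:
            y1 = find_equilibrium(standard_params.replace(p_ee=standard_params.p_ee + d), guess=y0)
            shifts.append(np.max(np.abs(y1 - y0)))
        assert shifts[0] > shifts[1] > shifts[2]
        assert shifts[2] < 1e-4


class TestSimulate:
    def test_fixed_point_persistence(self, standard_params):
        y0 = find_equilibrium(standard_params)
        traj = simulate(standard_params, y0, 1000.0,
                        t_eval=np.linspace(0, 1000, 11))
        assert np.max(np.abs(traj.states - y0)) < 1e-6

    def test_tolerance_convergence(self, standard_params):
        y0 = find_equilibrium(standard_params)
        y0[0] += 1.0
        end = {}
        for rtol in (1e-6, 1e-8):
            traj = simulate(standard_params, y0, 100.0,
                            t_eval=np.array([0.0, 100.0]), rtol=rtol, atol=rtol * 1e-2)
            end[rtol] = traj.states[-1]
        # the coarse answer is already within a small multiple of its tolerance
        scale = np.max(np.abs(end[1e-8]))
        assert np.max(np.abs(end[1e-6] - end[1e-8])) < 10 * 1e-6 * scale

    def test_linear_decay_rate_when_decoupled(self, standard_params):
        p = standard_params.replace(
            N_ee=0, N_ei=0, N_ie=0, N_ii=0, p_ee=0, p_ei=0, p_ie=0, p_ii=0,
            S_e_max=1e-300, S_i_max=1e-300,
        )
        y0 = p.resting_state
        y0[0] += 10.0
        traj = simulate(p, y0, p.tau_e, t_eval=np.array([0.0, p.tau_e]))
        decay = (traj.states[-1, 0] - p.h_e_rest) / 10.0
        assert decay == pytest.approx(math.exp(-1.0), rel=1e-2)

    def test_divergence_flagged_not_nan(self, standard_params):
        # start near the (unstable) equilibrium inside the bound; the growing
        # relaxation oscillation crosses it and must terminate with a flag
        y0 = find_equilibrium(standard_params)
        y0[0] += 1.0
        traj = simulate(standard_params, y0, 3000.0, divergence_bound=4000.0)
        assert traj.diverged
        assert traj.times[-1] < 3000.0  # partial trajectory
        assert np.all(np.isfinite(traj.states))

    def test_csv_export_header(self, tmp_path, standard_params):
        y0 = find_equilibrium(standard_params)
        traj = simulate(standard_params, y0, 10.0, t_eval=np.linspace(0, 10, 3))
        out = tmp_path / "traj.csv"
        traj.to_csv(out)
        assert out.read_text().splitlines()[0] == (
            "t_ms,h_e,h_i,I_ee,J_ee,I_ei,J_ei,I_ie,J_ie,I_ii,J_ii"
        )
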