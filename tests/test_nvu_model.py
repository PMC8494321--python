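"""Nonlinear NVU core: derivatives, equilibrium, simulation.

The derivative function is checked term-by-term against an independent
scalar re-implementation of the compartmental equations (written directly
from the model equations with ``math`` scalars, no shared code).
"""

import math

import numpy as np
import pytest

from nvugrey import NVUParameters, NVUState, derivatives, find_equilibrium, simulate
from nvugrey.errors import ConfigurationError, NumericalDomainError
from nvugrey.nvu_model import N_STATES, STATE_NAMES
from nvugrey.tdcs_input import StimulusWaveform


# ---------------------------------------------------------------------------
# Independent equation-by-equation oracle (scalar math, one function per
# compartment equation)
# ---------------------------------------------------------------------------

def _sigm(u):
    return 1.0 / (1.0 + math.exp(-u))


def _oracle_synaptic_K(p, K_s, v1):
    uptake = p["J_sigma_k_max"] * p["k_Na"] * K_s / (K_s + p["KKO_a"])
    return p["J_Ks"] + v1 - uptake


def _oracle_ip3(p, K_s, IP3):
    rho = p["rho_max"] * _sigm((K_s - p["K_rho"]) / p["sig_rho"])
    G = (rho + p["delta"]) / (p["K_G"] + rho + p["delta"])
    return p["r_h"] * G - p["k_deg"] * IP3


def _oracle_astro_ca(p, IP3, Ca, h, ss, Vk):
    gate = (IP3 / (IP3 + p["K_I"])) * (Ca / (Ca + p["K_act"])) * h
    j_rel = p["J_max"] * gate ** 3 * (1.0 - Ca / p["c_ER"])
    j_pump = p["V_pump"] * Ca * Ca / (Ca * Ca + p["k_pump"] ** 2)
    j_leak = p["P_leak"] * (1.0 - Ca / p["c_ER"])
    j_trpv = p["mu_trpv"] * ss * (1.0 - Vk / p["v_ca_astr"])
    return p["beta_buff"] * (j_rel - j_pump + j_leak + j_trpv)


def _oracle_h(p, Ca, h):
    return p["k_on"] * (p["K_inh"] - (Ca + p["K_inh"]) * h)


def _oracle_trpv(p, x, Ca_p, ss):
    strain = (x - p["x_trpv0"]) / p["x_trpv0"]
    s_inf = (_sigm((strain - p["eps_half"]) / p["kappa_eps"])
             * _sigm((p["Ca_tr_ref"] - Ca_p) / p["kap_ca_tr"]))
    return (s_inf - ss) / p["t_trpv"]


def _oracle_eet(p, Ca, EET):
    w = p["w_sp"]
    prod = p["V_eet"] * w * math.log1p(math.exp((Ca - p["Ca_eet"]) / w))
    return prod - p["k_eet"] * EET


def _oracle_bk(p, Vk, EET, n_bk):
    n_inf = 0.5 * (1.0 + math.tanh(
        (Vk + p["eet_shift"] * EET - p["v3_bk"]) / p["v4_bk"]))
    return p["phi_bk"] * (n_inf - n_bk)


def _oracle_astro_v(p, K_s, ss, n_bk, Vk, K_p, v2):
    e_bk = p["RTF"] * math.log(K_p / p["K_a_in"])
    i_bk = p["g_bk"] * n_bk * (Vk - e_bk)
    i_leak = p["g_leak_a"] * (Vk - p["v_leak_a"])
    i_trpv = p["g_trpv"] * ss * (Vk - p["E_trpv"])
    uptake = p["J_sigma_k_max"] * p["k_Na"] * K_s / (K_s + p["KKO_a"])
    i_sig = -p["c_sig"] * uptake
    return (-i_bk - i_leak - i_trpv - i_sig + v2) / p["C_astr"]


def _oracle_peri_K(p, n_bk, Vk, K_p, k, V, v3):
    e_bk = p["RTF"] * math.log(K_p / p["K_a_in"])
    e_kir = p["z1"] * K_p - p["z2"]
    j_bk = p["c_bk"] * n_bk * (Vk - e_bk)
    j_kir = p["c_kir"] * k * (V - e_kir)
    return (j_bk / p["VR_pa"] + j_kir / p["VR_ps"]
            - p["R_decay"] * (K_p - p["K_p_min"]) + v3)


def _oracle_peri_ca(p, ss, Vk, Ca_p):
    return (-p["mu_trpv"] * ss
            - p["R_cap"] * (Ca_p - p["Ca_p_min"]))


def _oracle_kir(p, K_p, V, k):
    k_inf = 0.5 * (1.0 + math.tanh(((p["z3"] * K_p - p["z4"]) - V) / p["z5"]))
    return p["phi_kir"] * (k_inf - k)


def _oracle_smc_v(p, K_p, k, V, n, Ca, v4):
    e_kir = p["z1"] * K_p - p["z2"]
    m_inf = 0.5 * (1.0 + math.tanh((V - p["v1_m"]) / p["v2_m"]))
    i_l = p["g_l_s"] * (V - p["v_l_s"])
    i_k = p["g_k_s"] * n * (V - p["v_k_s"])
    i_ca = p["g_ca_s"] * m_inf * (V - p["v_ca_s"])
    i_kir = p["g_kir_s"] * k * (V - e_kir)
    i_kv = p["g_kv"] * (V - p["v_k_s"])
    return (-i_l - i_k - i_ca - i_kir - i_kv + v4) / p["C_SMC"]


def _oracle_smc_n(p, V, n, Ca):
    v3 = -(p["v5_n"] / 2.0) * math.tanh((Ca - p["Ca3"]) / p["Ca4"]) + p["v6_n"]
    n_inf = 0.5 * (1.0 + math.tanh((V - v3) / p["v4_n"]))
    lam = p["lam_n"] * math.cosh((V - v3) / (2.0 * p["v4_n"]))
    return lam * (n_inf - n)


def _oracle_smc_ca(p, V, Ca):
    m_inf = 0.5 * (1.0 + math.tanh((V - p["v1_m"]) / p["v2_m"]))
    i_ca = p["g_ca_s"] * m_inf * (V - p["v_ca_s"])
    rho = (p["K_d"] + Ca) ** 2 / ((p["K_d"] + Ca) ** 2 + p["K_d"] * p["B_T"])
    return rho * (-p["alpha_ca"] * i_ca - p["k_ca_ex"] * Ca)


def _oracle_omega(p, Ca, om):
    q = p["q_psi"]
    psi = Ca ** q / (Ca ** q + p["Ca_psi"] ** q)
    return p["k_psi"] * (psi - om)


def _oracle_yy(p, x, om, yy):
    return ((x / p["x_ref"] - p["c_w"] * om) - yy) / p["tau_y"]


def _oracle_x(p, x, om, yy):
    return (p["f_p"] - (x - p["x_ref0"])
            - p["act_ratio"] * om * yy * (x / p["x_ref"])) / p["tau_x"]


def oracle_derivatives(p, y, pert=(0.0, 0.0, 0.0, 0.0)):
    (K_s, IP3, Ca_A, h, ss, EET, n_bk, Vk, K_p, Ca_p, k,
     V, n, Ca, om, yy, x) = y
    v1, v2, v3, v4 = pert
    return np.array([
        _oracle_synaptic_K(p, K_s, v1),
        _oracle_ip3(p, K_s, IP3),
        _oracle_astro_ca(p, IP3, Ca_A, h, ss, Vk),
        _oracle_h(p, Ca_A, h),
        _oracle_trpv(p, x, Ca_p, ss),
        _oracle_eet(p, Ca_A, EET),
        _oracle_bk(p, Vk, EET, n_bk),
        _oracle_astro_v(p, K_s, ss, n_bk, Vk, K_p, v2),
        _oracle_peri_K(p, n_bk, Vk, K_p, k, V, v3),
        _oracle_peri_ca(p, ss, Vk, Ca_p),
        _oracle_kir(p, K_p, V, k),
        _oracle_smc_v(p, K_p, k, V, n, Ca, v4),
        _oracle_smc_n(p, V, n, Ca),
        _oracle_smc_ca(p, V, Ca),
        _oracle_omega(p, Ca, om),
        _oracle_yy(p, x, om, yy),
        _oracle_x(p, x, om, yy),
    ])


def _random_states(rng, n):
    lo = np.array([1.0, 0.005, 0.05, 0.1, 0.01, 0.0, 0.01, -90.0, 2.0,
                   1500.0, 0.01, -70.0, 0.01, 0.05, 0.01, 0.5, 100.0])
    hi = np.array([8.0, 0.1, 0.4, 0.9, 0.9, 2.0, 0.9, -40.0, 10.0,
                   2500.0, 0.9, -20.0, 0.9, 0.6, 0.9, 1.5, 160.0])
    return lo + (hi - lo) * rng.uniform(size=(n, N_STATES))


# ---------------------------------------------------------------------------


class TestDerivatives:
    def test_dimensionality_is_seventeen(self, params, equilibrium):
        d = derivatives(equilibrium.state, 0.0, params)
        assert d.shape == (17,)
        assert len(STATE_NAMES) == 17

    def test_equilibrium_is_a_fixed_point(self, params, equilibrium):
        d = derivatives(equilibrium.state, 0.0, params)
        assert np.max(np.abs(d)) < 1e-6

    def test_astrocyte_current_perturbation_is_additive(self, params, equilibrium):
        # injecting dI_T adds exactly eps/C_astr to the Vk derivative
        eps = 0.37
        d0 = derivatives(equilibrium.state, 0.0, params)
        d1 = derivatives(equilibrium.state, 0.0, params, (0.0, eps, 0.0, 0.0))
        delta = d1 - d0
        i_vk = STATE_NAMES.index("Vk")
        assert delta[i_vk] == pytest.approx(eps / params.C_astr, rel=1e-12)
        delta[i_vk] = 0.0
        assert np.all(delta == 0.0)

    def test_matches_independent_equation_oracle(self, params):
        rng = np.random.default_rng(7)
        states = _random_states(rng, 100)
        perts = rng.uniform(-0.5, 0.5, size=(100, 4))
        for y, pe in zip(states, perts):
            got = derivatives(y, 0.0, params, pe)
            want = oracle_derivatives(params, y, pe)
            np.testing.assert_allclose(got, want, rtol=1e-10, atol=1e-12)

    def test_missing_parameter_is_configuration_error(self, params):
        vals = dict(params)
        vals.pop("R_decay")
        with pytest.raises(ConfigurationError, match="R_decay"):
            NVUParameters(vals)

    def test_nonfinite_state_names_offending_equation(self, params, equilibrium):
        y = equilibrium.state.to_array()
        y[STATE_NAMES.index("K_p")] = -1.0   # log of a negative concentration
        with np.errstate(invalid="ignore"), pytest.raises(NumericalDomainError):
            derivatives(y, 0.0, params)


class TestEquilibrium:
    def test_residual_below_tolerance(self, params, equilibrium):
        assert equilibrium.residual < 1e-8
        assert not equilibrium.oscillatory

    def test_idempotent_from_exact_solution(self, params, equilibrium):
        again = find_equilibrium(params, equilibrium.state)
        np.testing.assert_allclose(again.state.to_array(),
                                   equilibrium.state.to_array(),
                                   rtol=1e-10, atol=1e-12)

    def test_basin_of_attraction_five_percent(self, params, equilibrium):
        rng = np.random.default_rng(3)
        y0 = equilibrium.state.to_array()
        guess = y0 * (1.0 + 0.05 * rng.uniform(-1, 1, N_STATES))
        eq2 = find_equilibrium(params, NVUState.from_array(guess))
        np.testing.assert_allclose(eq2.state.to_array(), y0, rtol=1e-6)

    def test_state_invariant_validation(self, equilibrium):
        equilibrium.state.validate()
        bad = equilibrium.state.to_array()
        bad[STATE_NAMES.index("h")] = 1.5
        with pytest.raises(NumericalDomainError):
            NVUState.from_array(bad).validate()


class TestSimulate:
    def test_unforced_trajectory_stays_at_equilibrium(self, params, equilibrium):
        traj = simulate(equilibrium.state, params, stimulus=None,
                        t_span=(0.0, 150.0), dt_out=0.5)
        x = traj["x"]
        assert np.max(np.abs(x - equilibrium.state.x)) < 1e-4

    @pytest.mark.parametrize("pathway", [1, 2, 3, 4])
    def test_stimulated_vessel_transient(self, params, equilibrium, pathway):
        from nvugrey.synth import REFERENCE_GAINS
        from nvugrey.tdcs_input import VasoactiveFilter

        stim = StimulusWaveform(amplitude=2.0, ramp_up=30.0, plateau=120.0,
                                ramp_down=0.0)
        traj = simulate(equilibrium.state, params, stimulus=stim,
                        pathway=pathway,
                        filt=VasoactiveFilter(K_i=REFERENCE_GAINS[pathway]),
                        t_span=(0.0, 150.0), dt_out=0.1)
        dx = traj["x"] - equilibrium.state.x
        # a clear transient develops and is dilatory for the calibrated gains
        assert np.max(np.abs(dx)) > 0.05
        assert dx[np.argmax(np.abs(dx))] > 0.0
        # quiescent at onset
        assert abs(dx[0]) < 1e-9

    def test_refining_tolerance_changes_solution_marginally(self, params,
                                                            equilibrium):
        from nvugrey.synth import REFERENCE_GAINS
        from nvugrey.tdcs_input import VasoactiveFilter

        stim = StimulusWaveform(amplitude=2.0, ramp_up=30.0, plateau=60.0,
                                ramp_down=0.0)
        filt = VasoactiveFilter(K_i=REFERENCE_GAINS[3])
        kw = dict(stimulus=stim, pathway=3, filt=filt, t_span=(0.0, 100.0),
                  dt_out=0.5)
        a = simulate(equilibrium.state, params, rtol=1e-7, atol=1e-9, **kw)
        b = simulate(equilibrium.state, params, rtol=3.5e-8, atol=5e-10, **kw)
        scale = np.max(np.abs(a["x"] - equilibrium.state.x))
        assert np.max(np.abs(a["x"] - b["x"])) / scale < 1e-3

    def test_invalid_pathway_rejected(self, params, equilibrium):
        with pytest.raises(ConfigurationError):
            simulate(equilibrium.state, params, pathway=5)

    def test_trajectory_frame_export(self, params, equilibrium):
        traj = simulate(equilibrium.state, params, stimulus=None,
                        t_span=(0.0, 5.0), dt_out=1.0)
        df = traj.to_frame()
        assert list(df.columns[:2]) == ["time", "K_s"]
        assert len(df) == 6
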