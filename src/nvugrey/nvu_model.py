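"""Nonlinear lumped neurovascular-unit (NVU) model.

The model couples four compartments -- synaptic space, astrocyte,
perivascular space, and arteriolar smooth muscle cell (SMC) -- through
potassium, IP3/calcium, EET and electrical signaling, producing the mean
vessel circumference ``x`` as its output.  It carries 17 state variables
and supports four additive perturbation inputs through which a filtered
transcranial direct-current stimulation (tDCS) waveform can act:

pathway 1   synaptic K+ release flux         (added to dK_s/dt, mM/s)
pathway 2   astrocyte transmembrane current  (added inside dVk/dt, per C_astr)
pathway 3   perivascular K+ concentration    (added to dK_p/dt, mM/s)
pathway 4   SMC voltage-gated K current      (added inside dV_SMC/dt, per C_SMC)

The equations follow the published astrocyte/SMC neurovascular lineage
(bidirectional astrocyte-vessel communication with TRPV4 mechanosensing on
the endfoot and a Morris-Lecar-type SMC with KIR feedback from the
perivascular space).  All parameters live in ``data/parameters.yaml`` with
per-symbol provenance; see docs/methods.md for the model account.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .errors import (
    ConfigurationError,
    InstabilityError,
    IntegrationError,
    NumericalDomainError,
)

STATE_NAMES = (
    "K_s", "IP3", "Ca_A", "h", "ss", "EET", "n_bk", "Vk",
    "K_p", "Ca_p", "k", "V_smc", "n", "Ca_smc", "omega", "yy", "x",
)
N_STATES = len(STATE_NAMES)

#: indices of probability-type states (must stay in [0, 1])
PROBABILITY_STATES = tuple(
    STATE_NAMES.index(s) for s in ("h", "ss", "n_bk", "k", "n", "omega")
)
#: indices of concentration states (must stay non-negative)
CONCENTRATION_STATES = tuple(
    STATE_NAMES.index(s) for s in ("K_s", "IP3", "Ca_A", "EET", "K_p", "Ca_p", "Ca_smc")
)

#: state each pathway's perturbation is injected into
PATHWAY_INJECTION = {1: "K_s", 2: "Vk", 3: "K_p", 4: "V_smc"}

_PROB_TOL = 1e-6


@dataclass
class NVUState:
    """The 17 compartmental state variables of the lumped NVU model."""

    K_s: float      # synaptic potassium (mM)
    IP3: float      # astrocytic inositol trisphosphate (uM)
    Ca_A: float     # astrocytic calcium (uM)
    h: float        # IP3-receptor gating variable (0-1)
    ss: float       # TRPV4 open probability (0-1)
    EET: float      # astrocytic EET concentration (uM)
    n_bk: float     # BK-channel open probability (0-1)
    Vk: float       # astrocyte membrane potential (mV)
    K_p: float      # perivascular potassium (mM)
    Ca_p: float     # perivascular calcium (uM)
    k: float        # KIR open probability (0-1)
    V_smc: float    # SMC membrane potential (mV)
    n: float        # SMC K-channel open probability (0-1)
    Ca_smc: float   # SMC calcium (uM)
    omega: float    # fraction of attached cross-bridges (0-1)
    yy: float       # normalized contractile element length
    x: float        # mean vessel circumference (um)

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, nm) for nm in STATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "NVUState":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (N_STATES,):
            raise ConfigurationError(f"state vector must have shape ({N_STATES},)")
        return cls(**dict(zip(STATE_NAMES, arr)))

    def validate(self, prob_tol: float = _PROB_TOL) -> None:
        """Raise if invariants are violated (probabilities, signs)."""
        arr = self.to_array()
        for i in PROBABILITY_STATES:
            if arr[i] < -prob_tol or arr[i] > 1.0 + prob_tol:
                raise NumericalDomainError(
                    f"probability state {STATE_NAMES[i]}={arr[i]:.6g} outside [0,1]",
                    equation=STATE_NAMES[i],
                )
        for i in CONCENTRATION_STATES:
            if arr[i] < -prob_tol:
                raise NumericalDomainError(
                    f"concentration {STATE_NAMES[i]}={arr[i]:.6g} is negative",
                    equation=STATE_NAMES[i],
                )
        if self.x <= 0:
            raise NumericalDomainError("vessel circumference x must be positive",
                                       equation="x")


_REQUIRED = (
    "J_Ks J_sigma_k_max k_Na KKO_a rho_max K_rho sig_rho r_h K_G delta k_deg "
    "J_max K_I K_act c_ER V_pump k_pump P_leak mu_trpv beta_buff k_on K_inh "
    "x_trpv0 eps_half kappa_eps Ca_tr_ref kap_ca_tr t_trpv v_ca_astr "
    "V_eet Ca_eet k_eet "
    "w_sp v3_bk v4_bk eet_shift phi_bk g_bk g_leak_a v_leak_a g_trpv E_trpv "
    "c_sig C_astr K_a_in RTF c_bk c_kir VR_pa VR_ps R_decay K_p_min R_cap "
    "Ca_p_min z1 z2 z3 z4 z5 phi_kir v1_m v2_m v4_n v5_n v6_n Ca3 Ca4 lam_n "
    "g_l_s v_l_s g_k_s v_k_s g_ca_s v_ca_s g_kir_s g_kv C_SMC alpha_ca "
    "k_ca_ex K_d B_T q_psi Ca_psi k_psi tau_y tau_x x_ref0 f_p act_ratio "
    "x_ref c_w"
).split()

_POSITIVE = ("C_astr", "C_SMC", "VR_pa", "VR_ps", "R_decay", "k_deg", "k_eet",
             "t_trpv", "tau_x", "tau_y", "k_ca_ex", "R_cap")


class NVUParameters(Mapping):
    """Complete constant set of the NVU equations, keyed by symbol.

    Behaves as a read-only mapping; each symbol is also available as an
    attribute.  ``provenance`` records, per symbol, whether the value follows
    the published source-model lineage or is a package default.
    """

    def __init__(self, values: Mapping[str, float],
                 provenance: Mapping[str, str] | None = None,
                 units: Mapping[str, str] | None = None):
        self._values = {k: float(v) for k, v in values.items()}
        self.provenance = dict(provenance or {})
        self.units = dict(units or {})
        missing = [s for s in _REQUIRED if s not in self._values]
        if missing:
            raise ConfigurationError(f"unresolved parameter symbols: {missing}")
        for s in _POSITIVE:
            if self._values[s] <= 0:
                raise ConfigurationError(f"parameter {s} must be strictly positive")

    # Mapping protocol -----------------------------------------------------
    def __getitem__(self, key):
        return self._values[key]

    def __iter__(self):
        return iter(self._values)

    def __len__(self):
        return len(self._values)

    def __getattr__(self, key):
        try:
            return self.__dict__["_values"][key]
        except KeyError:
            raise AttributeError(key)

    def replace(self, **overrides) -> "NVUParameters":
        vals = dict(self._values)
        vals.update(overrides)
        return NVUParameters(vals, self.provenance, self.units)

    @classmethod
    def default(cls) -> "NVUParameters":
        """Load the packaged default parameter file."""
        from importlib.resources import files
        text = files("nvugrey").joinpath("data/parameters.yaml").read_text()
        doc = yaml.safe_load(text)
        entries = doc["parameters"]
        values = {k: v["value"] for k, v in entries.items()}
        prov = {k: v.get("provenance", "package") for k, v in entries.items()}
        units = {k: v.get("unit", "") for k, v in entries.items()}
        return cls(values, prov, units)

    @classmethod
    def from_yaml(cls, path) -> "NVUParameters":
        """Read a flat key-value parameter file (symbol: value or rich form)."""
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        entries = doc.get("parameters", doc)
        values, prov, units = {}, {}, {}
        for k, v in entries.items():
            if isinstance(v, dict):
                values[k] = v["value"]
                prov[k] = v.get("provenance", "file")
                units[k] = v.get("unit", "")
            else:
                values[k] = v
                prov[k] = "file"
        return cls(values, prov, units)

    def to_yaml(self, path) -> None:
        doc = {"parameters": {
            k: {"value": v,
                "unit": self.units.get(k, ""),
                "provenance": self.provenance.get(k, "package")}
            for k, v in self._values.items()}}
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def default_guess() -> NVUState:
    """Baseline guess from the packaged parameter file."""
    from importlib.resources import files
    doc = yaml.safe_load(files("nvugrey").joinpath("data/parameters.yaml").read_text())
    return NVUState(**doc["baseline_guess"])


# ---------------------------------------------------------------------------
# Right-hand side
# ---------------------------------------------------------------------------

def _sig(u):
    return 1.0 / (1.0 + np.exp(-u))


def _softplus(u, w):
    # smooth max(u, 0); differentiable replacement for the EET threshold
    return w * np.logaddexp(0.0, u / w)


def rhs(y: np.ndarray, p: Mapping[str, float],
        perturbation: Sequence[float] = (0.0, 0.0, 0.0, 0.0)) -> np.ndarray:
    """Raw 17-dimensional right-hand side on a plain state array.

    ``perturbation`` is the 4-vector of pathway inputs
    ``(dJ_Ks, dI_T, dK_p_rate, dI_KV)``; each is additive at its injection
    site (currents are divided by the respective capacitance).
    """
    (K_s, IP3, Ca_A, h, ss, EET, n_bk, Vk, K_p, Ca_p, k,
     V, n, Ca, om, yy, x) = y
    v1, v2, v3, v4 = perturbation

    # synaptic space: baseline release + perturbation - saturable uptake
    J_up = p["J_sigma_k_max"] * p["k_Na"] * K_s / (K_s + p["KKO_a"])
    dK_s = p["J_Ks"] + v1 - J_up

    # glutamate receptor occupancy tracks synaptic K+ (sigmoidal)
    rho = p["rho_max"] * _sig((K_s - p["K_rho"]) / p["sig_rho"])
    G = (rho + p["delta"]) / (p["K_G"] + rho + p["delta"])
    dIP3 = p["r_h"] * G - p["k_deg"] * IP3

    # astrocyte calcium: IP3R release, SERCA pump, ER leak, TRPV4 influx
    J_ip3r = p["J_max"] * ((IP3 / (IP3 + p["K_I"]))
                           * (Ca_A / (Ca_A + p["K_act"])) * h) ** 3 \
        * (1.0 - Ca_A / p["c_ER"])
    J_pump = p["V_pump"] * Ca_A ** 2 / (Ca_A ** 2 + p["k_pump"] ** 2)
    J_leak = p["P_leak"] * (1.0 - Ca_A / p["c_ER"])
    # TRPV4 Ca influx scales with the electrochemical driving force, so the
    # astrocyte membrane potential feeds the slow Ca/EET signaling chain
    J_trpv_ca = p["mu_trpv"] * ss * (1.0 - Vk / p["v_ca_astr"])
    dCa_A = p["beta_buff"] * (J_ip3r - J_pump + J_leak + J_trpv_ca)

    dh = p["k_on"] * (p["K_inh"] - (Ca_A + p["K_inh"]) * h)

    # TRPV4 gating: membrane strain activates, perivascular Ca inhibits
    eps = (x - p["x_trpv0"]) / p["x_trpv0"]
    s_inf = _sig((eps - p["eps_half"]) / p["kappa_eps"]) \
        * _sig((p["Ca_tr_ref"] - Ca_p) / p["kap_ca_tr"])
    dss = (s_inf - ss) / p["t_trpv"]

    dEET = p["V_eet"] * _softplus(Ca_A - p["Ca_eet"], p["w_sp"]) - p["k_eet"] * EET

    # astrocyte BK channel; EET left-shifts activation
    n_inf_bk = 0.5 * (1.0 + np.tanh((Vk + p["eet_shift"] * EET - p["v3_bk"])
                                    / p["v4_bk"]))
    dn_bk = p["phi_bk"] * (n_inf_bk - n_bk)

    # astrocyte membrane potential (pathway-2 current enters here)
    E_BK = p["RTF"] * np.log(K_p / p["K_a_in"])
    I_BK = p["g_bk"] * n_bk * (Vk - E_BK)
    I_leak = p["g_leak_a"] * (Vk - p["v_leak_a"])
    I_trpv = p["g_trpv"] * ss * (Vk - p["E_trpv"])
    I_sigk = -p["c_sig"] * J_up
    dVk = (-I_BK - I_leak - I_trpv - I_sigk + v2) / p["C_astr"]

    # perivascular potassium (pathway-3 rate enters here)
    E_kir = p["z1"] * K_p - p["z2"]
    J_bk = p["c_bk"] * n_bk * (Vk - E_BK)
    J_kir = p["c_kir"] * k * (V - E_kir)
    dK_p = J_bk / p["VR_pa"] + J_kir / p["VR_ps"] \
        - p["R_decay"] * (K_p - p["K_p_min"]) + v3

    dCa_p = -p["mu_trpv"] * ss - p["R_cap"] * (Ca_p - p["Ca_p_min"])

    # SMC KIR gating: opens with perivascular K+, closes with depolarization
    k_inf = 0.5 * (1.0 + np.tanh(((p["z3"] * K_p - p["z4"]) - V) / p["z5"]))
    dk = p["phi_kir"] * (k_inf - k)

    # SMC membrane (pathway-4 current enters here)
    m_inf = 0.5 * (1.0 + np.tanh((V - p["v1_m"]) / p["v2_m"]))
    v3n = -(p["v5_n"] / 2.0) * np.tanh((Ca - p["Ca3"]) / p["Ca4"]) + p["v6_n"]
    n_inf = 0.5 * (1.0 + np.tanh((V - v3n) / p["v4_n"]))
    lam = p["lam_n"] * np.cosh((V - v3n) / (2.0 * p["v4_n"]))
    dn = lam * (n_inf - n)
    I_L = p["g_l_s"] * (V - p["v_l_s"])
    I_K = p["g_k_s"] * n * (V - p["v_k_s"])
    I_Ca = p["g_ca_s"] * m_inf * (V - p["v_ca_s"])
    I_KIR = p["g_kir_s"] * k * (V - E_kir)
    I_KV = p["g_kv"] * (V - p["v_k_s"])
    dV = (-I_L - I_K - I_Ca - I_KIR - I_KV + v4) / p["C_SMC"]

    # SMC calcium with fast buffering
    rho_b = (p["K_d"] + Ca) ** 2 / ((p["K_d"] + Ca) ** 2 + p["K_d"] * p["B_T"])
    dCa = rho_b * (-p["alpha_ca"] * I_Ca - p["k_ca_ex"] * Ca)

    # cross-bridge attachment and Kelvin-Voigt vessel mechanics
    psi = Ca ** p["q_psi"] / (Ca ** p["q_psi"] + p["Ca_psi"] ** p["q_psi"])
    dom = p["k_psi"] * (psi - om)
    dyy = ((x / p["x_ref"] - p["c_w"] * om) - yy) / p["tau_y"]
    dx = (p["f_p"] - (x - p["x_ref0"])
          - p["act_ratio"] * om * yy * (x / p["x_ref"])) / p["tau_x"]

    return np.array([dK_s, dIP3, dCa_A, dh, dss, dEET, dn_bk, dVk, dK_p,
                     dCa_p, dk, dV, dn, dCa, dom, dyy, dx])


def derivatives(state, t: float, params: NVUParameters,
                perturbation: Sequence[float] = (0.0, 0.0, 0.0, 0.0)) -> np.ndarray:
    """Time derivatives of the 17 NVU states.

    Parameters
    ----------
    state : NVUState or array of shape (17,)
    t : float
        Time in seconds (the autonomous system ignores it; kept for the
        standard ODE signature).
    params : NVUParameters
    perturbation : length-4 sequence
        Additive pathway inputs ``(dJ_Ks, dI_T, dK_p_rate, dI_KV)``.

    Raises
    ------
    NumericalDomainError
        If any derivative is non-finite, naming the offending equation.
    """
    y = state.to_array() if isinstance(state, NVUState) else np.asarray(state, float)
    if y.shape != (N_STATES,):
        raise ConfigurationError(f"state must have {N_STATES} entries")
    dy = rhs(y, params, perturbation)
    if not np.all(np.isfinite(dy)):
        bad = STATE_NAMES[int(np.argmax(~np.isfinite(dy)))]
        raise NumericalDomainError(
            f"non-finite derivative in d{bad}/dt at state {y}", equation=bad)
    return dy


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Uniformly sampled solution of the NVU system."""

    t: np.ndarray                  # output times (s)
    states: np.ndarray             # (len(t), 17)
    info: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.states[:, STATE_NAMES.index(name)]

    def to_frame(self):
        import pandas as pd
        df = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        df.insert(0, "time", self.t)
        if "stimulus" in self.info:
            df["stimulus"] = self.info["stimulus"]
        return df


def simulate(initial, params: NVUParameters, stimulus=None, pathway: int = 1,
             filt=None, t_span=(0.0, 150.0), dt_out: float = 0.1,
             method: str = "LSODA", rtol: float = 1e-8, atol: float = 1e-9,
             state_bound: float = 1e6) -> Trajectory:
    """Integrate the NVU system under a (filtered) tDCS stimulus.

    ``stimulus`` is a :class:`~nvugrey.tdcs_input.StimulusWaveform` (or None
    for the unforced system); it is passed through the first-order vasoactive
    filter ``filt`` (default: unity gain, 20 ms time constant) and injected
    at the ``pathway`` site.  A pre-filtered perturbation series may be
    supplied directly as a ``(t, v)`` pair.  A stiff-capable adaptive solver
    is used; the system mixes fast membrane gating with multi-second vessel
    mechanics.
    """
    if pathway not in PATHWAY_INJECTION:
        raise ConfigurationError("pathway must be 1, 2, 3 or 4")
    y0 = initial.to_array() if isinstance(initial, NVUState) else np.asarray(initial, float)

    if stimulus is None:
        def v_of_t(t):
            return 0.0
        stim_samples = None
    elif isinstance(stimulus, tuple):
        t_st, v_st = (np.asarray(a, float) for a in stimulus)
        v_end = v_st[-1]

        def v_of_t(t):
            return float(np.interp(t, t_st, v_st, left=0.0, right=v_end))
        stim_samples = (t_st, v_st)
    else:
        from .tdcs_input import VasoactiveFilter, vasoactive_signal
        if filt is None:
            filt = VasoactiveFilter()
        t_st, v_st = vasoactive_signal(stimulus, filt)
        v_end = v_st[-1]

        def v_of_t(t):
            return float(np.interp(t, t_st, v_st, left=0.0, right=v_end))
        stim_samples = (t_st, v_st)

    idx = pathway - 1

    def f(t, y):
        pert = [0.0, 0.0, 0.0, 0.0]
        pert[idx] = v_of_t(t)
        return rhs(y, params, pert)

    t_eval = np.arange(t_span[0], t_span[1] + 0.5 * dt_out, dt_out)
    sol = solve_ivp(f, t_span, y0, method=method, rtol=rtol, atol=atol,
                    t_eval=t_eval, dense_output=False)
    if not sol.success:
        last = sol.t[-1] if sol.t.size else t_span[0]
        raise IntegrationError(f"integration failed: {sol.message}", last_time=last)
    states = sol.y.T
    if np.max(np.abs(states)) > state_bound:
        raise InstabilityError(
            f"state magnitude exceeded bound {state_bound:g}; system blew up")
    # probabilities are never clamped; out-of-range beyond tolerance is an error
    probs = states[:, list(PROBABILITY_STATES)]
    if probs.min() < -_PROB_TOL or probs.max() > 1.0 + _PROB_TOL:
        j = int(np.unravel_index(np.argmax(np.abs(probs - 0.5)), probs.shape)[1])
        raise NumericalDomainError(
            "probability state left [0,1] beyond tolerance during integration",
            equation=STATE_NAMES[PROBABILITY_STATES[j]])
    info = {"method": method, "rtol": rtol, "atol": atol, "pathway": pathway}
    if stim_samples is not None:
        info["stimulus"] = np.interp(sol.t, stim_samples[0], stim_samples[1],
                                     left=0.0, right=stim_samples[1][-1])
    return Trajectory(t=sol.t, states=states, info=info)


# ---------------------------------------------------------------------------
# Equilibrium
# ---------------------------------------------------------------------------

@dataclass
class EquilibriumResult:
    state: NVUState
    residual: float            # ||f(x*)||_inf
    strategy: str              # "newton" or "settle+newton" or "cycle-mean"
    oscillatory: bool = False  # True if the unforced baseline limit-cycles


def find_equilibrium(params: NVUParameters, guess: NVUState | None = None,
                     tol: float = 1e-8, settle_time: float = 300.0,
                     osc_tol: float = 1e-3) -> EquilibriumResult:
    """Locate the unforced baseline operating point.

    Newton/hybrid root-finding from ``guess``; on failure the system is
    settled by a long unforced simulation and the root search is retried.
    If the baseline is a limit cycle rather than a fixed point, the temporal
    mean of the cycle is returned with ``oscillatory=True``.
    """
    if guess is None:
        guess = default_guess()
    y0 = guess.to_array()

    def f(y):
        return rhs(y, params)

    sol = root(f, y0, method="hybr", tol=1e-13)
    if sol.success:
        res = float(np.max(np.abs(f(sol.x))))
        if res < tol and _physical(sol.x):
            return EquilibriumResult(_clamped_state(sol.x), res, "newton")

    # fallback: settle, then retry Newton
    traj = simulate(guess, params, stimulus=None, t_span=(0.0, settle_time),
                    dt_out=0.5, rtol=1e-9, atol=1e-10)
    y_settled = traj.states[-1]
    sol = root(f, y_settled, method="hybr", tol=1e-13)
    if sol.success:
        res = float(np.max(np.abs(f(sol.x))))
        if res < tol and _physical(sol.x):
            return EquilibriumResult(_clamped_state(sol.x), res, "settle+newton")

    # oscillatory baseline: report the cycle's temporal mean with a flag
    tail = simulate(NVUState.from_array(y_settled), params, stimulus=None,
                    t_span=(0.0, 120.0), dt_out=0.1, rtol=1e-9, atol=1e-10)
    x_series = tail["x"]
    if np.ptp(x_series) > osc_tol:
        mean_state = tail.states.mean(axis=0)
        res = float(np.max(np.abs(f(mean_state))))
        return EquilibriumResult(_clamped_state(mean_state), res,
                                 "cycle-mean", oscillatory=True)
    raise IntegrationError(
        "equilibrium search failed: no fixed point found and baseline "
        "is not oscillatory", last_time=settle_time)


def _physical(y: np.ndarray) -> bool:
    for i in PROBABILITY_STATES:
        if y[i] < -_PROB_TOL or y[i] > 1.0 + _PROB_TOL:
            return False
    for i in CONCENTRATION_STATES:
        if y[i] < -_PROB_TOL:
            return False
    return y[STATE_NAMES.index("x")] > 0


def _clamped_state(y: np.ndarray) -> NVUState:
    # probabilities within tolerance of [0,1] are snapped onto the bound
    y = y.copy()
    for i in PROBABILITY_STATES:
        if -_PROB_TOL <= y[i] < 0.0:
            y[i] = 0.0
        elif 1.0 < y[i] <= 1.0 + _PROB_TOL:
            y[i] = 1.0
    return NVUState.from_array(y)
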