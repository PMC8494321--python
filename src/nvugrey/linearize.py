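"""Jacobian linearization of the NVU system at its baseline operating point.

Produces per-pathway grey-box state-space models (input at the pathway's
injection state, output the vessel-circumference deviation) and rational
transfer functions.  The whole-system Jacobian is used; the compartmental
block structure is retained only as state-label metadata, which is
mathematically equivalent to a block-by-block linearization at a shared
operating point.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, ValidationError
from .nvu_model import (
    N_STATES,
    PATHWAY_INJECTION,
    STATE_NAMES,
    NVUParameters,
    NVUState,
    rhs,
)

#: compartment grouping of the state labels (metadata only)
COMPARTMENTS = {
    "synaptic": ("K_s",),
    "astrocyte": ("IP3", "Ca_A", "h", "ss", "EET", "n_bk", "Vk"),
    "perivascular": ("K_p", "Ca_p"),
    "smc": ("k", "V_smc", "n", "Ca_smc", "omega", "yy", "x"),
}

OUTPUT_STATE = "x"


@dataclass
class LinearModel:
    """Continuous-time state-space model linearized around an operating point.

    ``free_mask`` marks (A|B) entries that the grey-box refinement may
    adjust; structural zeros are frozen.
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    D: np.ndarray
    state_labels: tuple = STATE_NAMES
    pathway: int = 1
    free_mask: np.ndarray | None = None
    operating_point: NVUState | None = None

    def __post_init__(self):
        n = self.A.shape[0]
        if self.A.shape != (n, n) or self.B.shape[0] != n or self.C.shape[1] != n:
            raise ConfigurationError("inconsistent state-space dimensions")
        if np.any(self.D):
            raise ConfigurationError("direct term D must be zero")
        if not np.all(np.isfinite(np.linalg.eigvals(self.A))):
            raise ConfigurationError("A has non-finite eigenvalues")

    @property
    def order(self) -> int:
        return self.A.shape[0]

    def poles(self) -> np.ndarray:
        return np.linalg.eigvals(self.A)

    def zeros(self) -> np.ndarray:
        num, den = self.tf_coefficients()
        return np.roots(num)

    def tf_coefficients(self):
        """(num, den) polynomial coefficients of C (sI-A)^-1 B + D."""
        import scipy.signal as sps
        num, den = sps.ss2tf(self.A, self.B, self.C, self.D)
        num = np.atleast_2d(num)[0]
        # strip leading numerical zeros
        nz = np.flatnonzero(np.abs(num) > 1e-12 * max(1.0, np.abs(num).max()))
        num = num[nz[0]:] if nz.size else np.array([0.0])
        return num, den

    def frequency_response(self, w: np.ndarray) -> np.ndarray:
        """Exact resolvent response C (jwI - A)^-1 B at angular frequencies w."""
        n = self.order
        out = np.empty(len(w), dtype=complex)
        for i, wi in enumerate(w):
            out[i] = (self.C @ np.linalg.solve(1j * wi * np.eye(n) - self.A,
                                               self.B))[0, 0]
        return out

    def dc_gain(self) -> float:
        return float((self.C @ np.linalg.solve(-self.A, self.B))[0, 0])

    # serialization ---------------------------------------------------------
    def to_json(self, path=None) -> str:
        op = self.operating_point.to_array().tolist() if self.operating_point else None
        op_hash = (hashlib.sha256(json.dumps(op).encode()).hexdigest()[:16]
                   if op else None)
        doc = {
            "A": self.A.tolist(), "B": self.B.tolist(),
            "C": self.C.tolist(), "D": self.D.tolist(),
            "state_labels": list(self.state_labels),
            "pathway": self.pathway,
            "free_mask": self.free_mask.tolist() if self.free_mask is not None else None,
            "operating_point": op,
            "operating_point_hash": op_hash,
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "LinearModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        op = doc.get("operating_point")
        return cls(
            A=np.array(doc["A"]), B=np.array(doc["B"]),
            C=np.array(doc["C"]), D=np.array(doc["D"]),
            state_labels=tuple(doc["state_labels"]),
            pathway=doc.get("pathway", 1),
            free_mask=(np.array(doc["free_mask"])
                       if doc.get("free_mask") is not None else None),
            operating_point=(NVUState.from_array(op) if op is not None else None),
        )


def numerical_jacobian(params: NVUParameters, x0: np.ndarray,
                       rel_step: float = 1e-6) -> np.ndarray:
    """Central finite-difference Jacobian with per-state scaled steps."""
    J = np.empty((N_STATES, N_STATES))
    for j in range(N_STATES):
        h = rel_step * max(abs(x0[j]), 1e-3)
        yp = x0.copy(); yp[j] += h
        ym = x0.copy(); ym[j] -= h
        J[:, j] = (rhs(yp, params) - rhs(ym, params)) / (2.0 * h)
    return J


def default_free_mask(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Identifiable-parameter mask over the stacked (A|B) matrix.

    Diagonal rate entries of A and the structural nonzero of B are free
    (gains and decay rates the grey-box refinement adjusts); structural
    zeros stay frozen.
    """
    mask = np.zeros((A.shape[0], A.shape[1] + 1), dtype=bool)
    mask[np.arange(A.shape[0]), np.arange(A.shape[0])] = True
    mask[:, -1] = B[:, 0] != 0.0
    return mask


def jacobian_linearize(params: NVUParameters, x0, pathway: int,
                       equilibrium_tol: float = 1e-6,
                       rel_step: float = 1e-6,
                       cond_warn: float = 1e12) -> LinearModel:
    """Linearize the NVU system at equilibrium ``x0`` for one pathway.

    B carries a single structural nonzero at the pathway's injection state
    (scaled by 1/C where the nonlinear equation divides the injected
    current by a capacitance); C selects the vessel-circumference deviation.
    """
    if pathway not in PATHWAY_INJECTION:
        raise ConfigurationError("pathway must be 1, 2, 3 or 4")
    state = x0 if isinstance(x0, NVUState) else NVUState.from_array(np.asarray(x0))
    y0 = state.to_array()
    resid = np.max(np.abs(rhs(y0, params)))
    if resid > equilibrium_tol:
        raise ValidationError(
            f"x0 is not an equilibrium (||f||_inf = {resid:.3g} > "
            f"{equilibrium_tol:g}); run find_equilibrium first")

    A = numerical_jacobian(params, y0, rel_step)
    cond = np.linalg.cond(A)
    if cond > cond_warn:
        warnings.warn(f"ill-conditioned Jacobian (cond = {cond:.3g})",
                      RuntimeWarning, stacklevel=2)

    B = np.zeros((N_STATES, 1))
    inj = STATE_NAMES.index(PATHWAY_INJECTION[pathway])
    scale = {1: 1.0, 2: 1.0 / params.C_astr, 3: 1.0, 4: 1.0 / params.C_SMC}[pathway]
    B[inj, 0] = scale
    C = np.zeros((1, N_STATES))
    C[0, STATE_NAMES.index(OUTPUT_STATE)] = 1.0
    D = np.zeros((1, 1))
    return LinearModel(A=A, B=B, C=C, D=D, pathway=pathway,
                       free_mask=default_free_mask(A, B),
                       operating_point=state)


def to_transfer_function(model: LinearModel, cancel_tol: float = 1e-7):
    """Rational transfer function of a LinearModel with near cancellations removed.

    Pole-zero pairs closer than ``cancel_tol`` in relative distance are
    cancelled; the DC gain of the returned function matches the state-space
    model to high relative accuracy.

    Returns
    -------
    RationalTF
    """
    from .reduction import RationalTF

    poles = np.linalg.eigvals(model.A)
    num, den = model.tf_coefficients()
    zeros = np.roots(num) if len(num) > 1 else np.array([])
    gain = num[0] if len(num) else 0.0
    poles, zeros = _cancel_pairs(poles, zeros, cancel_tol)
    tf = RationalTF.from_pzk(zeros, poles, gain, label=f"pathway-{model.pathway}")
    # re-anchor the gain on the exact state-space DC value when finite
    dc_ss = model.dc_gain()
    dc_tf = tf.dc_gain()
    if np.isfinite(dc_ss) and abs(dc_tf) > 0 and abs(dc_ss) > 0:
        tf = RationalTF.from_pzk(tf.zeros, tf.poles, tf.gain * dc_ss / dc_tf,
                                 label=tf.label)
    return tf


def _cancel_pairs(poles: np.ndarray, zeros: np.ndarray, tol: float):
    poles = list(poles)
    zeros = list(zeros)
    out_z = []
    for z in zeros:
        dists = [abs(z - p) / max(abs(p), 1.0) for p in poles]
        if dists and min(dists) < tol:
            poles.pop(int(np.argmin(dists)))
        else:
            out_z.append(z)
    return np.array(poles), np.array(out_z)


def small_signal_error(params: NVUParameters, equilibrium, model: LinearModel,
                       stimulus, filt=None, t_span=(0.0, 150.0),
                       dt_out: float = 0.1) -> float:
    """Relative deviation between nonlinear and linearized responses.

    Simulates the full nonlinear system and the linear model under the same
    filtered stimulus and returns
    ``||x_nl - x_eq - y_lin|| / ||y_lin||`` (L2 over the window).  Used to
    verify first-order Taylor convergence as the stimulus amplitude shrinks.
    """
    from ._lsim import lsim_foh
    from .nvu_model import simulate
    from .tdcs_input import VasoactiveFilter, vasoactive_signal

    if filt is None:
        filt = VasoactiveFilter()
    eq_arr = (equilibrium.to_array() if isinstance(equilibrium, NVUState)
              else np.asarray(equilibrium))
    traj = simulate(NVUState.from_array(eq_arr), params, stimulus=stimulus,
                    pathway=model.pathway, filt=filt, t_span=t_span,
                    dt_out=dt_out)
    x_nl = traj["x"] - eq_arr[STATE_NAMES.index("x")]
    t_v, v = vasoactive_signal(stimulus, filt, t_end=t_span[1])
    v_i = np.interp(traj.t, t_v, v, left=0.0, right=v[-1])
    y_lin = lsim_foh(model.A, model.B, model.C, model.D, v_i, dt_out)
    denom = np.linalg.norm(y_lin)
    if denom == 0:
        return np.nan
    return float(np.linalg.norm(x_nl - y_lin) / denom)
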