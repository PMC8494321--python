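"""Reduced-order transfer-function analysis of the pathway models.

Contains:

* :class:`RationalTF` -- rational transfer functions kept in factored
  (zero/pole/gain) form, which stays numerically exact even when pole
  magnitudes span many decades;
* :func:`reference_tf` -- the minimal-realization transfer functions of the
  four perturbation pathways (nested factored forms with 11/3, 10/3, 8/2 and
  6/1 poles/zeros), optionally cascaded with the first-order vasoactive
  input filter;
* :func:`balanced_truncate` -- square-root balanced truncation with the
  2*sum(discarded Hankel singular values) error bound;
* :func:`impulse_peak_time` -- timing of the normalized impulse response;
* :func:`tf_estimate` -- fixed-order output-error estimation with a
  chi-square goodness-of-fit, and the nested difference-test comparison.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.linalg import schur, solve_continuous_lyapunov, svd
from scipy.optimize import least_squares
from scipy.stats import chi2 as chi2_dist

from ._lsim import lsim_foh
from .errors import ConfigurationError, InstabilityError, ValidationError
from .linearize import LinearModel


# ---------------------------------------------------------------------------
# Rational transfer functions
# ---------------------------------------------------------------------------

@dataclass
class RationalTF:
    """Rational transfer function in zero/pole/gain form.

    ``num``/``den`` expanded coefficient views (descending powers of s) are
    derived properties; the factored form is authoritative.
    """

    zeros: np.ndarray
    poles: np.ndarray
    gain: float
    label: str = ""

    def __post_init__(self):
        self.zeros = np.atleast_1d(np.asarray(self.zeros, dtype=complex))
        self.poles = np.atleast_1d(np.asarray(self.poles, dtype=complex))
        if self.zeros.size and self.poles.size and \
                len(self.zeros) > len(self.poles):
            raise ConfigurationError("numerator degree exceeds denominator degree")

    @classmethod
    def from_pzk(cls, zeros, poles, gain, label="") -> "RationalTF":
        return cls(np.asarray(zeros, dtype=complex),
                   np.asarray(poles, dtype=complex), float(gain), label)

    @classmethod
    def from_coefficients(cls, num, den, label="") -> "RationalTF":
        z, p, k = sps.tf2zpk(num, den)
        return cls(z, p, k, label)

    @property
    def num(self) -> np.ndarray:
        return np.real_if_close(self.gain * np.poly(self.zeros)).astype(float)

    @property
    def den(self) -> np.ndarray:
        return np.real_if_close(np.poly(self.poles)).astype(float)

    @property
    def n_poles(self) -> int:
        return len(self.poles)

    @property
    def n_zeros(self) -> int:
        return len(self.zeros)

    def is_stable(self, margin: float = 0.0) -> bool:
        return bool(np.all(self.poles.real < -margin))

    def dc_gain(self) -> float:
        num = self.gain * np.prod(-self.zeros) if self.n_zeros else self.gain
        den = np.prod(-self.poles) if self.n_poles else 1.0
        return float(np.real(num / den))

    def cascade(self, other: "RationalTF", label: str | None = None) -> "RationalTF":
        return RationalTF.from_pzk(
            np.concatenate([self.zeros, other.zeros]),
            np.concatenate([self.poles, other.poles]),
            self.gain * other.gain,
            label if label is not None else f"{self.label}*{other.label}")

    def frequency_response(self, w) -> np.ndarray:
        s = 1j * np.asarray(w, dtype=float)
        out = np.full(s.shape, self.gain, dtype=complex)
        for z in self.zeros:
            out *= (s - z)
        for p in self.poles:
            out /= (s - p)
        return out

    def impulse_response(self, t) -> np.ndarray:
        """Impulse response evaluated by partial fractions.

        Distinct poles (the generic case, including the factored reference
        forms whose pole magnitudes span seven decades) use the exact
        residue formula on the factored representation; repeated poles fall
        back to an expanded-coefficient residue computation.
        """
        t = np.asarray(t, dtype=float)
        p = self.poles
        if self.n_zeros >= self.n_poles:
            raise ValidationError("impulse response requires a strictly proper TF")
        scale = np.max(np.abs(p)) if p.size else 1.0
        distinct = True
        for i in range(len(p)):
            for j in range(i + 1, len(p)):
                if abs(p[i] - p[j]) < 1e-9 * scale:
                    distinct = False
        h = np.zeros_like(t, dtype=complex)
        if distinct:
            for i, pi in enumerate(p):
                r = self.gain * np.prod(pi - self.zeros) if self.n_zeros else self.gain
                others = np.delete(p, i)
                r = r / np.prod(pi - others) if others.size else r
                h += r * np.exp(pi * t)
        else:
            r, pp, _ = sps.residue(self.num, self.den)
            # group repeated poles: successive equal poles get t^m/m! factors
            mult = {}
            for ri, pi in zip(r, pp):
                key = complex(np.round(pi, 12))
                m = mult.get(key, 0)
                h += ri * t ** m * np.exp(pi * t) / max(1, math.factorial(m))
                mult[key] = m + 1
        return np.real(h)

    def to_statespace(self):
        return sps.zpk2ss(self.zeros, self.poles, self.gain)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "zeros_real": self.zeros.real.tolist(),
            "zeros_imag": self.zeros.imag.tolist(),
            "poles_real": self.poles.real.tolist(),
            "poles_imag": self.poles.imag.tolist(),
            "gain": self.gain,
            "num": self.num.tolist(),
            "den": self.den.tolist(),
        }

    @classmethod
    def from_dict(cls, d) -> "RationalTF":
        z = np.array(d["zeros_real"]) + 1j * np.array(d["zeros_imag"])
        p = np.array(d["poles_real"]) + 1j * np.array(d["poles_imag"])
        return cls(z, p, d["gain"], d.get("label", ""))


# ---------------------------------------------------------------------------
# Reference minimal-realization pathway transfer functions
# ---------------------------------------------------------------------------

# Factored forms of the reduced pathway models, nested from the SMC pathway
# outward.  The numerator/denominator assignment of each factor is the unique
# one consistent with the pole/zero counts (6/1, 8/2, 10/3, 11/3) of the four
# minimal realizations.
_TF4_ZEROS = (-2.962,)
_TF4_POLES_REAL = (-9.594e6, -20.69, -3.3, -0.2446)
_TF4_COMPLEX_PAIR = (1.0, 9.804, 95.24)      # s^2 + 9.804 s + 95.24
_TF3_EXTRA_ZEROS = (-2.371e7,)
_TF3_EXTRA_POLES = (-2.974e4, -1.0)
_TF2_EXTRA_ZEROS = (-46.5,)
_TF2_EXTRA_POLES = (-1.966, -15.08)
_TF1_EXTRA_POLES = (-0.4,)

EXPECTED_COUNTS = {1: (11, 3), 2: (10, 3), 3: (8, 2), 4: (6, 1)}


def reference_tf(pathway: int, include_input_filter: bool = False,
                 tau: float = 0.02, unit_peak: bool = False,
                 dt: float = 1e-3, horizon: float = 30.0) -> RationalTF:
    """Reference minimal-realization transfer function for a pathway.

    ``include_input_filter`` cascades the first-order vasoactive input
    filter (pole at -1/tau), raising the pole count by one (e.g. the
    perivascular pathway goes from 8 poles / 2 zeros to 9 poles / 2 zeros).
    ``unit_peak`` rescales the gain so the impulse-response peak is 1.
    """
    if pathway not in (1, 2, 3, 4):
        raise ConfigurationError("pathway must be 1, 2, 3 or 4")
    pair = np.roots(np.array(_TF4_COMPLEX_PAIR))
    zeros = list(_TF4_ZEROS)
    poles = list(_TF4_POLES_REAL) + list(pair)
    if pathway <= 3:
        zeros += list(_TF3_EXTRA_ZEROS)
        poles += list(_TF3_EXTRA_POLES)
    if pathway <= 2:
        zeros += list(_TF2_EXTRA_ZEROS)
        poles += list(_TF2_EXTRA_POLES)
    if pathway <= 1:
        poles += list(_TF1_EXTRA_POLES)
    tf = RationalTF.from_pzk(zeros, poles, 1.0, label=f"TF{pathway}")
    if include_input_filter:
        filt = RationalTF.from_pzk([], [-1.0 / tau], 1.0 / tau, label="input-filter")
        tf = tf.cascade(filt, label=f"TF{pathway}+filter")
    if unit_peak:
        t = np.arange(0.0, horizon, dt)
        peak = np.max(np.abs(tf.impulse_response(t)))
        tf = RationalTF.from_pzk(tf.zeros, tf.poles, tf.gain / peak, label=tf.label)
    return tf


def impulse_peak_time(tf: RationalTF, horizon: float = 30.0,
                      dt: float = 1e-3, refine: bool = True) -> float:
    """Time of the maximum of the normalized impulse response.

    Samples the impulse response at resolution ``dt`` over ``horizon``
    (normalizing the peak to 1) and refines the grid maximum by local
    parabolic interpolation.  Warns if the maximum sits on the horizon
    boundary (horizon shorter than settling).
    """
    if not tf.is_stable():
        raise InstabilityError("impulse peak time requires a stable TF")
    t = np.arange(0.0, horizon + 0.5 * dt, dt)
    h = tf.impulse_response(t)
    h = h / np.max(np.abs(h))
    i = int(np.argmax(h))
    if i in (0, len(t) - 1):
        warnings.warn("impulse peak on window boundary; increase horizon",
                      RuntimeWarning, stacklevel=2)
        return float(t[i])
    if refine:
        y0, y1, y2 = h[i - 1], h[i], h[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            return float(t[i] + 0.5 * dt * (y0 - y2) / denom)
    return float(t[i])


# ---------------------------------------------------------------------------
# Balanced truncation
# ---------------------------------------------------------------------------

@dataclass
class ReductionReport:
    hankel_singular_values: np.ndarray
    retained_order: int
    error_bound: float          # 2 * sum of discarded singular values
    dc_gain_error: float
    stable_split: bool = False  # True if an unstable/marginal part was carried


def _sqrt_factor(W: np.ndarray) -> np.ndarray:
    # symmetric positive-semidefinite square root factor W = L L^T
    Ws = 0.5 * (W + W.T)
    vals, vecs = np.linalg.eigh(Ws)
    vals = np.clip(vals, 0.0, None)
    return vecs * np.sqrt(vals)


def balanced_truncate(model, order: int | None = None,
                      tolerance: float | None = None,
                      stability_margin: float = 0.0,
                      allow_modal_split: bool = True):
    """Balanced-truncation model reduction with the standard error bound.

    ``model`` is a :class:`LinearModel` or an ``(A, B, C, D)`` tuple.
    Either a target ``order`` or an H-infinity ``tolerance`` (the reduction
    stops discarding once 2*sum(remaining HSV) would exceed it) must be
    given.  Marginal/unstable modes, if present, are split off by an ordered
    Schur decomposition, carried unreduced, and re-attached.
    """
    if isinstance(model, LinearModel):
        A, B, C, D = model.A, model.B, model.C, model.D
    else:
        A, B, C, D = (np.atleast_2d(np.asarray(m, float)) for m in model)
        B = B.reshape(A.shape[0], -1)
        C = C.reshape(-1, A.shape[0])
    n = A.shape[0]
    ev = np.linalg.eigvals(A)
    unstable = np.any(ev.real >= -stability_margin)
    split = False
    if unstable:
        if not allow_modal_split:
            raise InstabilityError(
                "balanced truncation requires an asymptotically stable model")
        return _reduce_with_split(A, B, C, D, order, tolerance, stability_margin)

    Wc = solve_continuous_lyapunov(A, -B @ B.T)
    Wo = solve_continuous_lyapunov(A.T, -C.T @ C)
    Lc = _sqrt_factor(Wc)
    Lo = _sqrt_factor(Wo)
    U, s, Vt = svd(Lo.T @ Lc)
    hsv = s.copy()
    if order is None:
        if tolerance is None:
            raise ConfigurationError("give either a target order or a tolerance")
        tails = 2.0 * np.cumsum(hsv[::-1])[::-1]   # tails[r] = 2*sum(hsv[r:])
        ok = np.flatnonzero(tails <= tolerance)
        order = int(ok[0]) if ok.size else n
    order = int(min(max(order, 1), n))
    # balancing transformation restricted to the retained subspace
    s_r = np.sqrt(hsv[:order])
    T = Lc @ Vt[:order].T / s_r
    Tinv = (U[:, :order] / s_r).T @ Lo.T
    Ar = Tinv @ A @ T
    Br = Tinv @ B
    Cr = C @ T
    bound = 2.0 * float(np.sum(hsv[order:]))
    dc_full = float((C @ np.linalg.solve(-A, B))[0, 0])
    dc_red = float((Cr @ np.linalg.solve(-Ar, Br))[0, 0])
    reduced = LinearModel(A=Ar, B=Br, C=Cr, D=np.zeros((C.shape[0], B.shape[1])),
                          state_labels=tuple(f"bal_{i}" for i in range(order)),
                          pathway=getattr(model, "pathway", 1))
    report = ReductionReport(hsv, order, bound, abs(dc_red - dc_full), split)
    return reduced, report


def _reduce_with_split(A, B, C, D, order, tolerance, margin):
    # ordered real Schur: stable block first, marginal/unstable carried whole
    T, Z, sdim = schur(A, output="real",
                       sort=lambda re, im: re < -max(margin, 1e-12))
    n = A.shape[0]
    if sdim == 0:
        raise InstabilityError("no stable subsystem to reduce")
    # block-diagonalize: solve Sylvester equation to decouple the two blocks
    A11 = T[:sdim, :sdim]
    A12 = T[:sdim, sdim:]
    A22 = T[sdim:, sdim:]
    from scipy.linalg import solve_sylvester
    X = solve_sylvester(A11, -A22, -A12)
    # similarity: state = Z @ [[I, X], [0, I]] @ [xs; xu]
    S = np.eye(n)
    S[:sdim, sdim:] = X
    V = Z @ S
    Vinv = np.linalg.inv(V)
    At = Vinv @ A @ V
    Bt = Vinv @ B
    Ct = C @ V
    As, Bs, Cs = At[:sdim, :sdim], Bt[:sdim], Ct[:, :sdim]
    Au, Bu, Cu = At[sdim:, sdim:], Bt[sdim:], Ct[:, sdim:]
    sub_order = None if order is None else max(order - (n - sdim), 1)
    red, rep = balanced_truncate((As, Bs, Cs, np.zeros((C.shape[0], B.shape[1]))),
                                 order=sub_order, tolerance=tolerance,
                                 allow_modal_split=False)
    r = red.order
    Ar = np.block([[red.A, np.zeros((r, n - sdim))],
                   [np.zeros((n - sdim, r)), Au]])
    Br = np.vstack([red.B, Bu])
    Cr = np.hstack([red.C, Cu])
    out = LinearModel(A=Ar, B=Br, C=Cr, D=np.zeros((C.shape[0], B.shape[1])),
                      state_labels=tuple(f"bal_{i}" for i in range(Ar.shape[0])))
    rep.stable_split = True
    rep.retained_order = Ar.shape[0]
    return out, rep


# ---------------------------------------------------------------------------
# Fixed-order transfer-function estimation
# ---------------------------------------------------------------------------

def chi2_goodness_of_fit(y: np.ndarray, yhat: np.ndarray) -> float:
    """Normalized residual sum: sum((y-yhat)^2) / sum((y-mean(y))^2).

    A dimensionless goodness-of-fit in [0, inf); 0 is a perfect fit and 1
    is no better than the output mean.  This is the quantity used in the
    nested difference test (scaled by the sample count there).
    """
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    denom = float(np.sum((y - y.mean()) ** 2))
    if denom == 0:
        raise ValidationError("chi-square GoF undefined for a constant output")
    return float(np.sum((y - yhat) ** 2) / denom)


@dataclass
class TFFit:
    tf: RationalTF
    mse: float
    chi2: float
    n_free: int
    converged: bool
    theta: np.ndarray = field(default=None, repr=False)


def _theta_to_tf(theta, n_poles, n_zeros):
    # stable-by-construction: poles = -exp(.), zeros free real, log-gain
    log_p = theta[:n_poles]
    zeros = theta[n_poles:n_poles + n_zeros]
    gain = theta[-1]
    poles = -np.exp(log_p)
    return RationalTF.from_pzk(zeros, poles, gain, label="tfest")


def _simulate_tf(tf: RationalTF, u: np.ndarray, dt: float) -> np.ndarray:
    A, B, C, D = tf.to_statespace()
    return lsim_foh(A, B, C, D, u, dt)


def tf_estimate(u: np.ndarray, y: np.ndarray, n_poles: int, n_zeros: int,
                dt: float = 0.1, init: RationalTF | None = None,
                max_nfev: int = 200, fit_slice: slice | None = None) -> TFFit:
    """Output-error estimation of a fixed-order rational transfer function.

    Poles are parameterized as ``-exp(theta)`` (real, stable by
    construction); zeros and the gain are free.  Initialized from ``init``
    when its real-pole projection is usable, otherwise from poles spread
    logarithmically over the data window.  Free-parameter count is
    ``n_poles + n_zeros + 1``.  ``fit_slice`` restricts the loss (and the
    reported MSE / goodness-of-fit) to a sub-window while simulating the
    full series.
    """
    u = np.asarray(u, float)
    y_full = np.asarray(y, float)
    if len(u) != len(y_full):
        raise ValidationError("input and output must share length")
    if n_zeros >= n_poles:
        raise ValidationError("need n_zeros < n_poles")
    if fit_slice is None:
        fit_slice = slice(0, len(y_full))
    y = y_full[fit_slice]

    if init is not None:
        p = np.sort(np.abs(init.poles.real))    # real projection of init poles
        p = np.clip(p, 1e-3, 1e4)
        if len(p) >= n_poles:
            p0 = p[:n_poles]
        else:
            p0 = np.concatenate([p, np.geomspace(10, 1e3, n_poles - len(p))])
        z = np.sort(np.abs(init.zeros.real))[:n_zeros]
        z0 = -np.clip(z, 1e-3, 1e6) if len(z) == n_zeros else \
            -np.geomspace(1.0, 10.0, n_zeros)
        g0 = init.gain if np.isfinite(init.gain) and init.gain != 0 else 1.0
    else:
        T = len(u) * dt
        p0 = np.geomspace(1.0 / T, 5.0 / dt / 10.0, n_poles)
        z0 = -np.geomspace(1.0 / T, 1.0, n_zeros) if n_zeros else np.array([])
        g0 = 1.0
    theta0 = np.concatenate([np.log(p0), z0, [g0]])

    # scale the gain so the initial simulation matches the output magnitude
    tf0 = _theta_to_tf(theta0, n_poles, n_zeros)
    y0 = _simulate_tf(tf0, u, dt)[fit_slice]
    scale = np.dot(y0, y) / max(np.dot(y0, y0), 1e-300)
    theta0[-1] *= scale if np.isfinite(scale) and scale != 0 else 1.0

    def resid(theta):
        yhat = _simulate_tf(_theta_to_tf(theta, n_poles, n_zeros), u, dt)
        return yhat[fit_slice] - y

    lb = np.concatenate([np.full(n_poles, -8.0), np.full(n_zeros, -1e7), [-1e9]])
    ub = np.concatenate([np.full(n_poles, 18.0), np.full(n_zeros, 1e7), [1e9]])
    sol = least_squares(resid, theta0, bounds=(lb, ub), max_nfev=max_nfev,
                        method="trf", x_scale="jac")
    tf = _theta_to_tf(sol.x, n_poles, n_zeros)
    yhat = _simulate_tf(tf, u, dt)[fit_slice]
    mse = float(np.mean((y - yhat) ** 2))
    chi2 = chi2_goodness_of_fit(y, yhat)
    return TFFit(tf=tf, mse=mse, chi2=chi2, n_free=n_poles + n_zeros + 1,
                 converged=bool(sol.success), theta=sol.x)


def nested_tf_comparison(fits: list[TFFit], n_samples: int,
                         alpha: float = 0.05) -> dict:
    """Difference-test comparison of nested fixed-order TF fits.

    ``fits`` must be ordered by increasing model order.  For each adjacent
    pair the statistic ``N * (chi2_small - chi2_large)`` is referred to a
    chi-square distribution with ``df = n_free_large - n_free_small``; the
    lowest-order model that is not significantly worse than the next larger
    one is selected.
    """
    if len(fits) < 2:
        raise ValidationError("need at least two nested fits")
    orders = [f.tf.n_poles for f in fits]
    if orders != sorted(orders):
        raise ValidationError("fits must be ordered by increasing pole count")
    trace = []
    selected = len(fits) - 1
    for i in range(len(fits) - 1):
        small, large = fits[i], fits[i + 1]
        stat = n_samples * max(small.chi2 - large.chi2, 0.0)
        df = max(large.n_free - small.n_free, 1)
        pval = float(chi2_dist.sf(stat, df))
        significant = pval < alpha
        trace.append({"orders": (small.tf.n_poles, large.tf.n_poles),
                      "stat": stat, "df": df, "p": pval,
                      "larger_preferred": significant})
        if not significant:
            selected = i
            break
    return {"selected_index": selected,
            "selected_order": fits[selected].tf.n_poles,
            "trace": trace}
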