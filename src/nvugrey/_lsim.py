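"""Fast uniform-step linear simulation with first-order-hold input.

Shared by the grey-box fitter and the reduction module.  The input is
treated as piecewise linear between samples (the tDCS trapezoid is exactly
that), discretized once through a single augmented matrix exponential.
For diagonalizable systems the update runs as one first-order IIR filter
per eigenmode (C-loop via scipy.signal.lfilter); a dense Python recursion
is kept as fallback for defective/ill-conditioned eigenbases.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm
from scipy.signal import lfilter


def foh_discretize(A: np.ndarray, B: np.ndarray, dt: float):
    """Exact first-order-hold discretization.

    Returns (Ad, B0, B1) such that
    ``x[k+1] = Ad x[k] + B0 u[k] + B1 u[k+1]``.
    """
    n, m = B.shape
    M = np.zeros((n + 2 * m, n + 2 * m))
    M[:n, :n] = A * dt
    M[:n, n:n + m] = B * dt
    M[n:n + m, n + m:] = np.eye(m)
    E = expm(M)
    G1 = E[:n, n:n + m]          # int_0^dt e^{A(dt-s)} B ds
    G2 = E[:n, n + m:]           # ramp-weighted integral / dt
    B1 = G2
    B0 = G1 - G2
    return E[:n, :n], B0, B1


def _lsim_modal(Ad, b0, b1, C, u):
    """Modal simulation: y[k] = sum_i c_i z_i[k] with scalar recursions
    z_i[k] = d_i z_i[k-1] + b0_i u[k-1] + b1_i u[k]."""
    d, V = np.linalg.eig(Ad)
    # refuse near-defective eigenbases
    cv = np.linalg.cond(V)
    if not np.isfinite(cv) or cv > 1e10:
        return None
    Vinv = np.linalg.inv(V)
    b0m = Vinv @ b0
    b1m = Vinv @ b1
    cm = (C @ V).ravel()
    y = np.zeros(len(u), dtype=complex)
    for i in range(len(d)):
        if cm[i] == 0 and (b0m[i] == 0 and b1m[i] == 0):
            continue
        z = lfilter([b1m[i], b0m[i]], [1.0, -d[i]], u)
        y += cm[i] * z
    return y.real


def lsim_foh(A, B, C, D, u, dt, x0=None):
    """Simulate ``y`` for a SISO/SIMO system under first-order-hold input."""
    A = np.atleast_2d(np.asarray(A, float))
    B = np.asarray(B, float).reshape(A.shape[0], -1)
    C = np.asarray(C, float).reshape(-1, A.shape[0])
    u = np.asarray(u, float)
    Ad, B0, B1 = foh_discretize(A, B, dt)
    n = A.shape[0]
    N = len(u)
    single_out = C.shape[0] == 1
    if x0 is None and single_out and B.shape[1] == 1:
        y = _lsim_modal(Ad, B0[:, 0], B1[:, 0], C, u)
        if y is not None:
            if D is not None and np.any(D):
                y = y + float(np.asarray(D).ravel()[0]) * u
            return y
    # dense fallback
    x = np.zeros(n) if x0 is None else np.asarray(x0, float)
    X = np.empty((N, n))
    X[0] = x
    b0 = B0[:, 0]
    b1 = B1[:, 0]
    for k in range(N - 1):
        x = Ad @ x + b0 * u[k] + b1 * u[k + 1]
        X[k + 1] = x
    y = X @ C.T
    if D is not None and np.any(D):
        y = y + u[:, None] * np.asarray(D, float).reshape(1, -1)
    return y[:, 0] if y.shape[1] == 1 else y
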