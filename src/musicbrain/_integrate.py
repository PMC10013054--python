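"""Adaptive Dormand-Prince RK45 core for the coupled FHN network.

JIT-compiled specialized integrator using the same embedded 5(4) pair and
error control as scipy's ``RK45``. Supports batched ensembles: the state is
(u, v) for N nodes times m ensemble members sharing the network and the
input signal but not initial conditions. The step size is controlled by the
worst member, so every member is integrated at least as accurately as a solo
run at the same tolerances.

The external input I(t) enters the activator equation of the auditory nodes
as a zero-order hold over a uniformly sampled array in dimensionless time;
outside the sample support the input is zero.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["fhn_rhs_flat", "integrate_fhn"]

# Dormand-Prince 5(4) tableau (identical to scipy.integrate.RK45)
_C = np.array([0.0, 1 / 5, 3 / 10, 4 / 5, 8 / 9, 1.0])
_A = np.array(
    [
        [0.0, 0.0, 0.0, 0.0, 0.0],
        [1 / 5, 0.0, 0.0, 0.0, 0.0],
        [3 / 40, 9 / 40, 0.0, 0.0, 0.0],
        [44 / 45, -56 / 15, 32 / 9, 0.0, 0.0],
        [19372 / 6561, -25360 / 2187, 64448 / 6561, -212 / 729, 0.0],
        [9017 / 3168, -355 / 33, 46732 / 5247, 49 / 176, -5103 / 18656],
    ]
)
_B = np.array([35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84])
# error weights: b5 - b4
_E = np.array(
    [71 / 57600, 0.0, -71 / 16695, 71 / 1920, -17253 / 339200, 22 / 525, -1 / 40]
)

SAFETY = 0.9
MIN_FACTOR = 0.2
MAX_FACTOR = 10.0


@njit(cache=True)
def fhn_rhs_flat(t, y, W, rowsum, Buu, Buv, Bvu, Bvv, eps, a, C, I_vals, I_dt, I_t0):
    """FHN network vector field on the flat state [u.ravel(), v.ravel()].

    y has length 2*N*m with u = y[:N*m].reshape(N, m). W is the adjacency
    pre-multiplied by the hemisphere-dependent coupling strengths, rowsum its
    row sums.
    """
    N = W.shape[0]
    m = y.shape[0] // (2 * N)
    u = y[: N * m].reshape(N, m)
    v = y[N * m :].reshape(N, m)
    su = W @ u
    sv = W @ v
    Iv = 0.0
    if I_vals.shape[0] > 0:
        idx = int((t - I_t0) / I_dt)
        if 0 <= idx < I_vals.shape[0]:
            Iv = I_vals[idx]
    dy = np.empty_like(y)
    du = dy[: N * m].reshape(N, m)
    dv = dy[N * m :].reshape(N, m)
    inv_eps = 1.0 / eps
    for k in range(N):
        rk = rowsum[k]
        ck = C[k] * Iv
        for j in range(m):
            pu = su[k, j] - rk * u[k, j]
            pv = sv[k, j] - rk * v[k, j]
            uk = u[k, j]
            du[k, j] = (uk - uk * uk * uk / 3.0 - v[k, j] + Buu * pu + Buv * pv + ck) * inv_eps
            dv[k, j] = uk + a + Bvu * pu + Bvv * pv
    return dy


@njit(cache=True)
def integrate_fhn(
    y0,
    t0,
    t1,
    t_eval,
    W,
    rowsum,
    Buu,
    Buv,
    Bvu,
    Bvv,
    eps,
    a,
    C,
    I_vals,
    I_dt,
    I_t0,
    rtol,
    atol,
):
    """Integrate the FHN network from t0 to t1, sampling the state at t_eval.

    Steps are clipped so that each requested output time is hit exactly
    (output spacing is far coarser than the natural step size, so this costs
    almost nothing). Returns (out, y_final, status); status 0 on success,
    1 on non-finite state, 2 if the step size underflows.
    """
    ny = y0.shape[0]
    n_out = t_eval.shape[0]
    out = np.empty((n_out, ny))
    y = y0.copy()
    t = t0
    i_out = 0
    # emit any output times at/before t0
    while i_out < n_out and t_eval[i_out] <= t0 + 1e-12:
        out[i_out] = y
        i_out += 1

    K = np.empty((7, ny))
    f = fhn_rhs_flat(t, y, W, rowsum, Buu, Buv, Bvu, Bvv, eps, a, C, I_vals, I_dt, I_t0)
    h = 1e-3
    while t < t1 - 1e-12:
        hit_output = False
        h_step = h
        if t + h_step >= t1:
            h_step = t1 - t
        if i_out < n_out and t + h_step >= t_eval[i_out] - 1e-12:
            h_step = t_eval[i_out] - t
            hit_output = True
        if h_step < 1e-14:
            return out, y, 2
        K[0] = f
        for s in range(1, 6):
            dy = np.zeros(ny)
            for q in range(s):
                aq = _A[s, q]
                if aq != 0.0:
                    dy += aq * K[q]
            K[s] = fhn_rhs_flat(
                t + _C[s] * h_step, y + h_step * dy,
                W, rowsum, Buu, Buv, Bvu, Bvv, eps, a, C, I_vals, I_dt, I_t0,
            )
        y_new = y.copy()
        for s in range(6):
            bs = _B[s]
            if bs != 0.0:
                y_new += (h_step * bs) * K[s]
        f_new = fhn_rhs_flat(
            t + h_step, y_new, W, rowsum, Buu, Buv, Bvu, Bvv, eps, a, C, I_vals, I_dt, I_t0
        )
        K[6] = f_new
        # scaled error norm as in scipy RK45
        err_sq = 0.0
        for i in range(ny):
            e = 0.0
            for s in range(7):
                es = _E[s]
                if es != 0.0:
                    e += es * K[s, i]
            e *= h_step
            sc = atol + rtol * max(abs(y[i]), abs(y_new[i]))
            err_sq += (e / sc) ** 2
        err = np.sqrt(err_sq / ny)
        if not np.isfinite(err):
            return out, y, 1
        if err < 1.0:
            t_new = t + h_step
            if hit_output:
                while i_out < n_out and t_eval[i_out] <= t_new + 1e-12:
                    out[i_out] = y_new
                    i_out += 1
            t = t_new
            y = y_new
            f = f_new
            if err == 0.0:
                factor = MAX_FACTOR
            else:
                factor = min(MAX_FACTOR, SAFETY * err ** (-0.2))
            h_next = h_step * factor
            if h_step < h:
                # step was clipped to an output time; keep the nominal step
                h_next = max(h_next, h)
            h = h_next
        else:
            h = h_step * max(MIN_FACTOR, SAFETY * err ** (-0.2))
    # emit any trailing outputs equal to t1
    while i_out < n_out and t_eval[i_out] <= t1 + 1e-12:
        out[i_out] = y
        i_out += 1
    return out, y, 0
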