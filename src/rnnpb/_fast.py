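"""Optional numba-compiled inner loop for the learning mode.

The kernel replays exactly the per-epoch schedule of the reference
implementation in :mod:`rnnpb.training` — sequence-by-sequence forward
pass, full-unroll backward pass, immediate per-weight gradient step and
adaptive PB update — over a stack of equal-length sequences.  It exists
purely for speed; :func:`rnnpb.training.train` falls back to the pure
numpy path when numba is unavailable or sequence lengths differ, and a
regression test keeps the two paths numerically aligned.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is normally present
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap

A = 1.7159
B = 2.0 / 3.0


@njit(cache=True)
def epoch_kernel(
    values,  # (S, T, n_in) stacked sequences
    w_d, v_d, wbar_d, w_v, v_v, wbar_v, u_d, u_v,  # weights, updated in place
    e_w_d, e_v_d, e_wbar_d, e_w_v, e_v_v, e_wbar_v, e_u_d, e_u_v,  # eta arrays
    rho1, rho2,  # (S, n_pb1), (S, n_pb2), updated in place
    m_gamma,
    pb_update,
    g_w_d, g_v_d, g_wbar_d, g_w_v, g_v_v, g_wbar_v, g_u_d, g_u_v,  # epoch-grad out
):
    S, T, n_in = values.shape
    n_steps = T - 1
    n_d = w_d.shape[0]
    n_v = w_v.shape[0]
    cost = 0.0
    for s in range(S):
        seq = values[s]
        act1 = A * np.tanh(B * rho1[s])
        act2 = A * np.tanh(B * rho2[s])
        pb_d = np.dot(wbar_d, act2)
        pb_v = np.dot(wbar_v, act1)

        s_d = np.empty((n_steps, n_d))
        s_v = np.empty((n_steps, n_v))
        s_d_prev = np.zeros((n_steps, n_d))
        s_v_prev = np.zeros((n_steps, n_v))
        sd = np.zeros(n_d)
        sv = np.zeros(n_v)
        for t in range(n_steps):
            s_d_prev[t] = sd
            s_v_prev[t] = sv
            yd = np.dot(w_d, seq[t]) + np.dot(v_d, sd) + pb_d
            yv = np.dot(w_v, seq[t]) + np.dot(v_v, sv) + pb_v
            sd = A * np.tanh(B * yd)
            sv = A * np.tanh(B * yv)
            s_d[t] = sd
            s_v[t] = sv
        x_d = np.dot(s_d, u_d.T)
        x_v = np.dot(s_v, u_v.T)
        err = seq[1:] - x_d * x_v
        for t in range(n_steps):
            for k in range(n_in):
                cost += 0.5 * err[t, k] * err[t, k]

        g_xd = -err * x_v
        g_xv = -err * x_d
        dy_d = np.empty((n_steps, n_d))
        dy_v = np.empty((n_steps, n_v))
        carry_d = np.zeros(n_d)
        carry_v = np.zeros(n_v)
        for t in range(n_steps - 1, -1, -1):
            gd = np.dot(u_d.T, g_xd[t]) + carry_d
            gv = np.dot(u_v.T, g_xv[t]) + carry_v
            # f'(y) expressed through the activation
            dy_d[t] = gd * (A * B * (1.0 - (s_d[t] / A) ** 2))
            dy_v[t] = gv * (A * B * (1.0 - (s_v[t] / A) ** 2))
            carry_d = np.dot(v_d.T, dy_d[t])
            carry_v = np.dot(v_v.T, dy_v[t])

        inputs = seq[:-1]
        gr_u_d = np.dot(g_xd.T, s_d)
        gr_u_v = np.dot(g_xv.T, s_v)
        gr_w_d = np.dot(dy_d.T, inputs)
        gr_w_v = np.dot(dy_v.T, inputs)
        gr_v_d = np.dot(dy_d.T, s_d_prev)
        gr_v_v = np.dot(dy_v.T, s_v_prev)
        sum_dy_d = dy_d.sum(axis=0)
        sum_dy_v = dy_v.sum(axis=0)
        gr_wbar_d = np.outer(sum_dy_d, act2)
        gr_wbar_v = np.outer(sum_dy_v, act1)

        # PB deltas (negative-gradient convention), summed over steps
        fp1 = A * B * (1.0 - (act1 / A) ** 2)
        fp2 = A * B * (1.0 - (act2 / A) ** 2)
        total1 = -np.dot(wbar_v.T, sum_dy_v) * fp1
        total2 = -np.dot(wbar_d.T, sum_dy_d) * fp2

        u_d -= e_u_d * gr_u_d
        u_v -= e_u_v * gr_u_v
        w_d -= e_w_d * gr_w_d
        w_v -= e_w_v * gr_w_v
        v_d -= e_v_d * gr_v_d
        v_v -= e_v_v * gr_v_v
        wbar_d -= e_wbar_d * gr_wbar_d
        wbar_v -= e_wbar_v * gr_wbar_v
        g_u_d += gr_u_d
        g_u_v += gr_u_v
        g_w_d += gr_w_d
        g_w_v += gr_w_v
        g_v_d += gr_v_d
        g_v_v += gr_v_v
        g_wbar_d += gr_wbar_d
        g_wbar_v += gr_wbar_v

        if pb_update:
            gamma1 = m_gamma * np.abs(total1 / n_steps)
            gamma2 = m_gamma * np.abs(total2 / n_steps)
            rho1[s] += gamma1 * total1
            rho2[s] += gamma2 * total2
    return cost
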