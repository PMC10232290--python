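"""Batched fixed-step RK4 integration of the microcircuit.

Two interchangeable backends: a numba-compiled kernel (used when numba
imports cleanly) and a vectorized numpy implementation.  Both integrate
``B`` parameter sets simultaneously, which is what makes the
finite-difference Jacobians of the inversion scheme affordable.  Tests
assert the two backends agree to machine precision.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore
        def wrap(f):
            return f

        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(cache=False)
def _deriv_nb(x, G, tauk, u, ip, VL, VE, VI, C, cL, thr, slope, mga, mgb, f, dx):
    # x, dx are flat 24-vectors: V in [0:6], g in [6:24] population-major
    for q in range(6):
        f[q] = 1.0 / (1.0 + np.exp(-slope * (x[q] - thr)))
    for p in range(6):
        sA = 0.0
        sN = 0.0
        sG = 0.0
        for q in range(6):
            sA += G[p, q, 0] * f[q]
            sN += G[p, q, 1] * f[q]
            sG += G[p, q, 2] * f[q]
        V = x[p]
        gA = x[6 + 3 * p]
        gN = x[7 + 3 * p]
        gG = x[8 + 3 * p]
        m = 1.0 / (1.0 + mgb * np.exp(-mga * V))
        drive = (
            cL * (VL - V)
            + gA * (VE - V)
            + gN * m * (VE - V)
            + gG * (VI - V)
        )
        if p == ip:
            drive += u
        dx[p] = drive / C
        dx[6 + 3 * p] = (sA - gA) / tauk[0]
        dx[7 + 3 * p] = (sN - gN) / tauk[1]
        dx[8 + 3 * p] = (sG - gG) / tauk[2]


@njit(cache=False)
def _rk4_batch_nb(V0, g0, G, tauk, uamp, ukern, ip, VL, VE, VI, C, cL, thr, slope,
                  mga, mgb, dt, n_steps, stride, out_V, out_g):
    B = V0.shape[0]
    x = np.empty(24)
    xt = np.empty(24)
    f = np.empty(6)
    k1 = np.empty(24)
    k2 = np.empty(24)
    k3 = np.empty(24)
    k4 = np.empty(24)
    for b in range(B):
        for p in range(6):
            x[p] = V0[b, p]
            for k in range(3):
                x[6 + 3 * p + k] = g0[b, p, k]
        for p in range(6):
            out_V[b, 0, p] = x[p]
            for k in range(3):
                out_g[b, 0, p, k] = x[6 + 3 * p + k]
        o = 1
        for s in range(n_steps):
            u0 = uamp[b] * ukern[2 * s]
            uh = uamp[b] * ukern[2 * s + 1]
            u1 = uamp[b] * ukern[2 * s + 2]
            _deriv_nb(x, G[b], tauk[b], u0, ip, VL, VE, VI, C, cL, thr, slope, mga, mgb, f, k1)
            for i in range(24):
                xt[i] = x[i] + 0.5 * dt * k1[i]
            _deriv_nb(xt, G[b], tauk[b], uh, ip, VL, VE, VI, C, cL, thr, slope, mga, mgb, f, k2)
            for i in range(24):
                xt[i] = x[i] + 0.5 * dt * k2[i]
            _deriv_nb(xt, G[b], tauk[b], uh, ip, VL, VE, VI, C, cL, thr, slope, mga, mgb, f, k3)
            for i in range(24):
                xt[i] = x[i] + dt * k3[i]
            _deriv_nb(xt, G[b], tauk[b], u1, ip, VL, VE, VI, C, cL, thr, slope, mga, mgb, f, k4)
            for i in range(24):
                x[i] = x[i] + (dt / 6.0) * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
            if (s + 1) % stride == 0:
                for p in range(6):
                    out_V[b, o, p] = x[p]
                    for k in range(3):
                        out_g[b, o, p, k] = x[6 + 3 * p + k]
                o += 1


def _deriv_np(V, g, G, tauk, u_col, consts):
    VL, VE, VI, C, cL, thr, slope, mga, mgb = consts
    with np.errstate(over="ignore"):
        f = 1.0 / (1.0 + np.exp(-slope * (V - thr)))      # (B, 6)
    sigma = np.einsum("btsk,bs->btk", G, f)               # (B, 6, 3)
    with np.errstate(over="ignore"):
        m = 1.0 / (1.0 + mgb * np.exp(-mga * V))
    dV = (
        cL * (VL - V)
        + g[:, :, 0] * (VE - V)
        + g[:, :, 1] * m * (VE - V)
        + g[:, :, 2] * (VI - V)
        + u_col
    ) / C
    dg = (sigma - g) / tauk[:, None, :]
    return dV, dg


def _rk4_batch_np(V0, g0, G, tauk, uamp, ukern, ip, VL, VE, VI, C, cL, thr, slope,
                  mga, mgb, dt, n_steps, stride, out_V, out_g):
    consts = (VL, VE, VI, C, cL, thr, slope, mga, mgb)
    B = V0.shape[0]
    V = V0.copy()
    g = g0.copy()
    out_V[:, 0] = V
    out_g[:, 0] = g
    ucol = np.zeros((B, 6))
    o = 1
    for s in range(n_steps):
        u0 = uamp * ukern[2 * s]
        uh = uamp * ukern[2 * s + 1]
        u1 = uamp * ukern[2 * s + 2]
        ucol[:, ip] = u0
        k1V, k1g = _deriv_np(V, g, G, tauk, ucol, consts)
        ucol[:, ip] = uh
        k2V, k2g = _deriv_np(V + 0.5 * dt * k1V, g + 0.5 * dt * k1g, G, tauk, ucol, consts)
        k3V, k3g = _deriv_np(V + 0.5 * dt * k2V, g + 0.5 * dt * k2g, G, tauk, ucol, consts)
        ucol[:, ip] = u1
        k4V, k4g = _deriv_np(V + dt * k3V, g + dt * k3g, G, tauk, ucol, consts)
        V = V + (dt / 6.0) * (k1V + 2.0 * k2V + 2.0 * k3V + k4V)
        g = g + (dt / 6.0) * (k1g + 2.0 * k2g + 2.0 * k3g + k4g)
        if (s + 1) % stride == 0:
            out_V[:, o] = V
            out_g[:, o] = g
            o += 1


def rk4_batch(V0, g0, G, tauk, uamp, ukern, ip, consts, dt, n_steps, stride,
              backend: str = "auto"):
    """Integrate a batch of circuits; returns (out_V, out_g).

    consts = (V_L, V_E, V_I, C, cL, threshold, slope, mg_alpha, mg_beta).
    ``ukern`` holds the input kernel sampled at half-step resolution
    (length 2*n_steps+1); per-batch input is uamp[b]*ukern.
    """
    B = V0.shape[0]
    n_out = n_steps // stride + 1
    out_V = np.empty((B, n_out, 6))
    out_g = np.empty((B, n_out, 6, 3))
    args = (
        np.ascontiguousarray(V0, dtype=np.float64),
        np.ascontiguousarray(g0, dtype=np.float64),
        np.ascontiguousarray(G, dtype=np.float64),
        np.ascontiguousarray(tauk, dtype=np.float64),
        np.ascontiguousarray(uamp, dtype=np.float64),
        np.ascontiguousarray(ukern, dtype=np.float64),
        int(ip), *[float(c) for c in consts],
        float(dt), int(n_steps), int(stride), out_V, out_g,
    )
    use_numba = HAVE_NUMBA if backend == "auto" else (backend == "numba")
    if use_numba:
        _rk4_batch_nb(*args)
    else:
        _rk4_batch_np(*args)
    return out_V, out_g
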