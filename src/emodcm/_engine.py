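"""JIT-compiled RK4 integrator for the neural + hemodynamic system.

State layout (n = number of regions): ``x = [z, s, lf, lv, lq]`` with
``z`` neuronal activity, ``s`` vasodilatory signal, and the hemodynamic
states inflow ``f``, volume ``v`` and deoxyhemoglobin ``q`` integrated
in log coordinates (lf = ln f, ...).  Log-space integration keeps the
states positive by construction and is markedly more stable at coarse
microtime steps; the underlying ODE is unchanged.

The same kernel optionally propagates forward sensitivities
``S = dx/dtheta`` for a list of free parameters, encoded by
``(kind, i1, i2, i3)`` integer tuples:

==== ======================== ==============================
kind parameter                index meaning
==== ======================== ==============================
0    A[i1, i2]                endogenous coupling
1    B[i3][i1, i2]            input-modulated coupling
2    C[i1, i2]                driving gain
3    D[i3][i1, i2]            activity-gated coupling
4    self-decay log-scale i1  A[i1,i1] = -0.5*exp(theta)
5    log kappa, region i1
6    log tau, region i1
==== ======================== ==============================

The sensitivity ODE ``dS/dt = J_x S + J_theta`` exploits the sparsity of
the hemodynamic Jacobian explicitly; only the neural block is dense.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a declared dependency
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        def wrap(fn):
            return fn
        return wrap


@njit(cache=True)
def _deriv(x, S, u0, u1, u2, A, Bn, Bp, C, Dg, gates,
           kappa, gamma, tau, alpha, rho,
           kinds, i1, i2, i3, with_sens, dx, dS):
    n = A.shape[0]
    z = x[0:n]
    s = x[n:2 * n]
    c_ln = np.log(1.0 - rho)
    ia = 1.0 / alpha

    # effective coupling at this instant
    M = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            M[i, j] = A[i, j] + u1 * Bn[i, j] + u2 * Bp[i, j]
    for gi in range(gates.shape[0]):
        g = gates[gi]
        zg = z[g]
        for i in range(n):
            for j in range(n):
                M[i, j] += zg * Dg[g, i, j]

    f = np.empty(n)
    v = np.empty(n)
    q = np.empty(n)
    dlv = np.empty(n)
    dlq = np.empty(n)
    for i in range(n):
        # clamp log states: wild RK4 trial stages must stay evaluable;
        # the integrator's admissibility guard rejects them afterwards
        lf = min(max(x[2 * n + i], -8.0), 8.0)
        lv = min(max(x[3 * n + i], -8.0), 8.0)
        lq = min(max(x[4 * n + i], -8.0), 8.0)
        f[i] = np.exp(lf)
        v[i] = np.exp(lv)
        q[i] = np.exp(lq)
    for i in range(n):
        acc = C[i, 0] * u0 + C[i, 1] * u1 + C[i, 2] * u2
        for j in range(n):
            acc += M[i, j] * z[j]
        dx[i] = acc
        dx[n + i] = z[i] - kappa[i] * s[i] - gamma * (f[i] - 1.0)
        dx[2 * n + i] = s[i] / f[i]
        fv = v[i] ** ia
        dlv[i] = (f[i] - fv) / (tau[i] * v[i])
        ef = np.exp(c_ln / f[i])
        dlq[i] = (f[i] * (1.0 - ef) / (rho * q[i]) - fv / v[i]) / tau[i]
        dx[3 * n + i] = dlv[i]
        dx[4 * n + i] = dlq[i]

    if not with_sens:
        return

    # Jacobian of the neural block: M plus gating feedback columns
    JM = M.copy()
    for gi in range(gates.shape[0]):
        g = gates[gi]
        for i in range(n):
            acc = 0.0
            for j in range(n):
                acc += Dg[g, i, j] * z[j]
            JM[i, g] += acc

    # hemodynamic partials in log coordinates
    ps_lf = np.empty(n)   # d(ds)/d lf
    plf_s = np.empty(n)   # d(dlf)/d s
    plf_lf = np.empty(n)  # d(dlf)/d lf
    plv_lf = np.empty(n)
    plv_lv = np.empty(n)
    plq_lf = np.empty(n)
    plq_lv = np.empty(n)
    plq_lq = np.empty(n)
    for i in range(n):
        ps_lf[i] = -gamma * f[i]
        plf_s[i] = 1.0 / f[i]
        plf_lf[i] = -s[i] / f[i]
        fv1 = v[i] ** (ia - 1.0)
        plv_lf[i] = f[i] / (tau[i] * v[i])
        plv_lv[i] = (-f[i] / v[i] - (ia - 1.0) * fv1) / tau[i]
        ef = np.exp(c_ln / f[i])
        plq_lf[i] = f[i] * (1.0 - ef * (1.0 - c_ln / f[i])) / (rho * q[i] * tau[i])
        plq_lv[i] = -(ia - 1.0) * fv1 / tau[i]
        plq_lq[i] = -f[i] * (1.0 - ef) / (rho * q[i] * tau[i])

    P = kinds.shape[0]
    for p in range(P):
        for i in range(n):
            acc = 0.0
            for j in range(n):
                acc += JM[i, j] * S[j, p]
            dS[i, p] = acc
        for i in range(n):
            dS[n + i, p] = (S[i, p] - kappa[i] * S[n + i, p]
                            + ps_lf[i] * S[2 * n + i, p])
            dS[2 * n + i, p] = (plf_s[i] * S[n + i, p]
                                + plf_lf[i] * S[2 * n + i, p])
            dS[3 * n + i, p] = (plv_lf[i] * S[2 * n + i, p]
                                + plv_lv[i] * S[3 * n + i, p])
            dS[4 * n + i, p] = (plq_lf[i] * S[2 * n + i, p]
                                + plq_lv[i] * S[3 * n + i, p]
                                + plq_lq[i] * S[4 * n + i, p])
        k = kinds[p]
        a = i1[p]
        b = i2[p]
        c = i3[p]
        if k == 0:
            dS[a, p] += z[b]
        elif k == 1:
            if c == 1:
                dS[a, p] += u1 * z[b]
            else:
                dS[a, p] += u2 * z[b]
        elif k == 2:
            if b == 0:
                dS[a, p] += u0
            elif b == 1:
                dS[a, p] += u1
            else:
                dS[a, p] += u2
        elif k == 3:
            dS[a, p] += z[c] * z[b]
        elif k == 4:
            dS[a, p] += A[a, a] * z[a]
        elif k == 5:
            dS[n + a, p] += -kappa[a] * s[a]
        elif k == 6:
            dS[3 * n + a, p] += -dlv[a]
            dS[4 * n + a, p] += -dlq[a]


@njit(cache=True)
def rk4_run(A, Bn, Bp, C, Dg, gates, kappa, gamma, tau, alpha, rho, v0,
            u, dt, keep, n_scans, kinds, i1, i2, i3, with_sens):
    """Integrate one run from rest; sample BOLD (and its parameter
    Jacobian when ``with_sens``) at scan times ``t = n * keep * dt``.

    Returns ``(y, Jy, status)`` where ``status`` is -1 on success or the
    offending microtime step index when the state left its admissible
    domain (|z| > 10 or a log hemodynamic state beyond +-3).
    """
    n = A.shape[0]
    nx = 5 * n
    P = kinds.shape[0] if with_sens else 0
    x = np.zeros(nx)          # rest: z = s = 0, lf = lv = lq = 0
    S = np.zeros((nx, P))
    y = np.zeros((n_scans, n))
    Jy = np.zeros((n_scans, n, P))
    k1c = 7.0 * rho
    k2c = 2.0
    k3c = 2.0 * rho - 0.2

    dx1 = np.zeros(nx)
    dx2 = np.zeros(nx)
    dx3 = np.zeros(nx)
    dx4 = np.zeros(nx)
    dS1 = np.zeros((nx, P))
    dS2 = np.zeros((nx, P))
    dS3 = np.zeros((nx, P))
    dS4 = np.zeros((nx, P))
    xt = np.zeros(nx)
    St = np.zeros((nx, P))

    # scan 0 is the resting baseline: y = 0, Jy = 0
    for scan in range(1, n_scans):
        for sub in range(keep):
            step = (scan - 1) * keep + sub
            u0 = u[step, 0]
            u1v = u[step, 1]
            u2v = u[step, 2]
            _deriv(x, S, u0, u1v, u2v, A, Bn, Bp, C, Dg, gates, kappa, gamma,
                   tau, alpha, rho, kinds, i1, i2, i3, with_sens, dx1, dS1)
            for ii in range(nx):
                xt[ii] = x[ii] + 0.5 * dt * dx1[ii]
            for ii in range(nx):
                for pp in range(P):
                    St[ii, pp] = S[ii, pp] + 0.5 * dt * dS1[ii, pp]
            _deriv(xt, St, u0, u1v, u2v, A, Bn, Bp, C, Dg, gates, kappa, gamma,
                   tau, alpha, rho, kinds, i1, i2, i3, with_sens, dx2, dS2)
            for ii in range(nx):
                xt[ii] = x[ii] + 0.5 * dt * dx2[ii]
            for ii in range(nx):
                for pp in range(P):
                    St[ii, pp] = S[ii, pp] + 0.5 * dt * dS2[ii, pp]
            _deriv(xt, St, u0, u1v, u2v, A, Bn, Bp, C, Dg, gates, kappa, gamma,
                   tau, alpha, rho, kinds, i1, i2, i3, with_sens, dx3, dS3)
            for ii in range(nx):
                xt[ii] = x[ii] + dt * dx3[ii]
            for ii in range(nx):
                for pp in range(P):
                    St[ii, pp] = S[ii, pp] + dt * dS3[ii, pp]
            _deriv(xt, St, u0, u1v, u2v, A, Bn, Bp, C, Dg, gates, kappa, gamma,
                   tau, alpha, rho, kinds, i1, i2, i3, with_sens, dx4, dS4)
            h6 = dt / 6.0
            for ii in range(nx):
                x[ii] += h6 * (dx1[ii] + 2.0 * dx2[ii] + 2.0 * dx3[ii] + dx4[ii])
            for ii in range(nx):
                for pp in range(P):
                    S[ii, pp] += h6 * (dS1[ii, pp] + 2.0 * dS2[ii, pp]
                                       + 2.0 * dS3[ii, pp] + dS4[ii, pp])
            for i in range(n):
                if np.abs(x[i]) > 10.0 or not np.isfinite(x[i]):
                    return y, Jy, step
                if (np.abs(x[2 * n + i]) > 3.0 or np.abs(x[3 * n + i]) > 3.0
                        or np.abs(x[4 * n + i]) > 3.0):
                    return y, Jy, step
        for i in range(n):
            vv = np.exp(x[3 * n + i])
            qq = np.exp(x[4 * n + i])
            y[scan, i] = v0 * (k1c * (1.0 - qq) + k2c * (1.0 - qq / vv)
                               + k3c * (1.0 - vv))
            if with_sens:
                dyv = v0 * (k2c * qq / (vv * vv) - k3c) * vv
                dyq = -v0 * (k1c + k2c / vv) * qq
                for pp in range(P):
                    Jy[scan, i, pp] = (dyv * S[3 * n + i, pp]
                                       + dyq * S[4 * n + i, pp])
    return y, Jy, -1
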