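"""Numba-compiled inner loops: network RHS, fixed-step RK4, divergence runs.

State layout is node-major: ``(x_1, y_1, z_1, ..., x_N, y_N, z_N)``.
Kernels are deliberately allocation-free inside the step loop so that long
horizons (10^5-10^6 steps) run in seconds.  All public error handling lives
in the Python wrappers; kernels only report a status code:

* ``0`` - completed
* ``1`` - non-finite state encountered (blow-up)
* ``2`` - a component fell below -1e-9 (model violation)
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: components in (-NEG_CLAMP, 0) are clamped to 0; beyond is an error
NEG_CLAMP = 1e-9
#: exp(-z/eps) is treated as 0 once z/eps exceeds this (overflow guard)
EXP_ARG_MAX = 700.0


@njit(cache=True, fastmath=True)
def rhs(v, alphas, A, B, sigma, b, d, r, K, c, eps, out):
    """Network vector field, Eqs of the coupled model, written into ``out``."""
    n_nodes = alphas.shape[0]
    for i in range(n_nodes):
        x = v[3 * i]
        y = v[3 * i + 1]
        z = v[3 * i + 2]
        ext = 0.0
        dif = 0.0
        for j in range(n_nodes):
            ext += v[3 * j] * A[i, j]
            dif += v[3 * j] * B[i, j]
        arg = -z / eps
        if arg < -EXP_ARG_MAX:
            fac = 1.0
        elif arg > EXP_ARG_MAX:
            fac = 1.0 - np.exp(EXP_ARG_MAX)
        else:
            fac = 1.0 - np.exp(arg)
        out[3 * i] = (b * z / (x + eps) - d * x) * fac - sigma * dif
        e = alphas[i] * x * y * ext
        out[3 * i + 1] = r * y * (1.0 - y / K) - e
        out[3 * i + 2] = e - c * z


@njit(cache=True, fastmath=True)
def _step(v, alphas, A, B, sigma, b, d, r, K, c, eps, dt, k1, k2, k3, k4, tmp):
    """One classical RK4 step in place.  Returns a status code."""
    n = v.shape[0]
    rhs(v, alphas, A, B, sigma, b, d, r, K, c, eps, k1)
    for i in range(n):
        tmp[i] = v[i] + 0.5 * dt * k1[i]
    rhs(tmp, alphas, A, B, sigma, b, d, r, K, c, eps, k2)
    for i in range(n):
        tmp[i] = v[i] + 0.5 * dt * k2[i]
    rhs(tmp, alphas, A, B, sigma, b, d, r, K, c, eps, k3)
    for i in range(n):
        tmp[i] = v[i] + dt * k3[i]
    rhs(tmp, alphas, A, B, sigma, b, d, r, K, c, eps, k4)
    status = 0
    for i in range(n):
        v[i] += dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
        if not np.isfinite(v[i]):
            status = 1
        elif v[i] < 0.0:
            if v[i] > -NEG_CLAMP:
                v[i] = 0.0
            else:
                status = 2
    return status


@njit(cache=True, fastmath=True)
def rk4_run(v0, alphas, A, B, sigma, b, d, r, K, c, eps, dt, n_burn, n_steps, stride):
    """Integrate ``n_burn`` discarded steps then ``n_steps`` recorded ones.

    Returns ``(status, failed_step, states)`` where ``states`` holds every
    ``stride``-th state after the burn-in, including the state at the end of
    the burn-in itself (so ``states.shape[0] == n_steps // stride + 1``).
    ``failed_step`` is the global step index at failure, or -1.
    """
    n = v0.shape[0]
    k1 = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    tmp = np.empty(n)
    v = v0.copy()
    for s in range(n_burn):
        st = _step(v, alphas, A, B, sigma, b, d, r, K, c, eps, dt, k1, k2, k3, k4, tmp)
        if st != 0:
            return st, s, np.empty((0, n))
    n_out = n_steps // stride + 1
    states = np.empty((n_out, n))
    states[0] = v
    m = 1
    for s in range(1, n_steps + 1):
        st = _step(v, alphas, A, B, sigma, b, d, r, K, c, eps, dt, k1, k2, k3, k4, tmp)
        if st != 0:
            return st, n_burn + s, states[:m]
        if s % stride == 0:
            states[m] = v
            m += 1
    return 0, -1, states


@njit(cache=True, fastmath=True)
def rk4_final(v0, alphas, A, B, sigma, b, d, r, K, c, eps, dt, n_steps):
    """Integrate without recording; return ``(status, failed_step, final_state)``."""
    n = v0.shape[0]
    k1 = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    tmp = np.empty(n)
    v = v0.copy()
    for s in range(n_steps):
        st = _step(v, alphas, A, B, sigma, b, d, r, K, c, eps, dt, k1, k2, k3, k4, tmp)
        if st != 0:
            return st, s, v
    return 0, -1, v


@njit(cache=True, fastmath=True)
def rk4_total_population(v0, alphas, A, B, sigma, b, d, r, K, c, eps, dt, n_steps):
    """Integrate recording only the total population sum(x_i) every step."""
    n = v0.shape[0]
    n_nodes = alphas.shape[0]
    k1 = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    tmp = np.empty(n)
    v = v0.copy()
    tot = np.empty(n_steps + 1)
    s0 = 0.0
    for i in range(n_nodes):
        s0 += v[3 * i]
    tot[0] = s0
    for s in range(1, n_steps + 1):
        st = _step(v, alphas, A, B, sigma, b, d, r, K, c, eps, dt, k1, k2, k3, k4, tmp)
        if st != 0:
            return st, s, v, tot[:s]
        sv = 0.0
        for i in range(n_nodes):
            sv += v[3 * i]
        tot[s] = sv
    return 0, -1, v, tot


@njit(cache=True, fastmath=True)
def divergence_run(v0, w0, alphas, A, B, sigma, b, d, r, K, c, eps, dt, n_steps, stride):
    """Co-integrate two trajectories; record their Euclidean distance.

    Returns ``(status, dist, v_final)``; ``dist`` is sampled every
    ``stride`` steps (first entry is the initial separation).
    """
    n = v0.shape[0]
    k1 = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    tmp = np.empty(n)
    v = v0.copy()
    w = w0.copy()
    m = n_steps // stride + 1
    dist = np.empty(m)
    acc = 0.0
    for i in range(n):
        acc += (w[i] - v[i]) ** 2
    dist[0] = np.sqrt(acc)
    idx = 1
    for s in range(1, n_steps + 1):
        st = _step(v, alphas, A, B, sigma, b, d, r, K, c, eps, dt, k1, k2, k3, k4, tmp)
        if st != 0:
            return st, dist[:idx], v
        st = _step(w, alphas, A, B, sigma, b, d, r, K, c, eps, dt, k1, k2, k3, k4, tmp)
        if st != 0:
            return st, dist[:idx], v
        if s % stride == 0:
            acc = 0.0
            for i in range(n):
                acc += (w[i] - v[i]) ** 2
            dist[idx] = np.sqrt(acc)
            idx += 1
    return 0, dist, v


@njit(cache=True, fastmath=True)
def benettin_run(v0, alphas, A, B, sigma, b, d, r, K, c, eps, dt, d0, tau_steps, n_intervals):
    """Benettin renormalization: log growth factors over ``n_intervals``.

    A companion trajectory is kept at distance ``d0`` and rescaled back to
    ``d0`` every ``tau_steps`` steps; the mean of the returned logs divided
    by ``tau_steps * dt`` estimates the largest Lyapunov exponent.
    """
    n = v0.shape[0]
    k1 = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    tmp = np.empty(n)
    v = v0.copy()
    w = v0.copy()
    off = d0 / np.sqrt(n)
    for i in range(n):
        w[i] += off
    logs = np.empty(n_intervals)
    for m in range(n_intervals):
        for s in range(tau_steps):
            st = _step(v, alphas, A, B, sigma, b, d, r, K, c, eps, dt, k1, k2, k3, k4, tmp)
            if st != 0:
                return st, logs[:m]
            st = _step(w, alphas, A, B, sigma, b, d, r, K, c, eps, dt, k1, k2, k3, k4, tmp)
            if st != 0:
                return st, logs[:m]
        acc = 0.0
        for i in range(n):
            acc += (w[i] - v[i]) ** 2
        sep = np.sqrt(acc)
        if sep <= 0.0:
            sep = 1e-300
        logs[m] = np.log(sep / d0)
        scale = d0 / sep
        for i in range(n):
            w[i] = v[i] + (w[i] - v[i]) * scale
    return 0, logs
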