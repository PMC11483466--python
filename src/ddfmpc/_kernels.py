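"""Numba-compiled inner loops.

Everything here operates on plain float64 arrays; the public modules wrap
these kernels with the trace/model containers.  Units follow the rest of
the package: mV, ms, µA, µF, mS (per 1 cm² soma).

Gating kinetics are the canonical Connor-Stevens rate functions (Na, K
delayed rectifier, transient A-current, leak) with voltage in mV and
rates in 1/ms.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, inline="always")
def _vtrap(x: float, scale: float) -> float:
    # x / (1 - exp(-x/scale)) with the removable singularity at x = 0 filled in.
    if abs(x) < 1e-7:
        return scale
    return x / (1.0 - np.exp(-x / scale))


@njit(cache=True, inline="always")
def cs_gate_targets(v):
    """Steady states and time constants of the five gates at voltage v.

    Returns (m_inf, tau_m, h_inf, tau_h, n_inf, tau_n, a_inf, tau_a,
    b_inf, tau_b); rates in 1/ms, taus in ms.
    """
    am = 0.38 * _vtrap(v + 34.7, 10.0)
    bm = 15.2 * np.exp(-0.0556 * (v + 59.7))
    ah = 0.266 * np.exp(-0.05 * (v + 53.0))
    bh = 3.8 / (1.0 + np.exp(-0.1 * (v + 23.0)))
    an = 0.02 * _vtrap(v + 50.7, 10.0)
    bn = 0.25 * np.exp(-0.0125 * (v + 60.7))

    a_inf = (0.0761 * np.exp((v + 99.22) / 31.84)
             / (1.0 + np.exp((v + 6.17) / 28.93))) ** (1.0 / 3.0)
    tau_a = 0.3632 + 1.158 / (1.0 + np.exp((v + 60.96) / 20.12))
    b_inf = (1.0 / (1.0 + np.exp((v + 58.3) / 14.54))) ** 4
    tau_b = 1.24 + 2.678 / (1.0 + np.exp((v + 55.0) / 16.027))
    return (am / (am + bm), 1.0 / (am + bm),
            ah / (ah + bh), 1.0 / (ah + bh),
            an / (an + bn), 1.0 / (an + bn),
            a_inf, tau_a, b_inf, tau_b)


@njit(cache=True, inline="always")
def cs_dv(v, m, hh, n, a, b, i_ext,
          C, g_na, g_k, g_a, g_l, e_na, e_k, e_a, e_l):
    """Membrane-voltage derivative with the gates held fixed."""
    i_na = g_na * m ** 3 * hh * (e_na - v)
    i_k = g_k * n ** 4 * (e_k - v)
    i_a = g_a * a ** 3 * b * (e_a - v)
    i_l = g_l * (e_l - v)
    return (i_na + i_k + i_a + i_l + i_ext) / C


@njit(cache=True)
def cs_integrate(v0, g0, i_ext, h,
                 C, g_na, g_k, g_a, g_l,
                 e_na, e_k, e_a, e_l):
    """Fixed-step integration of the Connor-Stevens equations.

    Per step, the five gating variables are advanced with the exponential
    (Rush-Larsen) update x <- x_inf + (x - x_inf) exp(-h/tau) evaluated at
    the current voltage -- exact for frozen V and unconditionally stable,
    which keeps every gate inside [0, 1] by construction even when the
    rates become stiff at strongly hyperpolarized voltages.  The voltage
    is then advanced with an RK4 step at fixed gates.

    ``i_ext`` holds the total external current (injected + noise), one
    value per integration step, zero-order-held across the step.  Returns
    the voltage at every grid point (length ``len(i_ext) + 1``), the
    gating trajectories (same length, columns m, h, n, a, b), and the
    index of the first non-finite state (-1 if none).
    """
    n_steps = i_ext.shape[0]
    V = np.empty(n_steps + 1)
    G = np.empty((n_steps + 1, 5))
    v = v0
    m, hh, n, a, b = g0[0], g0[1], g0[2], g0[3], g0[4]
    V[0] = v
    G[0, 0], G[0, 1], G[0, 2], G[0, 3], G[0, 4] = m, hh, n, a, b
    for k in range(n_steps):
        i_k = i_ext[k]
        (m_inf, tau_m, h_inf, tau_h, n_inf, tau_n,
         a_inf, tau_a, b_inf, tau_b) = cs_gate_targets(v)
        m = m_inf + (m - m_inf) * np.exp(-h / tau_m)
        hh = h_inf + (hh - h_inf) * np.exp(-h / tau_h)
        n = n_inf + (n - n_inf) * np.exp(-h / tau_n)
        a = a_inf + (a - a_inf) * np.exp(-h / tau_a)
        b = b_inf + (b - b_inf) * np.exp(-h / tau_b)

        k1 = cs_dv(v, m, hh, n, a, b, i_k,
                   C, g_na, g_k, g_a, g_l, e_na, e_k, e_a, e_l)
        k2 = cs_dv(v + 0.5 * h * k1, m, hh, n, a, b, i_k,
                   C, g_na, g_k, g_a, g_l, e_na, e_k, e_a, e_l)
        k3 = cs_dv(v + 0.5 * h * k2, m, hh, n, a, b, i_k,
                   C, g_na, g_k, g_a, g_l, e_na, e_k, e_a, e_l)
        k4 = cs_dv(v + h * k3, m, hh, n, a, b, i_k,
                   C, g_na, g_k, g_a, g_l, e_na, e_k, e_a, e_l)
        v = v + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if not np.isfinite(v):
            return V, G, k + 1
        V[k + 1] = v
        G[k + 1, 0], G[k + 1, 1], G[k + 1, 2] = m, hh, n
        G[k + 1, 3], G[k + 1, 4] = a, b
    return V, G, -1


@njit(cache=True)
def lorenz_integrate(state0, n_steps, h, tau, sigma, rho, beta):
    """RK4 integration of the time-scaled Lorenz-63 system.

    ``tau * dx/dt = sigma (y - x)`` etc.; ``h`` is the step in the same time
    units as ``tau`` scales (ms here).  Returns the x(t) samples at every
    grid point (length ``n_steps + 1``) and the final (x, y, z) state.
    """
    x, y, z = state0[0], state0[1], state0[2]
    out = np.empty(n_steps + 1)
    out[0] = x
    for k in range(n_steps):
        x1 = sigma * (y - x) / tau
        y1 = (x * (rho - z) - y) / tau
        z1 = (x * y - beta * z) / tau

        xa, ya, za = x + 0.5 * h * x1, y + 0.5 * h * y1, z + 0.5 * h * z1
        x2 = sigma * (ya - xa) / tau
        y2 = (xa * (rho - za) - ya) / tau
        z2 = (xa * ya - beta * za) / tau

        xa, ya, za = x + 0.5 * h * x2, y + 0.5 * h * y2, z + 0.5 * h * z2
        x3 = sigma * (ya - xa) / tau
        y3 = (xa * (rho - za) - ya) / tau
        z3 = (xa * ya - beta * za) / tau

        xa, ya, za = x + h * x3, y + h * y3, z + h * z3
        x4 = sigma * (ya - xa) / tau
        y4 = (xa * (rho - za) - ya) / tau
        z4 = (xa * ya - beta * za) / tau

        x += (h / 6.0) * (x1 + 2.0 * x2 + 2.0 * x3 + x4)
        y += (h / 6.0) * (y1 + 2.0 * y2 + 2.0 * y3 + y4)
        z += (h / 6.0) * (z1 + 2.0 * z2 + 2.0 * z3 + z4)
        out[k + 1] = x
    final = np.array([x, y, z])
    return out, final


@njit(cache=True, inline="always")
def rbf_sum(vbuf, pos, tau, centers, w, R):
    """F_RBF(S_n) where S_n[d] = vbuf[pos - d*tau], d = 0..D_e-1."""
    n_centers, dim = centers.shape
    total = 0.0
    for c in range(n_centers):
        d2 = 0.0
        for d in range(dim):
            diff = vbuf[pos - d * tau] - centers[c, d]
            d2 += diff * diff
        total += w[c] * np.exp(-R * d2)
    return total


@njit(cache=True)
def rbf_forecast(v_seed, i_inj, centers, w, alpha, R, tau, v_guard):
    """Open-loop rollout of the voltage-increment RBFN forecaster.

    ``v_seed`` holds the first ``(D_e - 1) * tau + 1`` voltage samples;
    predictions are fed back into the delay embedding, the true voltage is
    never read past the seed.  Returns the full trajectory (seed included,
    same length as ``i_inj``) and the index at which |V| first exceeded
    ``v_guard`` (-1 if it never did; past that index the trajectory is
    held constant).
    """
    n = i_inj.shape[0]
    L = v_seed.shape[0] - 1
    v = np.empty(n)
    v[: L + 1] = v_seed
    diverged = -1
    for k in range(L, n - 1):
        f = rbf_sum(v, k, tau, centers, w, R)
        v[k + 1] = v[k] + f + alpha * (i_inj[k + 1] + i_inj[k])
        if abs(v[k + 1]) > v_guard:
            diverged = k + 1
            v[k + 1:] = v[k]
            break
    return v, diverged


@njit(cache=True)
def mpc_cost_grad(x, v_hist, i_prev, ref, centers, w, alpha, R, tau,
                  s, q, r):
    """Horizon cost and gradient for the receding-horizon problem.

    ``x`` are the decision currents I_1..I_T; ``v_hist`` the measured voltage
    history (oldest first, last entry is V_0) long enough to form the delay
    embedding; ``ref`` the next T reference voltages V^ref_1..V^ref_T.

    The rollout follows the forecaster dynamics
    V_{n+1} = V_n + F_RBF(S_n) + alpha (I_{n+1} + I_n) and the cost is
    s e_T^2 + sum_{n=0}^{T-1} [ q e_{n+1}^2 + r (I_{n+1} - I_n)^2 ].

    The gradient is exact, via forward sensitivities dV_k / dI_j.
    """
    T = x.shape[0]
    n_centers, dim = centers.shape
    L = v_hist.shape[0] - 1  # (D_e - 1) * tau
    # vbuf[0..L] = history, vbuf[L+k] = predicted V_k
    vbuf = np.empty(L + T + 1)
    vbuf[: L + 1] = v_hist
    # sens[k, j-1] = dV_k / dI_j
    sens = np.zeros((T + 1, T))
    for k in range(T):
        pos = L + k
        # F and dF/dS at S_k
        f = 0.0
        dfds = np.zeros(dim)
        for c in range(n_centers):
            d2 = 0.0
            for d in range(dim):
                diff = vbuf[pos - d * tau] - centers[c, d]
                d2 += diff * diff
            psi = w[c] * np.exp(-R * d2)
            f += psi
            for d in range(dim):
                dfds[d] += psi * (-2.0 * R) * (vbuf[pos - d * tau] - centers[c, d])
        i_k = i_prev if k == 0 else x[k - 1]
        vbuf[pos + 1] = vbuf[pos] + f + alpha * (x[k] + i_k)
        for j in range(T):
            acc = sens[k, j]
            for d in range(dim):
                kk = k - d * tau
                if kk >= 0:
                    acc += dfds[d] * sens[kk, j]
            if j == k:
                acc += alpha
            if j == k - 1:
                acc += alpha
            sens[k + 1, j] = acc
    cost = 0.0
    grad = np.zeros(T)
    for n in range(T):
        e = vbuf[L + n + 1] - ref[n]
        weight = q + (s if n == T - 1 else 0.0)
        cost += weight * e * e
        for j in range(T):
            grad[j] += 2.0 * weight * e * sens[n + 1, j]
        i_n = i_prev if n == 0 else x[n - 1]
        di = x[n] - i_n
        cost += r * di * di
        grad[n] += 2.0 * r * di
        if n > 0:
            grad[n - 1] -= 2.0 * r * di
    return cost, grad
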