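"""Fixed-step RK4 integration kernels (numba-compiled).

Because the stomach-jejunum chain has exact closed forms, the delayed ileal
forcing J(t - tau) is an explicit function of time and only (L, G, I) need
numerical integration -- the delay introduces no history-interpolation error.
These kernels are the hot path of the fitting machinery; the reference
LSODA path lives in :mod:`ogttfit.solver`.

Parameter vector layout (matches ``params.FREE_PARAM_NAMES``)::

    0 k_js, 1 k_gj, 2 k_jl, 3 k_gl, 4 tau, 5 k_xg, 6 k_xgi, 7 eta,
    8 k_lambda, 9 k_xi, 10 beta, 11 gamma, 12 f_gj
"""

from __future__ import annotations

import numpy as np
from numba import njit

_DEGENERATE_RATE_TOL = 1e-10


@njit(cache=True)
def _jejunum(theta, D, t):
    """Closed-form J(t); analytic limit at k_js == k_gj + k_jl."""
    if t <= 0.0:
        return 0.0
    kjs = theta[0]
    a = theta[1] + theta[2]
    if abs(a - kjs) < _DEGENERATE_RATE_TOL:
        return D * kjs * t * np.exp(-kjs * t)
    return D * kjs * (np.exp(-kjs * t) - np.exp(-a * t)) / (a - kjs)


@njit(cache=True)
def _phi(theta, D, t):
    """Delayed jejunal mass phi(t) = J(t - tau), zero before the delay."""
    tau = theta[4]
    if t < tau:
        return 0.0
    return _jejunum(theta, D, t - tau)


@njit(cache=True)
def _sigma(beta, gamma, Gb, G_tilde):
    """Hill secretion factor, evaluated in log space to avoid overflow."""
    b = gamma * np.log(beta)
    x = gamma * (np.log(Gb) - np.log(G_tilde))
    log_num = np.logaddexp(b, 0.0)
    log_den = np.logaddexp(b + x, 0.0)
    return np.exp(log_num - log_den)


@njit(cache=True)
def _rhs_lgi(theta, Gb, Ib, D, gprod0, t, L, G, I, out):
    """dL, dG, dI at time t.  Returns False if the model leaves its domain."""
    if G <= 0.0 or I <= 0.0:
        return False
    den = theta[8] / gprod0 + (G - Gb)
    if den <= 1e-12:
        return False
    gprod = theta[8] / den
    J = _jejunum(theta, D, t)
    absorption = theta[1] * J + theta[3] * L
    g_tilde = G + theta[12] * absorption
    if g_tilde <= 0.0:
        return False
    out[0] = theta[2] * _phi(theta, D, t) - theta[3] * L
    out[1] = -(theta[5] + theta[6] * I) * G + gprod + theta[7] * absorption
    out[2] = theta[9] * Ib * (_sigma(theta[10], theta[11], Gb, g_tilde) - I / Ib)
    return True


@njit(cache=True)
def integrate_lgi(theta, Gb, Ib, D, t_grid, n_sub):
    """RK4-integrate (L, G, I) from (0, G_b, I_b) over ``t_grid``.

    ``n_sub`` substeps are taken inside every grid interval.  Returns
    (L, G, I, ok); ``ok`` is False when the state left the model's domain,
    in which case the remaining entries are NaN.
    """
    n = t_grid.shape[0]
    L = np.empty(n)
    G = np.empty(n)
    I = np.empty(n)
    L[0] = 0.0
    G[0] = Gb
    I[0] = Ib
    gprod0 = (theta[5] + theta[6] * Ib) * Gb
    k1 = np.empty(3)
    k2 = np.empty(3)
    k3 = np.empty(3)
    k4 = np.empty(3)
    l, g, i = 0.0, Gb, Ib
    for m in range(1, n):
        t0 = t_grid[m - 1]
        h = (t_grid[m] - t0) / n_sub
        for s in range(n_sub):
            t = t0 + s * h
            ok = _rhs_lgi(theta, Gb, Ib, D, gprod0, t, l, g, i, k1)
            if not ok:
                L[m:] = np.nan
                G[m:] = np.nan
                I[m:] = np.nan
                return L, G, I, False
            ok = _rhs_lgi(theta, Gb, Ib, D, gprod0, t + 0.5 * h,
                          l + 0.5 * h * k1[0], g + 0.5 * h * k1[1],
                          i + 0.5 * h * k1[2], k2)
            if ok:
                ok = _rhs_lgi(theta, Gb, Ib, D, gprod0, t + 0.5 * h,
                              l + 0.5 * h * k2[0], g + 0.5 * h * k2[1],
                              i + 0.5 * h * k2[2], k3)
            if ok:
                ok = _rhs_lgi(theta, Gb, Ib, D, gprod0, t + h,
                              l + h * k3[0], g + h * k3[1], i + h * k3[2], k4)
            if not ok:
                L[m:] = np.nan
                G[m:] = np.nan
                I[m:] = np.nan
                return L, G, I, False
            l += h * (k1[0] + 2.0 * k2[0] + 2.0 * k3[0] + k4[0]) / 6.0
            g += h * (k1[1] + 2.0 * k2[1] + 2.0 * k3[1] + k4[1]) / 6.0
            i += h * (k1[2] + 2.0 * k2[2] + 2.0 * k3[2] + k4[2]) / 6.0
            if not (np.isfinite(l) and np.isfinite(g) and np.isfinite(i)):
                L[m:] = np.nan
                G[m:] = np.nan
                I[m:] = np.nan
                return L, G, I, False
        L[m] = l
        G[m] = g
        I[m] = i
    return L, G, I, True


@njit(cache=True)
def integrate_g_exogenous_insulin(theta, Gb, Ib, D, t_grid, n_sub, I_fine):
    """RK4-integrate (L, G) with insulinemia prescribed exogenously.

    ``I_fine`` holds the exogenous insulin curve sampled at half-substep
    resolution: index ``2*n_sub*(m-1) + 2*s (+1)`` is t_grid[m-1] + s*h
    (+ h/2).  Used by the staged initial guess, where the measured-insulin
    interpolant replaces the insulin equation.
    """
    n = t_grid.shape[0]
    L = np.empty(n)
    G = np.empty(n)
    L[0] = 0.0
    G[0] = Gb
    gprod0 = (theta[5] + theta[6] * Ib) * Gb
    l, g = 0.0, Gb
    for m in range(1, n):
        t0 = t_grid[m - 1]
        h = (t_grid[m] - t0) / n_sub
        base = 2 * n_sub * (m - 1)
        for s in range(n_sub):
            t = t0 + s * h
            i0 = I_fine[base + 2 * s]
            i_half = I_fine[base + 2 * s + 1]
            i1 = I_fine[base + 2 * s + 2]
            ok = True
            # k1
            den = theta[8] / gprod0 + (g - Gb)
            if g <= 0.0 or den <= 1e-12:
                ok = False
            if ok:
                J = _jejunum(theta, D, t)
                dl1 = theta[2] * _phi(theta, D, t) - theta[3] * l
                dg1 = (-(theta[5] + theta[6] * i0) * g + theta[8] / den
                       + theta[7] * (theta[1] * J + theta[3] * l))
                # k2
                l2 = l + 0.5 * h * dl1
                g2 = g + 0.5 * h * dg1
                den = theta[8] / gprod0 + (g2 - Gb)
                if g2 <= 0.0 or den <= 1e-12:
                    ok = False
                else:
                    J = _jejunum(theta, D, t + 0.5 * h)
                    dl2 = theta[2] * _phi(theta, D, t + 0.5 * h) - theta[3] * l2
                    dg2 = (-(theta[5] + theta[6] * i_half) * g2 + theta[8] / den
                           + theta[7] * (theta[1] * J + theta[3] * l2))
            if ok:
                l3 = l + 0.5 * h * dl2
                g3 = g + 0.5 * h * dg2
                den = theta[8] / gprod0 + (g3 - Gb)
                if g3 <= 0.0 or den <= 1e-12:
                    ok = False
                else:
                    J = _jejunum(theta, D, t + 0.5 * h)
                    dl3 = theta[2] * _phi(theta, D, t + 0.5 * h) - theta[3] * l3
                    dg3 = (-(theta[5] + theta[6] * i_half) * g3 + theta[8] / den
                           + theta[7] * (theta[1] * J + theta[3] * l3))
            if ok:
                l4 = l + h * dl3
                g4 = g + h * dg3
                den = theta[8] / gprod0 + (g4 - Gb)
                if g4 <= 0.0 or den <= 1e-12:
                    ok = False
                else:
                    J = _jejunum(theta, D, t + h)
                    dl4 = theta[2] * _phi(theta, D, t + h) - theta[3] * l4
                    dg4 = (-(theta[5] + theta[6] * i1) * g4 + theta[8] / den
                           + theta[7] * (theta[1] * J + theta[3] * l4))
            if not ok:
                L[m:] = np.nan
                G[m:] = np.nan
                return L, G, False
            l += h * (dl1 + 2.0 * dl2 + 2.0 * dl3 + dl4) / 6.0
            g += h * (dg1 + 2.0 * dg2 + 2.0 * dg3 + dg4) / 6.0
            if not (np.isfinite(l) and np.isfinite(g)):
                L[m:] = np.nan
                G[m:] = np.nan
                return L, G, False
        L[m] = l
        G[m] = g
    return L, G, True


@njit(cache=True)
def integrate_i_exogenous_glucose(k_xi, beta, gamma, f_gj, Gb, Ib,
                                  t_grid, n_sub, G_fine, absorption_fine):
    """RK4-integrate insulinemia with glucose and absorption flux prescribed.

    ``G_fine`` / ``absorption_fine`` are sampled at half-substep resolution
    (same layout as in :func:`integrate_g_exogenous_insulin`).  Used by the
    insulin stage of the staged initial guess.
    """
    n = t_grid.shape[0]
    I = np.empty(n)
    I[0] = Ib
    i = Ib
    for m in range(1, n):
        h = (t_grid[m] - t_grid[m - 1]) / n_sub
        base = 2 * n_sub * (m - 1)
        for s in range(n_sub):
            ok = True
            di = np.empty(4)
            offs = (0, 1, 1, 2)
            ys = np.empty(4)
            ys[0] = i
            for stage in range(4):
                g_t = G_fine[base + 2 * s + offs[stage]]
                ab = absorption_fine[base + 2 * s + offs[stage]]
                g_tilde = g_t + f_gj * ab
                if g_tilde <= 0.0 or ys[stage] <= -Ib:
                    ok = False
                    break
                di[stage] = k_xi * Ib * (_sigma(beta, gamma, Gb, g_tilde)
                                         - ys[stage] / Ib)
                if stage == 0:
                    ys[1] = i + 0.5 * h * di[0]
                elif stage == 1:
                    ys[2] = i + 0.5 * h * di[1]
                elif stage == 2:
                    ys[3] = i + h * di[2]
            if not ok:
                I[m:] = np.nan
                return I, False
            i += h * (di[0] + 2.0 * di[1] + 2.0 * di[2] + di[3]) / 6.0
            if not np.isfinite(i) or i <= 0.0:
                I[m:] = np.nan
                return I, False
        I[m] = i
    return I, True
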