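"""Numba kernels for the C-alpha SBM: energy, forces, Langevin integration.

Everything here works in reduced units: length in Angstrom, energy in units
of the base scale epsilon, mass 1 per bead, k_B = 1, time in sqrt(m A^2 /
epsilon).  Force constants arrive as multiples of epsilon, so scaling the
physical epsilon never touches these kernels — it only rescales reported
energies and temperatures.

The arithmetic is deliberately scalarized (no temporary arrays inside the
step loop); the integrator allocates its buffers once per run.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# bias modes
BIAS_NONE = 0
BIAS_ENERGY = 1
BIAS_Q = 2


@njit(cache=True, fastmath=True, error_model="numpy")
def _energy_forces_into(x, r0, theta0, phi0,
                        ci, cj, sig, ri, rj,
                        kr, kth, kphi1, kphi3, eps1, eps2, sig_rep, f):
    """Fill ``f`` with forces; return per-term energies."""
    n = x.shape[0]
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0
    e_bond = 0.0
    e_angle = 0.0
    e_dih = 0.0
    e_con = 0.0
    e_rep = 0.0

    # --- bonds: K_r (r - r0)^2
    for b in range(n - 1):
        dx0 = x[b + 1, 0] - x[b, 0]
        dx1 = x[b + 1, 1] - x[b, 1]
        dx2 = x[b + 1, 2] - x[b, 2]
        r = np.sqrt(dx0 * dx0 + dx1 * dx1 + dx2 * dx2)
        dr = r - r0[b]
        e_bond += kr * dr * dr
        g = 2.0 * kr * dr / r
        f[b, 0] += g * dx0
        f[b, 1] += g * dx1
        f[b, 2] += g * dx2
        f[b + 1, 0] -= g * dx0
        f[b + 1, 1] -= g * dx1
        f[b + 1, 2] -= g * dx2

    # --- angles: K_theta (theta - theta0)^2
    for a in range(n - 2):
        u0 = x[a, 0] - x[a + 1, 0]
        u1 = x[a, 1] - x[a + 1, 1]
        u2 = x[a, 2] - x[a + 1, 2]
        v0 = x[a + 2, 0] - x[a + 1, 0]
        v1 = x[a + 2, 1] - x[a + 1, 1]
        v2 = x[a + 2, 2] - x[a + 1, 2]
        nu = np.sqrt(u0 * u0 + u1 * u1 + u2 * u2)
        nv = np.sqrt(v0 * v0 + v1 * v1 + v2 * v2)
        c = (u0 * v0 + u1 * v1 + u2 * v2) / (nu * nv)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        th = np.arccos(c)
        s = np.sqrt(1.0 - c * c)
        if s < 1e-8:
            s = 1e-8
        dth = th - theta0[a]
        e_angle += kth * dth * dth
        coef = 2.0 * kth * dth / s
        inun = 1.0 / (nu * nv)
        iuu = c / (nu * nu)
        ivv = c / (nv * nv)
        du0 = v0 * inun - u0 * iuu
        du1 = v1 * inun - u1 * iuu
        du2 = v2 * inun - u2 * iuu
        dv0 = u0 * inun - v0 * ivv
        dv1 = u1 * inun - v1 * ivv
        dv2 = u2 * inun - v2 * ivv
        f[a, 0] += coef * du0
        f[a, 1] += coef * du1
        f[a, 2] += coef * du2
        f[a + 2, 0] += coef * dv0
        f[a + 2, 1] += coef * dv1
        f[a + 2, 2] += coef * dv2
        f[a + 1, 0] -= coef * (du0 + dv0)
        f[a + 1, 1] -= coef * (du1 + dv1)
        f[a + 1, 2] -= coef * (du2 + dv2)

    # --- dihedrals: K1 (1 - cos dphi) + K3 (1 - cos 3 dphi)
    for t in range(n - 3):
        b1x = x[t + 1, 0] - x[t, 0]
        b1y = x[t + 1, 1] - x[t, 1]
        b1z = x[t + 1, 2] - x[t, 2]
        b2x = x[t + 2, 0] - x[t + 1, 0]
        b2y = x[t + 2, 1] - x[t + 1, 1]
        b2z = x[t + 2, 2] - x[t + 1, 2]
        b3x = x[t + 3, 0] - x[t + 2, 0]
        b3y = x[t + 3, 1] - x[t + 2, 1]
        b3z = x[t + 3, 2] - x[t + 2, 2]
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        nb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        # m1 = n1 x b2
        m1x = n1y * b2z - n1z * b2y
        m1y = n1z * b2x - n1x * b2z
        m1z = n1x * b2y - n1y * b2x
        yy = (m1x * n2x + m1y * n2y + m1z * n2z) / nb2
        xx = n1x * n2x + n1y * n2y + n1z * n2z
        phi = np.arctan2(yy, xx)
        # branch-free wrap to (-pi, pi]: a while-loop wrap never terminates
        # on NaN under fastmath
        dphi = phi - phi0[t]
        dphi -= 2.0 * np.pi * np.round(dphi / (2.0 * np.pi))
        e_dih += kphi1 * (1.0 - np.cos(dphi)) \
            + kphi3 * (1.0 - np.cos(3.0 * dphi))
        dU = kphi1 * np.sin(dphi) + 3.0 * kphi3 * np.sin(3.0 * dphi)
        nn1 = n1x * n1x + n1y * n1y + n1z * n1z
        nn2 = n2x * n2x + n2y * n2y + n2z * n2z
        if nn1 < 1e-12 or nn2 < 1e-12:
            continue
        b12 = b1x * b2x + b1y * b2y + b1z * b2z
        b32 = b3x * b2x + b3y * b2y + b3z * b2z
        nb22 = nb2 * nb2
        ca = nb2 / nn1
        cb = nb2 / nn2
        r12 = b12 / nb22
        r32 = b32 / nb22
        # dphi/dx for the four beads (verified against finite differences)
        for d in range(3):
            if d == 0:
                a1 = n1x
                a2 = n2x
            elif d == 1:
                a1 = n1y
                a2 = n2y
            else:
                a1 = n1z
                a2 = n2z
            dp0 = ca * a1
            dp3 = -cb * a2
            dp1 = -dp0 - r12 * dp0 + r32 * dp3
            dp2 = -dp3 + r12 * dp0 - r32 * dp3
            f[t, d] -= dU * dp0
            f[t + 1, d] -= dU * dp1
            f[t + 2, d] -= dU * dp2
            f[t + 3, d] -= dU * dp3

    # --- native contacts: eps1 [5 (s/r)^12 - 6 (s/r)^10]
    for c_ in range(ci.shape[0]):
        i = ci[c_]
        j = cj[c_]
        dx0 = x[j, 0] - x[i, 0]
        dx1 = x[j, 1] - x[i, 1]
        dx2 = x[j, 2] - x[i, 2]
        r2 = dx0 * dx0 + dx1 * dx1 + dx2 * dx2
        sr2 = (sig[c_] * sig[c_]) / r2
        sr10 = sr2 * sr2 * sr2 * sr2 * sr2
        sr12 = sr10 * sr2
        e_con += eps1 * (5.0 * sr12 - 6.0 * sr10)
        g = eps1 * 60.0 * (sr10 - sr12) / r2
        f[i, 0] += g * dx0
        f[i, 1] += g * dx1
        f[i, 2] += g * dx2
        f[j, 0] -= g * dx0
        f[j, 1] -= g * dx1
        f[j, 2] -= g * dx2

    # --- excluded volume: eps2 (sigma_rep / r)^12 over non-contact pairs
    for p in range(ri.shape[0]):
        i = ri[p]
        j = rj[p]
        dx0 = x[j, 0] - x[i, 0]
        dx1 = x[j, 1] - x[i, 1]
        dx2 = x[j, 2] - x[i, 2]
        r2 = dx0 * dx0 + dx1 * dx1 + dx2 * dx2
        sr2 = (sig_rep * sig_rep) / r2
        if sr2 < 0.04:      # (s/r)^12 < 4e-17: negligible
            continue
        sr12 = sr2 * sr2 * sr2 * sr2 * sr2 * sr2
        e_rep += eps2 * sr12
        g = -12.0 * eps2 * sr12 / r2
        f[i, 0] += g * dx0
        f[i, 1] += g * dx1
        f[i, 2] += g * dx2
        f[j, 0] -= g * dx0
        f[j, 1] -= g * dx1
        f[j, 2] -= g * dx2

    return e_bond, e_angle, e_dih, e_con, e_rep


def energy_forces(x, r0, theta0, phi0, ci, cj, sig, ri, rj,
                  kr, kth, kphi1, kphi3, eps1, eps2, sig_rep):
    """Allocating wrapper: per-term energies + force array."""
    f = np.zeros_like(x)
    eb, ea, ed, ec, er = _energy_forces_into(
        x, r0, theta0, phi0, ci, cj, sig, ri, rj,
        kr, kth, kphi1, kphi3, eps1, eps2, sig_rep, f)
    return eb, ea, ed, ec, er, f


@njit(cache=True, fastmath=True, error_model="numpy")
def fraction_native(x, ci, cj, sig, factor):
    """Hard fraction of native contacts: r_ij < factor * sigma_ij."""
    m = ci.shape[0]
    if m == 0:
        return 1.0
    formed = 0
    for c_ in range(m):
        dx0 = x[cj[c_], 0] - x[ci[c_], 0]
        dx1 = x[cj[c_], 1] - x[ci[c_], 1]
        dx2 = x[cj[c_], 2] - x[ci[c_], 2]
        if np.sqrt(dx0 * dx0 + dx1 * dx1 + dx2 * dx2) < factor * sig[c_]:
            formed += 1
    return formed / m


@njit(cache=True, fastmath=True, error_model="numpy")
def smooth_fraction_native(x, ci, cj, sig, factor, delta):
    """Differentiable Q: mean logistic indicator with softness delta (A)."""
    m = ci.shape[0]
    if m == 0:
        return 1.0
    q = 0.0
    for c_ in range(m):
        dx0 = x[cj[c_], 0] - x[ci[c_], 0]
        dx1 = x[cj[c_], 1] - x[ci[c_], 1]
        dx2 = x[cj[c_], 2] - x[ci[c_], 2]
        r = np.sqrt(dx0 * dx0 + dx1 * dx1 + dx2 * dx2)
        q += 1.0 / (1.0 + np.exp((r - factor * sig[c_]) / delta))
    return q / m


@njit(cache=True, fastmath=True, error_model="numpy")
def _apply_bias(x, ci, cj, sig, e, f,
                bias_mode, bias_center, bias_width, bias_strength,
                q_factor, q_delta):
    """Add the Gaussian-well bias force in place; return (W, smooth Q)."""
    w = 0.0
    qs = 0.0
    if bias_mode == BIAS_ENERGY:
        z = (e - bias_center) / bias_width
        g = np.exp(-0.5 * z * z)
        w = -bias_strength * g
        dw = bias_strength * g * (e - bias_center) / (bias_width * bias_width)
        scale = 1.0 + dw
        for i in range(x.shape[0]):
            f[i, 0] *= scale
            f[i, 1] *= scale
            f[i, 2] *= scale
    elif bias_mode == BIAS_Q:
        qs = smooth_fraction_native(x, ci, cj, sig, q_factor, q_delta)
        z = (qs - bias_center) / bias_width
        g = np.exp(-0.5 * z * z)
        w = -bias_strength * g
        dwdq = bias_strength * g * (qs - bias_center) / (bias_width * bias_width)
        m = ci.shape[0]
        for c_ in range(m):
            i = ci[c_]
            j = cj[c_]
            dx0 = x[j, 0] - x[i, 0]
            dx1 = x[j, 1] - x[i, 1]
            dx2 = x[j, 2] - x[i, 2]
            r = np.sqrt(dx0 * dx0 + dx1 * dx1 + dx2 * dx2)
            s = 1.0 / (1.0 + np.exp((r - q_factor * sig[c_]) / q_delta))
            dqdr = -s * (1.0 - s) / (q_delta * m)
            g2 = -dwdq * dqdr / r
            f[i, 0] -= g2 * dx0
            f[i, 1] -= g2 * dx1
            f[i, 2] -= g2 * dx2
            f[j, 0] += g2 * dx0
            f[j, 1] += g2 * dx1
            f[j, 2] += g2 * dx2
    return w, qs


@njit(cache=True, fastmath=True, error_model="numpy")
def run_baoab(x0, v0, n_steps, dt, gamma, temp, seed, save_interval,
              save_coords,
              r0, theta0, phi0, ci, cj, sig, ri, rj,
              kr, kth, kphi1, kphi3, eps1, eps2, sig_rep,
              bias_mode, bias_center, bias_width, bias_strength,
              q_factor, q_delta):
    """BAOAB Langevin splitting at reduced temperature ``temp``.

    gamma = 0 degenerates to velocity Verlet (NVE).  Saves every
    ``save_interval`` steps: unbiased potential energy, kinetic energy, hard
    Q, smooth Q, bias value W.  Returns (epot, ekin, q, qs, w, coords,
    x_final, v_final, nan_step); nan_step >= 0 flags divergence.
    """
    np.random.seed(seed)
    n = x0.shape[0]
    x = x0.copy()
    v = v0.copy()
    f = np.zeros((n, 3))
    n_frames = n_steps // save_interval
    epot = np.empty(n_frames)
    ekin = np.empty(n_frames)
    qh = np.empty(n_frames)
    qsm = np.empty(n_frames)
    wv = np.empty(n_frames)
    if save_coords:
        coords = np.empty((n_frames, n, 3))
    else:
        coords = np.empty((0, n, 3))

    if gamma > 0.0:
        c1 = np.exp(-gamma * dt)
        c2 = np.sqrt((1.0 - c1 * c1) * temp)
    else:
        c1 = 1.0
        c2 = 0.0

    eb, ea, ed, ec, er = _energy_forces_into(
        x, r0, theta0, phi0, ci, cj, sig, ri, rj,
        kr, kth, kphi1, kphi3, eps1, eps2, sig_rep, f)
    e = eb + ea + ed + ec + er
    w, qs = _apply_bias(x, ci, cj, sig, e, f, bias_mode, bias_center,
                        bias_width, bias_strength, q_factor, q_delta)
    frame = 0
    half = 0.5 * dt
    for step in range(n_steps):
        for i in range(n):
            v[i, 0] += half * f[i, 0]
            v[i, 1] += half * f[i, 1]
            v[i, 2] += half * f[i, 2]
            x[i, 0] += half * v[i, 0]
            x[i, 1] += half * v[i, 1]
            x[i, 2] += half * v[i, 2]
        if gamma > 0.0:
            for i in range(n):
                v[i, 0] = c1 * v[i, 0] + c2 * np.random.standard_normal()
                v[i, 1] = c1 * v[i, 1] + c2 * np.random.standard_normal()
                v[i, 2] = c1 * v[i, 2] + c2 * np.random.standard_normal()
        for i in range(n):
            x[i, 0] += half * v[i, 0]
            x[i, 1] += half * v[i, 1]
            x[i, 2] += half * v[i, 2]
        eb, ea, ed, ec, er = _energy_forces_into(
            x, r0, theta0, phi0, ci, cj, sig, ri, rj,
            kr, kth, kphi1, kphi3, eps1, eps2, sig_rep, f)
        e = eb + ea + ed + ec + er
        w, qs = _apply_bias(x, ci, cj, sig, e, f, bias_mode, bias_center,
                            bias_width, bias_strength, q_factor, q_delta)
        for i in range(n):
            v[i, 0] += half * f[i, 0]
            v[i, 1] += half * f[i, 1]
            v[i, 2] += half * f[i, 2]
        if (step + 1) % save_interval == 0:
            if not np.isfinite(e):
                return (epot[:frame], ekin[:frame], qh[:frame], qsm[:frame],
                        wv[:frame], coords[:frame], x, v, step)
            ke = 0.0
            for i in range(n):
                ke += 0.5 * (v[i, 0] * v[i, 0] + v[i, 1] * v[i, 1]
                             + v[i, 2] * v[i, 2])
            epot[frame] = e
            ekin[frame] = ke
            qh[frame] = fraction_native(x, ci, cj, sig, q_factor)
            qsm[frame] = qs if bias_mode == BIAS_Q else smooth_fraction_native(
                x, ci, cj, sig, q_factor, q_delta)
            wv[frame] = w
            if save_coords:
                for i in range(n):
                    coords[frame, i, 0] = x[i, 0]
                    coords[frame, i, 1] = x[i, 1]
                    coords[frame, i, 2] = x[i, 2]
            frame += 1
    return epot, ekin, qh, qsm, wv, coords, x, v, -1
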