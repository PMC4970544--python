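"""Numba-accelerated BD inner loop.

Mirrors the reference propagator in :mod:`vwforce.engine` but works in
reduced units (length a, energy kBT, mobility mu0, time tau_a =
a^2/(mu0 kBT)) inside a jitted kernel, rebuilding the Rotne–Prager–Blake
mobility and its Cholesky noise factor every step.  A zero-noise
equivalence test ties this path to the numpy reference.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .bdmodel import ChainConfig
from .constants import kbt, stokes_mobility

_MODE = {"none": 0, "free": 1, "wall": 2}


@njit(cache=True)
def _mobility(pos, mode, M):  # pos (N,3) in a units; M (3N,3N) out, mu0 units
    n = pos.shape[0]
    M[:, :] = 0.0
    if mode == 0:
        for k in range(3 * n):
            M[k, k] = 1.0
        return
    for i in range(n):
        if mode == 2:
            z = pos[i, 2]
            inv = 1.0 / z
            par = 1.0 - 0.5625 * inv + 0.125 * inv**3
            perp = 1.0 - 1.125 * inv + 0.5 * inv**3
            M[3 * i, 3 * i] = par
            M[3 * i + 1, 3 * i + 1] = par
            M[3 * i + 2, 3 * i + 2] = perp
        else:
            for c in range(3):
                M[3 * i + c, 3 * i + c] = 1.0
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            ex, ey, ez = dx / r, dy / r, dz / r
            e = np.empty(3)
            e[0], e[1], e[2] = ex, ey, ez
            blk = np.empty((3, 3))
            if r >= 2.0:
                c1 = (3.0 / (4.0 * r)) * (1.0 + 2.0 / (3.0 * r * r))
                c2 = (3.0 / (4.0 * r)) * (1.0 - 2.0 / (r * r))
            else:
                c1 = 1.0 - 9.0 * r / 32.0
                c2 = 3.0 * r / 32.0
            for p in range(3):
                for q in range(3):
                    blk[p, q] = c2 * e[p] * e[q]
                blk[p, p] += c1
            if mode == 2:
                h = pos[j, 2]
                Rx = pos[i, 0] - pos[j, 0]
                Ry = pos[i, 1] - pos[j, 1]
                Rz = pos[i, 2] + h
                R = np.empty(3)
                R[0], R[1], R[2] = Rx, Ry, Rz
                Rn = np.sqrt(Rx * Rx + Ry * Ry + Rz * Rz)
                Rn3 = Rn**3
                Rn5 = Rn**5
                for p in range(3):
                    for q in range(3):
                        # S_pq(R)
                        s = R[p] * R[q] / Rn3
                        if p == q:
                            s += 1.0 / Rn
                        # A_pq = h (delta/Rn^3 - 3 R R /Rn^5)
                        a_ = h * (-3.0 * R[p] * R[q] / Rn5)
                        if p == q:
                            a_ += h / Rn3
                        # B_pq = -d_{p3} R_q/Rn^3 + (d_pq R_3 + d_{3q} R_p)/Rn^3
                        #        - 3 R_p R_3 R_q / Rn^5
                        b_ = -3.0 * R[p] * R[2] * R[q] / Rn5
                        if p == 2:
                            b_ -= R[q] / Rn3
                        if p == q:
                            b_ += R[2] / Rn3
                        if q == 2:
                            b_ += R[p] / Rn3
                        sgn = -1.0 if q == 2 else 1.0
                        blk[p, q] += 0.75 * (-s + 2.0 * h * sgn * (a_ - b_))
            for p in range(3):
                for q in range(3):
                    M[3 * i + p, 3 * j + q] = blk[p, q]
                    M[3 * j + q, 3 * i + p] = blk[p, q]


@njit(cache=True)
def _forces(pos, eps, kappa, wall_on, sigma, wpref, soft_core, F):
    # reduced units: lengths in a, energies kBT; F (N,3) out
    n = pos.shape[0]
    F[:, :] = 0.0
    r_sc = soft_core * 2.0
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            r = np.sqrt(r2)
            r_eff = r if r > r_sc else r_sc
            s6 = (2.0 / r_eff) ** 6
            coef = 12.0 * eps * (s6 * s6 - s6) / (r_eff * r)
            F[i, 0] += coef * dx
            F[i, 1] += coef * dy
            F[i, 2] += coef * dz
            F[j, 0] -= coef * dx
            F[j, 1] -= coef * dy
            F[j, 2] -= coef * dz
    for i in range(n - 1):
        dx = pos[i + 1, 0] - pos[i, 0]
        dy = pos[i + 1, 1] - pos[i, 1]
        dz = pos[i + 1, 2] - pos[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        c = -kappa * (r - 2.0) / r
        F[i + 1, 0] += c * dx
        F[i + 1, 1] += c * dy
        F[i + 1, 2] += c * dz
        F[i, 0] -= c * dx
        F[i, 1] -= c * dy
        F[i, 2] -= c * dz
    if wall_on:
        pref = 8.0 * np.pi * wpref * sigma
        for i in range(n):
            z = pos[i, 2]
            if z < sigma:
                F[i, 2] += pref * (sigma**10 / z**11 - sigma**4 / z**5)


@njit(cache=True)
def _kernel(pos0, eps, kappa, sigma, wpref, mode, wall_on, grafted,
            shear_scaled, noise_on, gamma, dt, n_equil, n_steps, block,
            seed, record_pos, max_bond, max_step, soft_core):
    np.random.seed(seed)
    n = pos0.shape[0]
    pos = pos0.copy()
    n3 = 3 * n
    M = np.zeros((n3, n3))
    F = np.zeros((n, 3))
    n_blocks = n_steps // block
    block_means = np.zeros((n_blocks, n - 1))
    block_pos = np.zeros((n_blocks, n, 3)) if record_pos \
        else np.zeros((1, n, 3))
    acc = np.zeros(n - 1)
    b = 0
    sq2dt = np.sqrt(2.0 * dt)
    total = n_equil + n_blocks * block
    L = np.zeros((n3, n3))
    for s_idx in range(total):
        _mobility(pos, mode, M)
        # keep the (truncated) mobility positive semi-definite: repulsive
        # forces must never drive beads together through negative modes;
        # the Cholesky factor doubles as the noise square root
        have_l = False
        try:
            C = M.copy()
            for k in range(n3):
                C[k, k] += 1e-9
            L = np.linalg.cholesky(C)
            have_l = True
        except Exception:
            w, V = np.linalg.eigh(M)
            for k in range(n3):
                if w[k] < 1e-6:
                    w[k] = 1e-6
            M = (V * w) @ V.T
            L = V * np.sqrt(w)
            have_l = True
        _forces(pos, eps, kappa, wall_on, sigma, wpref, soft_core, F)
        vel = M @ F.reshape(n3)
        if gamma != 0.0:
            for i in range(n):
                vs = gamma * pos[i, 2]
                if shear_scaled:
                    for c in range(3):
                        vel[3 * i + c] += vs * M[3 * i + c, 3 * i]
                else:
                    vel[3 * i] += vs
        if mode == 2:
            for i in range(n):
                z = pos[i, 2]
                vel[3 * i + 2] += 1.125 / z**2 - 1.5 / z**4
        if grafted:
            # tether reaction force keeping bead 0 stationary (projection)
            lam = np.linalg.solve(np.ascontiguousarray(M[0:3, 0:3]),
                                  -np.ascontiguousarray(vel[0:3]))
            vel += np.ascontiguousarray(M[:, 0:3]) @ lam
        disp = vel * dt
        if noise_on and have_l:
            xi = np.random.standard_normal(n3)
            disp += sq2dt * (L @ xi)
        # uniform rescale of oversized steps preserves relative motion
        dmax = 0.0
        for i in range(n):
            if grafted and i == 0:
                continue
            dn = np.sqrt(disp[3 * i]**2 + disp[3 * i + 1]**2
                         + disp[3 * i + 2]**2)
            if dn > dmax:
                dmax = dn
        sc = max_step / dmax if dmax > max_step else 1.0
        for i in range(n):
            if grafted and i == 0:
                continue
            pos[i, 0] += sc * disp[3 * i]
            pos[i, 1] += sc * disp[3 * i + 1]
            pos[i, 2] += sc * disp[3 * i + 2]
            if wall_on and pos[i, 2] <= 0.0:
                pos[i, 2] = abs(pos[i, 2]) + 1e-9
        if s_idx >= n_equil:
            bmax = 0.0
            for i in range(n - 1):
                dx = pos[i + 1, 0] - pos[i, 0]
                dy = pos[i + 1, 1] - pos[i, 1]
                dz = pos[i + 1, 2] - pos[i, 2]
                bl = np.sqrt(dx * dx + dy * dy + dz * dz)
                acc[i] += bl
                if bl > bmax:
                    bmax = bl
            if bmax > max_bond or not np.isfinite(bmax):
                raise RuntimeError("BD step diverged: time step too large")
            if (s_idx - n_equil + 1) % block == 0:
                for i in range(n - 1):
                    block_means[b, i] = acc[i] / block
                    acc[i] = 0.0
                if record_pos:
                    for i in range(n):
                        for c in range(3):
                            block_pos[b, i, c] = pos[i, c]
                b += 1
    return block_means, pos, block_pos


def run_kernel_wrapper(pos0_nm: np.ndarray, cfg: ChainConfig, eng):
    """Convert to reduced units, run the jitted kernel, convert back."""
    a = cfg.a
    mu0 = stokes_mobility(a, eng.viscosity)
    tau_a = a**2 / (mu0 * kbt(cfg.temperature))
    block_means, final_pos, block_pos = _kernel(
        np.ascontiguousarray(pos0_nm / a),
        float(cfg.epsilon),
        float(cfg.kappa * a**2),
        float(cfg.sigma_r / a),
        float(cfg.wall_prefactor),
        _MODE[eng.hydrodynamics],
        bool(eng.wall),
        bool(eng.grafted),
        bool(eng.shear_mobility_scaling),
        bool(eng.thermal_noise),
        float(eng.shear_rate * tau_a),
        float(eng.dt / tau_a),
        int(eng.n_equil),
        int(eng.n_steps),
        int(eng.block_size),
        int(eng.seed),
        bool(eng.record_positions),
        float(10.0 * cfg.contour_length / a),
        float(eng.max_step_frac),
        float(cfg.soft_core),
    )
    return (block_means * a, final_pos * a,
            block_pos * a if eng.record_positions else None)
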