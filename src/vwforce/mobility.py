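"""Hydrodynamic mobility of a bead chain near a no-slip wall.

Builds the 3N x 3N mobility supermatrix in units of the Stokes mobility
mu0 = 1/(6 pi eta a), with lengths in units of the bead radius a:

* ``free`` mode — Rotne–Prager–Yamakawa pair mobilities (with the overlap
  form for r < 2a, which keeps the matrix positive semi-definite) and
  identity self blocks.
* ``wall`` mode — the free-space part plus Blake's image system for each
  stokeslet, i.e. the Rotne–Prager–Blake tensor.  Self blocks gain the
  standard wall corrections including the O((a/z)^3) finite-size terms,

      mu_par/mu0  = 1 - (9/16)(a/z) + (1/8)(a/z)^3,
      mu_perp/mu0 = 1 - (9/8)(a/z) + (1/2)(a/z)^3,

  so the mobility stays positive down to bead-wall contact (z = a).  The
  truncated far-field series is accurate for z >~ 1.2 a, which the
  repulsive wall potential enforces in practice.
* ``none`` mode — mu0 times the identity (free-draining).

The matrix is symmetric by construction (Blake's Green's function obeys
reciprocity) and positive semi-definite in the configurations the
simulations visit; the noise generator clips tiny negative eigenvalues if
truncation ever produces them.
"""

from __future__ import annotations

import numpy as np

_MODES = ("wall", "free", "none")


def rpy_block(dr: np.ndarray) -> np.ndarray:
    """Free-space Rotne–Prager–Yamakawa pair mobility block (units mu0).

    ``dr`` is the center-to-center vector in units of the bead radius a.
    """
    r = float(np.linalg.norm(dr))
    if r <= 0:
        raise ValueError("coincident beads in mobility computation")
    e = dr / r
    ee = np.outer(e, e)
    if r >= 2.0:
        return (3.0 / (4.0 * r)) * ((1.0 + 2.0 / (3.0 * r * r)) * np.eye(3)
                                    + (1.0 - 2.0 / (r * r)) * ee)
    return (1.0 - 9.0 * r / 32.0) * np.eye(3) + (3.0 * r / 32.0) * ee


def blake_image_block(xi: np.ndarray, xj: np.ndarray) -> np.ndarray:
    """Wall correction to the pair mobility from Blake's image system.

    Point-force (stokeslet) level: image stokeslet plus stokeslet-doublet
    and source-doublet images of a force at ``xj`` (height h) evaluated at
    ``xi``; both positions in units of a, wall at z = 0.  Returned in
    units of mu0 (the 1/(8 pi eta) prefactor becomes 3/4 in these units).
    """
    h = xj[2]
    R = xi - np.array([xj[0], xj[1], -h])
    Rn = float(np.linalg.norm(R))
    eye = np.eye(3)
    RR = np.outer(R, R)
    S = eye / Rn + RR / Rn**3

    # A_il = d/dR_l (h R_i / Rn^3)
    A = h * (eye / Rn**3 - 3.0 * RR / Rn**5)
    # B_il = d/dR_l S_i3(R)
    B = (-np.outer(eye[2], R) / Rn**3
         + (eye * R[2] + np.outer(R, eye[2])) / Rn**3
         - 3.0 * R[2] * RR / Rn**5)
    C = A - B
    sgn = np.array([1.0, 1.0, -1.0])
    G = -S + 2.0 * h * C * sgn[None, :]
    return 0.75 * G


def self_block_wall(z: float) -> np.ndarray:
    """Wall-corrected self mobility (units mu0) of a bead at height z/a."""
    if z <= 0:
        raise ValueError("bead at or below the wall")
    inv = 1.0 / z
    par = 1.0 - (9.0 / 16.0) * inv + 0.125 * inv**3
    perp = 1.0 - (9.0 / 8.0) * inv + 0.5 * inv**3
    return np.diag([par, par, perp])


def self_mobility_zz_derivative(z: float) -> float:
    """Analytic d(mu_perp/mu0)/dz at height z (both in units of a).

    This is the spurious-drift (divergence) correction of the propagator,
    v_corr = kBT * d mu_zz / dz, in reduced units.
    """
    return (9.0 / 8.0) / z**2 - 1.5 / z**4


def reduced_mobility(positions: np.ndarray, mode: str = "wall") -> np.ndarray:
    """3N x 3N mobility matrix in units of mu0; positions in units of a."""
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}")
    pos = np.asarray(positions, dtype=float)
    n = pos.shape[0]
    M = np.zeros((3 * n, 3 * n))
    if mode == "none":
        np.fill_diagonal(M, 1.0)
        return M
    if mode == "wall" and np.any(pos[:, 2] <= 0):
        raise ValueError("wall-corrected mobility requires all beads at z > 0")
    for i in range(n):
        si = slice(3 * i, 3 * i + 3)
        if mode == "wall":
            M[si, si] = self_block_wall(pos[i, 2])
        else:
            M[si, si] = np.eye(3)
        for j in range(i + 1, n):
            sj = slice(3 * j, 3 * j + 3)
            blk = rpy_block(pos[i] - pos[j])
            if mode == "wall":
                blk = blk + blake_image_block(pos[i], pos[j])
            M[si, sj] = blk
            M[sj, si] = blk.T
    return M
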