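"""Coarse-grained VWF force field.

A linear chain of N beads (one bead per VWF protomer, radius a = 30 nm)
interacting through a full attractive 12-6 Lennard-Jones potential with
minimum at contact distance 2a, harmonic backbone springs of rest length
2a, and a short-ranged repulsive 10-4 wall at z = 0:

    U_chain = eps * sum_{i<j} [(2a/r_ij)^12 - 2 (2a/r_ij)^6]
              + (kappa/2) * sum_i (r_{i,i+1} - 2a)^2
    U_wall(z) = 2 pi * w * (sigma_R/a) * [(2/5)(sigma_R/z)^10
                - (sigma_R/z)^4 + 3/5]  for 0 < z < sigma_R, else 0.

Energies are expressed in kBT, forces in kBT/nm.  A cohesion strength of
2 kBT collapses the untethered multimer into a globule, mimicking
circulating VWF.  The default spring constant is 203 kBT/a^2, which keeps
the explicit propagator stable at the standard 55 ns time step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import kbt


@dataclass
class ChainConfig:
    """Bead-spring chain parameters (physical units)."""

    n_beads: int = 20
    a: float = 30.0  # bead radius (protomer radius of gyration), nm
    epsilon: float = 2.0  # LJ cohesion strength, kBT
    kappa: float = 203.0 / 30.0**2  # backbone spring constant, kBT/nm^2
    sigma_r: float = 45.0  # wall repulsion range, nm
    temperature: float = 298.0  # K
    wall_prefactor: float = 1.0  # dimensionless multiplier of the 10-4 wall
    graft_height: float | None = None  # z of the grafted bead; default a
    #: soft-core radius as a fraction of the contact distance 2a; below it
    #: the Lennard-Jones force is held at its boundary value (linear energy
    #: continuation), so rare deep overlaps relax instead of exploding
    soft_core: float = 0.75

    def __post_init__(self) -> None:
        if self.n_beads < 1:
            raise ValueError("need at least 1 bead")
        if min(self.a, self.epsilon, self.kappa, self.sigma_r) <= 0:
            raise ValueError("a, epsilon, kappa and sigma_r must be positive")
        if self.graft_height is None:
            self.graft_height = self.a

    @property
    def contour_length(self) -> float:
        """(N-1) bonds of rest length 2a, in nm."""
        return (self.n_beads - 1) * 2.0 * self.a

    @property
    def kappa_pn_nm(self) -> float:
        """Spring constant in pN/nm at the configured temperature."""
        return self.kappa * kbt(self.temperature)


@dataclass
class ChainState:
    """Bead positions (N, 3) in nm; the wall is the plane z = 0."""

    positions: np.ndarray
    grafted_index: int = 0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (N, 3)")

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    def bond_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.positions, axis=0), axis=1)


def wall_energy(z, cfg: ChainConfig):
    """Repulsive truncated-shifted 10-4 wall energy (kBT) at height z (nm).

    Active for 0 < z < sigma_r, identically zero above; continuous (and
    with continuous force) at the cutoff.
    """
    z = np.asarray(z, dtype=float)
    if np.any(z <= 0):
        raise ValueError("z must be positive (bead below the wall)")
    s = cfg.sigma_r / z
    pref = 2.0 * np.pi * cfg.wall_prefactor * cfg.sigma_r / cfg.a
    u = pref * (0.4 * s**10 - s**4 + 0.6)
    out = np.where(z < cfg.sigma_r, u, 0.0)
    return out if out.ndim else float(out)


def wall_force(z, cfg: ChainConfig):
    """z-component of the wall force (kBT/nm), -dU/dz; repulsive."""
    z = np.asarray(z, dtype=float)
    if np.any(z <= 0):
        raise ValueError("z must be positive (bead below the wall)")
    pref = 8.0 * np.pi * cfg.wall_prefactor * cfg.sigma_r / cfg.a
    f = pref * (cfg.sigma_r**10 / z**11 - cfg.sigma_r**4 / z**5)
    out = np.where(z < cfg.sigma_r, f, 0.0)
    return out if out.ndim else float(out)


def _pair_distances(pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    diff = pos[:, None, :] - pos[None, :, :]
    r = np.linalg.norm(diff, axis=-1)
    return diff, r


def chain_energy(state: ChainState, cfg: ChainConfig,
                 include_wall: bool = True) -> float:
    """Total potential energy of the chain (kBT)."""
    pos = state.positions
    diff, r = _pair_distances(pos)
    iu = np.triu_indices(state.n_beads, k=1)
    rij = r[iu]
    if np.any(rij <= 0):
        raise ValueError("coincident beads: pair distance is zero")
    r_sc = cfg.soft_core * 2.0 * cfg.a
    s6 = (2.0 * cfg.a / np.maximum(rij, r_sc)) ** 6
    u = s6 * s6 - 2.0 * s6
    # linear continuation below the soft-core radius
    s6c = (2.0 * cfg.a / r_sc) ** 6
    f_sc = 12.0 * (s6c * s6c - s6c) / r_sc
    u = np.where(rij < r_sc, (s6c * s6c - 2.0 * s6c)
                 + f_sc * (r_sc - rij), u)
    e_lj = cfg.epsilon * np.sum(u)
    bonds = state.bond_lengths()
    e_spring = 0.5 * cfg.kappa * np.sum((bonds - 2.0 * cfg.a) ** 2)
    e_wall = np.sum(wall_energy(pos[:, 2], cfg)) if include_wall else 0.0
    return float(e_lj + e_spring + e_wall)


def chain_forces(state: ChainState, cfg: ChainConfig,
                 include_wall: bool = True) -> np.ndarray:
    """Analytic forces -dU/dr_i, shape (N, 3), in kBT/nm.

    The pairwise Lennard-Jones and spring contributions obey Newton's
    third law; the wall adds a per-bead z force.
    """
    pos = state.positions
    n = state.n_beads
    diff, r = _pair_distances(pos)
    np.fill_diagonal(r, np.inf)
    if np.any(r <= 0):
        raise ValueError("coincident beads: pair distance is zero")
    r_sc = cfg.soft_core * 2.0 * cfg.a
    r_eff = np.maximum(r, r_sc)
    s6 = (2.0 * cfg.a / r_eff) ** 6
    # f_i += 12 eps / r_eff^2 * (s12 - s6) * rhat * (r_eff/r) -> pair force
    # magnitude frozen at its soft-core boundary value for r < r_sc
    coef = 12.0 * cfg.epsilon * (s6 * s6 - s6) / (r_eff * r)
    forces = np.einsum("ij,ijk->ik", coef, diff)

    bonds_vec = pos[1:] - pos[:-1]
    bl = np.linalg.norm(bonds_vec, axis=1)
    fs = -cfg.kappa * (bl - 2.0 * cfg.a)[:, None] * bonds_vec / bl[:, None]
    forces[1:] += fs
    forces[:-1] -= fs

    if include_wall:
        forces[:, 2] += wall_force(pos[:, 2], cfg)
    return forces


def initial_positions(cfg: ChainConfig, mode: str = "coil",
                      seed: int = 0) -> np.ndarray:
    """Starting configurations.

    ``line``: bonds at rest along x at the graft height (useful for
    zero-temperature relaxation checks).  ``coil``: a compact self-avoiding
    random walk above the wall, close to the collapsed steady state, which
    shortens equilibration.
    """
    n, a = cfg.n_beads, cfg.a
    z0 = float(cfg.graft_height)
    if mode == "line":
        pos = np.zeros((n, 3))
        pos[:, 0] = 2.0 * a * np.arange(n)
        pos[:, 2] = z0
        return pos
    if mode != "coil":
        raise ValueError(f"unknown init mode {mode!r}")
    rng = np.random.default_rng(seed)
    pos = np.zeros((n, 3))
    pos[0] = (0.0, 0.0, z0)
    z_min = 1.2 * a
    for i in range(1, n):
        for _ in range(500):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            cand = pos[i - 1] + 2.0 * a * v
            if cand[2] < z_min:
                continue
            if i >= 2 and np.min(
                    np.linalg.norm(pos[:i - 1] - cand, axis=1)) < 1.6 * a:
                continue
            pos[i] = cand
            break
        else:  # pragma: no cover - extremely unlikely
            pos[i] = pos[i - 1] + (0.0, 0.0, 2.0 * a)
    return pos
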