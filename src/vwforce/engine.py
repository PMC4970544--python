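"""Brownian-dynamics propagation of the grafted chain under shear.

Explicit first-order propagation with hydrodynamic interactions:

    dr_i = [ v_shear(z_i) (mu_ii/mu0) x_hat + sum_j mu_ij F_j
             + v_corr(z_i) z_hat ] dt + dr_random,

where v_shear(z) = gamma_dot * z is the linear shear profile (advection
scaled by the normalized self mobility), F_j the total deterministic force
on bead j, v_corr = kBT d(mu_zz)/dz the spurious-drift correction of the
wall-corrected mobility, and dr_random a zero-mean Gaussian with
covariance 2 kBT dt mu (fluctuation-dissipation), realized through a
Cholesky factor.  The grafted bead never moves; a bead diffusing through
the plane z = 0 is reflected.

The public API works in physical units (nm, pN, s); the numba production
kernel (:mod:`vwforce.fastengine`) runs the same scheme in reduced units
(length a, energy kBT, mobility mu0, time tau_a = a^2/(mu0 kBT) ~
1.1e-4 s for a 30 nm bead in water).  Production runs record block
averages of all bond lengths; the block means yield the tensile-force
profile f_i = kappa (<r_{i,i+1}> - 2a) with standard errors corrected by
the integrated autocorrelation time of the block series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .bdmodel import ChainConfig, ChainState, chain_forces, initial_positions
from .constants import kbt, stokes_mobility
from .evans_ritchie import bell_evans_lifetime
from .mobility import reduced_mobility, self_mobility_zz_derivative

#: Shear rates of the reference sweep, 1/s.
SWEEP_SHEAR_RATES = (5.5, 18.0, 55.0, 182.0, 545.0, 1818.0, 5453.0, 18175.0)


@dataclass
class EngineConfig:
    """Integration and recording parameters."""

    shear_rate: float = 0.0  # 1/s
    dt: float = 55e-9  # s
    n_steps: int = 100_000
    n_equil: int = 100_000
    block_size: int = 100
    viscosity: float = 0.89e-3  # Pa s
    seed: int = 0
    hydrodynamics: str = "wall"  # wall | free | none
    shear_mobility_scaling: bool = True  # advection scaled by mu_ii/mu0
    wall: bool = True  # wall potential + reflection active
    grafted: bool = True  # bead 0 held fixed
    thermal_noise: bool = True
    backend: str = "auto"  # auto | numba | numpy
    record_positions: bool = False
    init: str = "coil"  # coil | line
    #: per-bead displacement cap per step, as a fraction of the bead radius;
    #: tames the rare steep Lennard-Jones kicks of near-overlapping beads
    max_step_frac: float = 0.15

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.n_steps < 1 or self.n_equil < 0:
            raise ValueError("dt > 0, n_steps >= 1, n_equil >= 0 required")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")
        if self.hydrodynamics not in ("wall", "free", "none"):
            raise ValueError("hydrodynamics must be wall, free or none")

    def simulated_time(self, n_steps: int | None = None) -> float:
        """Physical time covered by ``n_steps`` (default: configured) steps."""
        return self.dt * (self.n_steps if n_steps is None else n_steps)


@dataclass
class TensileProfile:
    """Per-bond mean tension of the grafted chain in steady shear."""

    mean_bond_length: np.ndarray  # nm, length N-1
    tensile_force: np.ndarray  # pN
    se: np.ndarray  # pN, standard error from block means
    shear_rate: float  # 1/s
    contour_length: float  # nm

    @property
    def grafted_end_tension(self) -> float:
        """f_0, the tension of the bond at the grafted end (pN)."""
        return float(self.tensile_force[0])


@dataclass
class BDResult:
    profile: TensileProfile
    block_bond_lengths: np.ndarray  # (n_blocks, N-1), nm
    final_positions: np.ndarray  # (N, 3), nm
    block_positions: np.ndarray | None = None  # (n_blocks, N, 3), nm
    chain: ChainConfig = field(default_factory=ChainConfig)
    engine: EngineConfig = field(default_factory=EngineConfig)


def time_unit(cfg: ChainConfig, eng: EngineConfig) -> float:
    """Diffusive time tau_a = a^2/(mu0 kBT) in seconds."""
    mu0 = stokes_mobility(cfg.a, eng.viscosity)
    return cfg.a**2 / (mu0 * kbt(cfg.temperature))


def mobility_matrix(state: ChainState, cfg: ChainConfig,
                    eng: EngineConfig) -> np.ndarray:
    """Physical mobility matrix, nm/(pN s), shape (3N, 3N)."""
    mu0 = stokes_mobility(cfg.a, eng.viscosity)
    return mu0 * reduced_mobility(state.positions / cfg.a, eng.hydrodynamics)


def drift_correction(state: ChainState, cfg: ChainConfig,
                     eng: EngineConfig) -> np.ndarray:
    """Per-bead z drift velocity kBT d(mu_ii^zz)/dz_i, nm/s.

    Zero in free-space and free-draining modes, where the self mobility is
    position independent.
    """
    n = state.n_beads
    if eng.hydrodynamics != "wall":
        return np.zeros(n)
    mu0 = stokes_mobility(cfg.a, eng.viscosity)
    z = state.positions[:, 2] / cfg.a
    dmu = np.array([self_mobility_zz_derivative(zi) for zi in z])
    return kbt(cfg.temperature) * mu0 * dmu / cfg.a


def random_displacement(mu: np.ndarray, dt: float, temperature: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Correlated Gaussian displacement with covariance 2 kBT dt mu (nm).

    Uses a Cholesky factor, falling back to an eigenvalue square root with
    clipped negative modes if the (numerically) truncated mobility is not
    strictly positive definite.
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    if dt == 0:
        return np.zeros(mu.shape[0])
    C = 2.0 * kbt(temperature) * dt * np.asarray(mu, float)
    try:
        L = np.linalg.cholesky(C + 1e-12 * np.trace(C) / C.shape[0]
                               * np.eye(C.shape[0]))
    except np.linalg.LinAlgError:
        # truncated far-field mobility can lose strict positive
        # definiteness in rare close configurations; clip those modes
        w, V = np.linalg.eigh(C)
        if w.min() < -0.1 * max(w.max(), 1e-300):
            raise np.linalg.LinAlgError(
                "mobility matrix is far from positive semi-definite")
        L = V * np.sqrt(np.clip(w, 0.0, None))
    return L @ rng.standard_normal(mu.shape[0])


def step(state: ChainState, cfg: ChainConfig, eng: EngineConfig,
         rng: np.random.Generator, mu: np.ndarray | None = None) -> ChainState:
    """One explicit propagation step (reference numpy implementation)."""
    pos = state.positions
    n = state.n_beads
    if mu is None:
        mu = mobility_matrix(state, cfg, eng)
    mu0 = stokes_mobility(cfg.a, eng.viscosity)
    # the truncated far-field mobility can lose positive definiteness in
    # tight wall-near configurations; clip such modes before use so that
    # repulsive forces can never drive beads together
    try:
        np.linalg.cholesky(mu + 1e-9 * mu0 * np.eye(3 * n))
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(mu)
        mu = (V * np.clip(w, 1e-6 * mu0, None)) @ V.T

    forces = chain_forces(state, cfg, include_wall=eng.wall) \
        * kbt(cfg.temperature)  # pN
    vel = mu @ forces.ravel()  # nm/s

    if eng.shear_rate != 0.0:
        vshear = eng.shear_rate * pos[:, 2]  # nm/s
        for i in range(n):
            if eng.shear_mobility_scaling:
                col = mu[3 * i:3 * i + 3, 3 * i] / mu0
            else:
                col = np.array([1.0, 0.0, 0.0])
            vel[3 * i:3 * i + 3] += vshear[i] * col

    vcorr = drift_correction(state, cfg, eng)
    vel[2::3] += vcorr

    if eng.grafted:
        # constraint by projection: the tether exerts the reaction force
        # that keeps bead 0 stationary, and that reaction couples back to
        # the rest of the chain through the mobility
        g = state.grafted_index
        sg = slice(3 * g, 3 * g + 3)
        lam = -np.linalg.solve(mu[sg, sg], vel[sg])
        vel += mu[:, sg] @ lam

    disp = vel * eng.dt
    if eng.thermal_noise:
        disp += random_displacement(mu, eng.dt, cfg.temperature, rng)

    dvec = disp.reshape(n, 3)
    cap = eng.max_step_frac * cfg.a
    mobile = np.ones(n, dtype=bool)
    if eng.grafted:
        mobile[state.grafted_index] = False
    dmax = np.linalg.norm(dvec[mobile], axis=1).max() if mobile.any() else 0.0
    if dmax > cap:  # uniform rescale preserves relative motion
        dvec = dvec * (cap / dmax)
    new = pos + dvec
    if eng.grafted:
        new[state.grafted_index] = pos[state.grafted_index]
    if eng.wall:
        below = new[:, 2] <= 0
        new[below, 2] = np.abs(new[below, 2]) + 1e-9 * cfg.a

    bonds = np.linalg.norm(np.diff(new, axis=0), axis=1)
    if not np.all(np.isfinite(new)) or (
            bonds.size and bonds.max() > 10.0 * cfg.contour_length):
        raise RuntimeError("BD step diverged (bond > 10 x contour length); "
                           "the time step is too large for these parameters")
    return ChainState(positions=new, grafted_index=state.grafted_index)


def integrated_autocorr_time(x: np.ndarray, window: int = 400) -> float:
    """Integrated autocorrelation time of a series, in sampling intervals.

    Initial-positive-sequence estimator; the standard error of the series
    mean is sd * sqrt(tau / n).  Used to de-bias block-mean errors, whose
    blocks are correlated through slow conformational modes.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    v = x.var()
    if n < 4 or v == 0:
        return 1.0
    xc = x - x.mean()
    acf = np.correlate(xc, xc, "full")[n - 1:] / (np.arange(n, 0, -1) * v)
    tau = 1.0
    for t in range(1, min(n // 4, window)):
        if acf[t] <= 0:
            break
        tau += 2.0 * acf[t]
    return float(tau)


def tensile_profile(mean_bond_lengths, cfg: ChainConfig,
                    shear_rate: float = 0.0,
                    se_bond_lengths=None) -> TensileProfile:
    """Tensile forces f_i = kappa (<r_{i,i+1}> - 2a), converted to pN."""
    mb = np.asarray(mean_bond_lengths, dtype=float)
    if mb.size != cfg.n_beads - 1:
        raise ValueError("expected N-1 mean bond lengths")
    k_pn = cfg.kappa_pn_nm  # pN/nm
    se = (np.zeros_like(mb) if se_bond_lengths is None
          else k_pn * np.asarray(se_bond_lengths, float))
    return TensileProfile(
        mean_bond_length=mb,
        tensile_force=k_pn * (mb - 2.0 * cfg.a),
        se=se,
        shear_rate=shear_rate,
        contour_length=cfg.contour_length,
    )


def lifetime_under_shear(profile: TensileProfile, tau0: float, x_beta: float,
                         temperature: float = 298.0) -> float:
    """Bell-equation lifetime at the grafted-end bond tension.

    Negative (compressive) mean tension is clamped to zero with a warning:
    compression does not accelerate rupture in the Bell regime.
    """
    f0 = profile.grafted_end_tension
    if f0 < 0:
        warnings.warn("grafted-end tension is compressive; clamping to 0 "
                      "for the lifetime estimate", stacklevel=2)
        f0 = 0.0
    return float(bell_evans_lifetime(f0, tau0, x_beta, temperature))


def _run_numpy(pos0: np.ndarray, cfg: ChainConfig, eng: EngineConfig):
    rng = np.random.default_rng(eng.seed)
    state = ChainState(positions=pos0.copy())
    n_blocks = eng.n_steps // eng.block_size
    block_means = np.zeros((n_blocks, cfg.n_beads - 1))
    block_pos = (np.zeros((n_blocks, cfg.n_beads, 3))
                 if eng.record_positions else None)
    acc = np.zeros(cfg.n_beads - 1)
    b = 0
    for s in range(eng.n_equil + n_blocks * eng.block_size):
        state = step(state, cfg, eng, rng)
        if s >= eng.n_equil:
            acc += state.bond_lengths()
            if (s - eng.n_equil + 1) % eng.block_size == 0:
                block_means[b] = acc / eng.block_size
                if block_pos is not None:
                    block_pos[b] = state.positions
                acc[:] = 0.0
                b += 1
    return block_means, state.positions, block_pos


def run(cfg: ChainConfig | None = None, eng: EngineConfig | None = None,
        initial: np.ndarray | None = None) -> BDResult:
    """Equilibrate, run production, and return the tensile-force profile.

    Block means of all bond lengths are recorded every ``block_size``
    steps; the profile is the average of block means and its standard
    error comes from their scatter.
    """
    cfg = cfg or ChainConfig()
    eng = eng or EngineConfig()
    pos0 = (initial.copy() if initial is not None
            else initial_positions(cfg, eng.init, seed=eng.seed))

    backend = eng.backend
    if backend == "auto":
        try:
            from . import fastengine  # noqa: F401
            backend = "numba"
        except ImportError:  # pragma: no cover - numba always present in CI
            backend = "numpy"
    if backend == "numba":
        from .fastengine import run_kernel_wrapper
        block_means, final_pos, block_pos = run_kernel_wrapper(pos0, cfg, eng)
    else:
        block_means, final_pos, block_pos = _run_numpy(pos0, cfg, eng)

    mean_bonds = block_means.mean(axis=0)
    nb = block_means.shape[0]
    if nb > 1:
        tau = np.array([integrated_autocorr_time(block_means[:, i])
                        for i in range(block_means.shape[1])])
        se_bonds = (block_means.std(axis=0, ddof=1)
                    * np.sqrt(tau / nb))
    else:
        se_bonds = np.zeros_like(mean_bonds)
    profile = tensile_profile(mean_bonds, cfg, shear_rate=eng.shear_rate,
                              se_bond_lengths=se_bonds)
    return BDResult(profile=profile, block_bond_lengths=block_means,
                    final_positions=final_pos, block_positions=block_pos,
                    chain=cfg, engine=eng)


def sweep(cfg: ChainConfig | None = None, eng: EngineConfig | None = None,
          shear_rates=SWEEP_SHEAR_RATES) -> list[BDResult]:
    """Run the shear-rate series, one seeded run per rate."""
    cfg = cfg or ChainConfig()
    eng = eng or EngineConfig()
    results = []
    for k, gamma in enumerate(shear_rates):
        e = EngineConfig(**{**eng.__dict__, "shear_rate": float(gamma),
                            "seed": eng.seed + k})
        results.append(run(cfg, e))
    return results
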