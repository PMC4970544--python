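"""Synthetic SMFS data generation.

Generates every input the analysis pipeline consumes without touching an
instrument: rupture-event datasets drawn from known single-barrier ground
truth, retraction traces with a parabolic linker-stretching segment ending
in a rupture jump, and bimodal force samples for first-peak fitting.

Study conditions follow the measurement protocol being emulated: nine
pulling velocities (50 ... 3000 nm/s), at least ~1000 cycles per velocity
for reliable statistics, a cantilever spring constant of 0.03 N/m
(30 pN/nm), and a blocking condition in which the binding probability
collapses.  Noise level and nonspecific-adhesion rate of the real
instrument are not on record; defaults (5 pN sd, 10%) are realistic
placeholders and fully configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import kbt
from .evans_ritchie import effective_spring, evans_ritchie_ppf
from .fdc import FDCTrace, RuptureEvent

#: The nine pulling velocities of the emulated protocol, nm/s.
STUDY_VELOCITIES = (50.0, 100.0, 200.0, 400.0, 600.0, 800.0, 1200.0,
                    2000.0, 3000.0)

#: Floor for per-event effective spring constants, pN/nm.
KEFF_FLOOR = 0.1


@dataclass(frozen=True)
class BellGroundTruth:
    """Single-barrier kinetic ground truth for the generator."""

    koff: float = 0.01  # 1/s
    x_beta: float = 0.3  # nm
    temperature: float = 298.0

    def __post_init__(self) -> None:
        if self.koff <= 0 or self.x_beta <= 0 or self.temperature <= 0:
            raise ValueError("kinetic ground-truth parameters must be positive")


@dataclass
class SyntheticFDCParams:
    """Parameters of the synthetic force-distance-cycle generator."""

    velocity: float = 400.0  # nm/s
    cantilever_k: float = 30.0  # pN/nm (0.03 N/m probe)
    linker_keff: float = 5.0  # linker stiffness, pN/nm
    rupture_model: BellGroundTruth = field(default_factory=BellGroundTruth)
    noise_sd: float = 5.0  # pN
    specific_fraction: float = 0.4
    nonspecific_fraction: float = 0.1
    n_cycles: int = 200
    seed: int = 0
    sampling_per_nm: float = 1.0  # points per nm of distance
    tether_start: float = 30.0  # nm, where the linker engages

    def __post_init__(self) -> None:
        if not (0 <= self.specific_fraction <= 1
                and 0 <= self.nonspecific_fraction <= 1
                and self.specific_fraction + self.nonspecific_fraction <= 1):
            raise ValueError("specific_fraction + nonspecific_fraction must "
                             "lie in [0, 1]")
        if min(self.cantilever_k, self.linker_keff, self.velocity,
               self.sampling_per_nm) <= 0 or self.noise_sd < 0:
            raise ValueError("stiffnesses, velocity and sampling must be "
                             "positive; noise_sd >= 0")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")

    @property
    def keff(self) -> float:
        """Series stiffness of cantilever and linker (slope at rupture)."""
        return effective_spring(self.cantilever_k, self.linker_keff)


def gen_rupture_dataset(
    koff: float,
    x_beta: float,
    velocities,
    keff_mean: float,
    keff_sd: float,
    n_per_velocity: int,
    temperature: float = 298.0,
    seed: int = 0,
) -> list[RuptureEvent]:
    """Draw rupture events from the Evans–Ritchie model at each velocity.

    Per event, keff is Gaussian (truncated at 0.1 pN/nm), the loading rate
    is r = keff*v, and the rupture force is drawn by the analytic inverse
    CDF.  Reproducible for a given seed.
    """
    if koff <= 0 or x_beta <= 0 or temperature <= 0:
        raise ValueError("koff, x_beta and temperature must be positive")
    velocities = np.atleast_1d(np.asarray(velocities, dtype=float))
    if np.any(velocities <= 0) or keff_mean <= 0 or keff_sd < 0:
        raise ValueError("velocities and keff_mean must be positive; "
                         "keff_sd >= 0")
    if n_per_velocity < 1:
        raise ValueError("n_per_velocity must be >= 1")

    rng = np.random.default_rng(seed)
    events: list[RuptureEvent] = []
    for v in velocities:
        keff = np.maximum(rng.normal(keff_mean, keff_sd, n_per_velocity),
                          KEFF_FLOOR)
        r = keff * v
        u = rng.random(n_per_velocity)
        F = evans_ritchie_ppf(u, r, koff, x_beta, temperature)
        for Fi, ki in zip(F, keff):
            events.append(RuptureEvent(force=float(Fi), keff=float(ki),
                                       velocity=float(v)))
    return events


def _specific_segment(d: np.ndarray, d_r: float, keff: float,
                      force: float) -> np.ndarray:
    """Parabolic linker stretch ending in a rupture jump of size ``force``.

    The parabola F(x) = -A (x - d_start)^2 reaches -force at the rupture
    distance d_r with local slope exactly -keff there (series stiffness of
    cantilever and linker).  ``d_r`` should lie on the sampling grid so
    the last loaded sample carries the full rupture force.
    """
    d_start = d_r - 2.0 * force / keff
    amp = keff**2 / (4.0 * force)
    f = np.zeros_like(d)
    stretch = (d >= d_start) & (d <= d_r)
    f[stretch] = -amp * (d[stretch] - d_start) ** 2
    return f


def gen_fdc_traces(params: SyntheticFDCParams) -> list[FDCTrace]:
    """Generate synthetic retraction traces.

    Each cycle is, with probability ``specific_fraction``, a specific
    unbinding event (parabolic stretch, rupture force from the ground-truth
    model at r = keff*v); with probability ``nonspecific_fraction`` a
    short-range adhesion spike near contact; otherwise event-free baseline.
    Ground truth is recorded in ``trace.meta``.
    """
    rng = np.random.default_rng(params.seed)
    model = params.rupture_model
    keff = params.keff
    r = keff * params.velocity
    dx = 1.0 / params.sampling_per_nm

    traces: list[FDCTrace] = []
    for _ in range(params.n_cycles):
        kind = rng.random()
        if kind < params.specific_fraction:
            F = float(evans_ritchie_ppf(rng.random(), r, model.koff,
                                        model.x_beta, model.temperature))
            # snap the rupture point onto the sampling grid so the last
            # loaded sample carries the full rupture force
            d_r = dx * round((params.tether_start + 2.0 * F / keff) / dx)
            extent = max(200.0, 1.6 * d_r + 50.0)
            d = np.arange(0.0, extent, dx)
            f = _specific_segment(d, d_r, keff, F)
            meta = {"kind": "specific",
                    "events": [{"distance": d_r, "force": F, "keff": keff}]}
        elif kind < params.specific_fraction + params.nonspecific_fraction:
            d = np.arange(0.0, 200.0, dx)
            f = np.zeros_like(d)
            f_ns = rng.uniform(20.0, 100.0)
            d_ns = 10.0
            near = d <= d_ns
            f[near] = -f_ns * (1.0 - d[near] / (2.0 * d_ns))
            meta = {"kind": "nonspecific", "events": []}
        else:
            d = np.arange(0.0, 200.0, dx)
            f = np.zeros_like(d)
            meta = {"kind": "empty", "events": []}
        if params.noise_sd > 0:
            f = f + rng.normal(0.0, params.noise_sd, f.size)
        traces.append(FDCTrace(distance=d, force=f, velocity=params.velocity,
                               cantilever_k=params.cantilever_k, meta=meta))
    return traces


def gen_bimodal_forces(mu1: float, sd1: float, mu2: float, sd2: float,
                       w1: float, n: int, seed: int = 0) -> np.ndarray:
    """Two-component Gaussian mixture sample (fixture for first-peak fits)."""
    if not mu1 < mu2:
        raise ValueError("mu1 must be smaller than mu2")
    if not 0 < w1 <= 1:
        raise ValueError("w1 must lie in (0, 1]")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("sd1 and sd2 must be positive")
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    comp = rng.random(n) < w1
    out = np.where(comp, rng.normal(mu1, sd1, n), rng.normal(mu2, sd2, n))
    return out
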