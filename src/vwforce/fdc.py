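"""Force-distance-cycle (FDC) analysis.

Extracts unbinding (rupture) events from AFM retraction traces and builds
the per-velocity statistics used by the kinetic fits: rupture force and
effective spring constant per event, binding probability, Gaussian fit to
the first peak of the force distribution, and the mu +/- sigma selection.

A retraction trace is stored with the conventional AFM sign convention: the
baseline (free cantilever) sits at zero force, a loaded tether pulls the
force negative, and rupture appears as a discontinuous jump back toward the
baseline. Rupture force magnitudes are reported positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks, peak_widths
from scipy.stats import gaussian_kde


@dataclass
class FDCTrace:
    """One retraction curve: tip-sample distance (nm) vs force (pN).

    ``distance`` must be monotonically increasing along the retraction.
    ``meta`` is free-form; the synthetic generator stores ground-truth
    event positions there for round-trip testing.
    """

    distance: np.ndarray
    force: np.ndarray
    velocity: float  # pulling velocity, nm/s
    cantilever_k: float  # cantilever spring constant, pN/nm
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.distance = np.asarray(self.distance, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.distance.ndim != 1 or self.distance.shape != self.force.shape:
            raise ValueError("distance and force must be 1-D arrays of equal length")
        if self.distance.size < 2:
            raise ValueError("trace needs at least 2 samples")
        if self.velocity <= 0:
            raise ValueError("velocity must be positive")


@dataclass(frozen=True)
class RuptureEvent:
    """A single unbinding event: the atom of all kinetic fits."""

    force: float  # rupture force F, pN
    keff: float  # slope at rupture, pN/nm
    velocity: float  # pulling velocity v, nm/s
    loading_rate: float = 0.0  # r = keff * v, pN/s

    def __post_init__(self) -> None:
        if self.force <= 0 or self.keff <= 0 or self.velocity <= 0:
            raise ValueError("force, keff and velocity must be positive")
        object.__setattr__(self, "loading_rate", self.keff * self.velocity)


@dataclass(frozen=True)
class PeakFit:
    """Gaussian fit (mu, sigma) to the first peak of a force distribution."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @property
    def interval(self) -> tuple[float, float]:
        return (self.mu - self.sigma, self.mu + self.sigma)


@dataclass(frozen=True)
class BindingStats:
    """Binding probability: fraction of FDCs showing an unbinding event."""

    n_total: int
    n_with_event: int

    @property
    def bp(self) -> float:
        return self.n_with_event / self.n_total


def detect_rupture(
    trace: FDCTrace,
    snr_threshold: float = 4.0,
    fit_window: float = 20.0,
    poly_order: int = 2,
    min_force: float = 5.0,
    min_distance: float = 15.0,
) -> list[RuptureEvent]:
    """Locate rupture events in a retraction trace.

    The baseline and its noise level are estimated from the final 20% of
    the trace (far from the surface; median and MAD-based sd).  Candidate
    ruptures are single-sample force jumps back toward the baseline that
    exceed ``snr_threshold`` times the noise sd of a difference (and an
    absolute floor ``min_force``, which also rejects the sample-to-sample
    rise of the stretching segment itself).  For each event a polynomial of
    order ``poly_order`` is fitted to the stretching segment within
    ``fit_window`` nm before the jump; the rupture force is the gap between
    baseline and the fitted force at the jump onset, and keff is the
    magnitude of the fitted slope there.

    Events closer than ``min_distance`` nm to the surface are discarded as
    nonspecific adhesion — the automated stand-in for the manual
    "parabolic fingerprint" discrimination.

    Returns events sorted by distance; an event-free trace gives ``[]``.
    """
    if snr_threshold <= 0:
        raise ValueError("snr_threshold must be positive")
    d, f = trace.distance, trace.force
    span = d[-1] - d[0]
    if span <= fit_window:
        raise ValueError("trace shorter than fit_window")

    n_tail = max(4, int(0.2 * d.size))
    tail = f[-n_tail:]
    baseline = float(np.median(tail))

    jumps = np.diff(f)
    # robust noise of a single difference from the whole trace (slopes and
    # the rare jumps are outliers to the median)
    sd_diff = 1.4826 * float(np.median(np.abs(jumps - np.median(jumps))))
    thr = max(snr_threshold * sd_diff, min_force)
    cand = np.flatnonzero(jumps > thr)
    if cand.size == 0:
        return []

    # group consecutive samples belonging to one jump; onset = first index
    groups: list[int] = []
    for idx in cand:
        if groups and idx - groups[-1] <= 1:
            continue
        groups.append(int(idx))

    events: list[RuptureEvent] = []
    for i0 in groups:
        x0 = d[i0]
        if x0 < min_distance:
            continue
        sel = (d >= x0 - fit_window) & (d <= x0)
        if np.count_nonzero(sel) < poly_order + 2:
            continue
        coeffs = np.polyfit(d[sel] - x0, f[sel], poly_order)
        f_at_onset = np.polyval(coeffs, 0.0)
        slope = np.polyval(np.polyder(coeffs), 0.0)
        force = baseline - f_at_onset
        keff = abs(slope)
        if force >= min_force and keff > 0:
            events.append(RuptureEvent(force=float(force), keff=float(keff),
                                       velocity=trace.velocity))
    return events


def binding_probability(events_per_trace: Sequence[Sequence]) -> BindingStats:
    """Binding probability from per-trace event lists."""
    if len(events_per_trace) == 0:
        raise ValueError("need at least one trace")
    n_with = sum(1 for ev in events_per_trace if len(ev) > 0)
    return BindingStats(n_total=len(events_per_trace), n_with_event=n_with)


def _gauss(x, amp, mu, sigma):
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def fit_first_peak(
    forces: Sequence[float],
    n_bins: int | None = None,
    min_count: int = 50,
) -> PeakFit:
    """Fit a Gaussian to the lowest-force peak of the force distribution.

    The lowest peak corresponds, in most cases, to the fingerprint of the
    specific single-complex rupture; higher peaks (multiple tethers,
    unfolding) are ignored.  Raises ``ValueError`` when no local maximum
    can be identified (e.g. a degenerate zero-width distribution).
    """
    forces = np.asarray(forces, dtype=float)
    if forces.size < min_count:
        raise ValueError(f"need at least {min_count} forces, got {forces.size}")
    if np.ptp(forces) <= 0:
        raise ValueError("zero-width force distribution: no peak to fit")

    # a kernel density is far less prone to spurious local maxima than a
    # raw histogram; the Gaussian is fitted to the density around the
    # lowest peak and its sigma deconvolved from the KDE bandwidth
    try:
        kde = gaussian_kde(forces)
    except np.linalg.LinAlgError as exc:
        raise ValueError("degenerate force distribution: KDE failed") from exc
    n_grid = 4 * n_bins if n_bins else 512
    pad = 0.1 * np.ptp(forces)
    grid = np.linspace(forces.min() - pad, forces.max() + pad, n_grid)
    dens = kde(grid)
    peaks, _ = find_peaks(dens, prominence=0.05 * dens.max())
    if peaks.size == 0:
        raise ValueError("no local maximum found in the force density; "
                         "check the input distribution")
    p = int(peaks[0])  # lowest-force peak
    widths = peak_widths(dens, [p], rel_height=0.5)[0]
    dg = grid[1] - grid[0]
    sigma0 = max(widths[0] * dg / 2.355, dg)
    mu0 = grid[p]

    window = (grid > mu0 - 1.5 * sigma0) & (grid < mu0 + 1.5 * sigma0)
    try:
        popt, _ = curve_fit(
            _gauss, grid[window], dens[window],
            p0=(dens[p], mu0, sigma0),
            bounds=([0, grid[0], 1e-6], [np.inf, grid[-1], np.ptp(forces)]),
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological densities
        raise ValueError(f"Gaussian fit to first peak failed: {exc}") from exc
    bw = kde.factor * forces.std(ddof=1)
    sigma = float(np.sqrt(max(popt[2] ** 2 - bw ** 2, dg ** 2)))
    return PeakFit(mu=float(popt[1]), sigma=sigma)


def select_mu_sigma(forces: Sequence[float], peak: PeakFit) -> np.ndarray:
    """Forces inside the closed interval [mu - sigma, mu + sigma]."""
    forces = np.asarray(forces, dtype=float)
    lo, hi = peak.interval
    return forces[(forces >= lo) & (forces <= hi)]


def last_event_per_trace(events_per_trace: Sequence[Sequence[RuptureEvent]]
                         ) -> list[RuptureEvent]:
    """Standard SMFS convention: keep the last (farthest) rupture per trace."""
    return [ev[-1] for ev in events_per_trace if len(ev) > 0]
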