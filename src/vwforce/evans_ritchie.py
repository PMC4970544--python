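"""Single-energy-barrier (Bell–Evans / Evans–Ritchie) rupture kinetics.

Under a force ramp with constant loading rate r, a bond whose off-rate
grows exponentially with force, k(F) = koff * exp(x_beta*F/kBT), ruptures
at a force distributed as

    p(F | r) = (koff/r) * exp(x_beta*F/kBT)
               * exp[-(koff*kBT/(r*x_beta)) * (exp(x_beta*F/kBT) - 1)].

This module provides the density, its analytic CDF/quantile function, a
per-event maximum-likelihood fit over (koff, x_beta), the Bell lifetime
law tau(F) = tau0 * exp(-x_beta*F/kBT), and the loading-rate arithmetic
LR = V*ke with the series spring composition 1/ke = 1/ks + 1/kp.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .constants import kbt
from .fdc import RuptureEvent

_EXP_CLIP = 700.0


def _validate(r, koff, x_beta, temperature):
    if np.any(np.asarray(r) <= 0):
        raise ValueError("loading rate r must be positive (no quasi-static limit)")
    if koff <= 0 or x_beta <= 0 or temperature <= 0:
        raise ValueError("koff, x_beta and temperature must be positive")


def evans_ritchie_logpdf(F, r, koff: float, x_beta: float,
                         temperature: float = 298.0):
    """Log rupture-force density log p(F | r); F in pN, r in pN/s."""
    _validate(r, koff, x_beta, temperature)
    F = np.asarray(F, dtype=float)
    r = np.asarray(r, dtype=float)
    kt = kbt(temperature)
    u = np.clip(x_beta * F / kt, -_EXP_CLIP, _EXP_CLIP)
    return np.log(koff) - np.log(r) + u - (koff * kt / (r * x_beta)) * np.expm1(u)


def evans_ritchie_pdf(F, r, koff: float, x_beta: float,
                      temperature: float = 298.0):
    """Rupture-force density p(F | r) in 1/pN at constant loading rate r."""
    return np.exp(evans_ritchie_logpdf(F, r, koff, x_beta, temperature))


def evans_ritchie_cdf(F, r, koff: float, x_beta: float,
                      temperature: float = 298.0):
    """P(rupture force <= F) at loading rate r."""
    _validate(r, koff, x_beta, temperature)
    F = np.asarray(F, dtype=float)
    kt = kbt(temperature)
    u = np.clip(x_beta * F / kt, -_EXP_CLIP, _EXP_CLIP)
    return -np.expm1(-(koff * kt / (np.asarray(r, float) * x_beta)) * np.expm1(u))


def evans_ritchie_ppf(q, r, koff: float, x_beta: float,
                      temperature: float = 298.0):
    """Quantile function (analytic inverse CDF); used for sampling."""
    _validate(r, koff, x_beta, temperature)
    q = np.asarray(q, dtype=float)
    if np.any((q < 0) | (q >= 1)):
        raise ValueError("quantiles must lie in [0, 1)")
    kt = kbt(temperature)
    c = np.asarray(r, float) * x_beta / (koff * kt)
    return (kt / x_beta) * np.log1p(-c * np.log1p(-q))


def bell_evans_lifetime(F, tau0: float, x_beta: float,
                        temperature: float = 298.0):
    """Bell lifetime law tau(F) = tau0 * exp(-x_beta*F/kBT); seconds."""
    if tau0 <= 0:
        raise ValueError("tau0 must be positive")
    if x_beta <= 0 or temperature <= 0:
        raise ValueError("x_beta and temperature must be positive")
    F = np.asarray(F, dtype=float)
    out = tau0 * np.exp(-x_beta * F / kbt(temperature))
    return float(out) if out.ndim == 0 else out


def loading_rate(velocity: float, ke: float) -> float:
    """LR = V * ke (pN/s); velocity in nm/s, ke in pN/nm."""
    if velocity < 0 or ke <= 0:
        raise ValueError("velocity must be >= 0 and ke > 0")
    return velocity * ke


def effective_spring(ks: float, kp: float) -> float:
    """Series composition of apparatus and protein springs: 1/ke = 1/ks + 1/kp."""
    if ks <= 0 or kp <= 0:
        raise ValueError("spring constants must be positive")
    return 1.0 / (1.0 / ks + 1.0 / kp)


@dataclass(frozen=True)
class BellEvansFit:
    """Maximum-likelihood single-barrier fit of a loading-rate-dependence cloud."""

    koff: float  # 1/s
    x_beta: float  # nm
    temperature: float
    log_likelihood: float
    se_koff: float
    se_x_beta: float
    n_events: int

    @property
    def tau0(self) -> float:
        """Zero-force lifetime 1/koff (s)."""
        return 1.0 / self.koff


def _fd_hessian(fun, x, rel_step=1e-4):
    """Central finite-difference Hessian of a scalar function."""
    x = np.asarray(x, dtype=float)
    n = x.size
    h = rel_step * np.maximum(np.abs(x), 1.0)
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            fpp = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmm = fun(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


def fit_bell_evans(events: Sequence[RuptureEvent],
                   temperature: float = 298.0) -> BellEvansFit:
    """Fit (koff, x_beta) by maximum likelihood over per-event loading rates.

    Each event contributes log p(F_i | r_i) with its own r_i = keff_i * v_i.
    Optimization runs in log-parameter space (simplex start, quasi-Newton
    polish); standard errors come from the observed information matrix.
    """
    if len(events) < 3:
        raise ValueError("need at least 3 events")
    F = np.array([e.force for e in events], dtype=float)
    r = np.array([e.loading_rate for e in events], dtype=float)
    if np.unique(r).size < 2:
        raise ValueError("need at least 2 distinct loading rates to identify "
                         "(koff, x_beta)")
    if np.ptp(F) <= 0:
        raise ValueError("degenerate data: all rupture forces identical")
    kt = kbt(temperature)

    def nll(theta):
        lkoff, lxb = theta
        if not (np.isfinite(lkoff) and np.isfinite(lxb)):
            return np.inf
        koff, xb = np.exp(lkoff), np.exp(lxb)
        u = np.clip(xb * F / kt, -_EXP_CLIP, _EXP_CLIP)
        ll = np.log(koff) - np.log(r) + u - (koff * kt / (r * xb)) * np.expm1(u)
        return -np.sum(ll)

    # Bell-line moment start: mean F approx (kBT/xb)*ln(xb*r/(koff*kBT))
    slope = np.polyfit(np.log(r), F, 1)[0]
    xb0 = kt / slope if slope > 0 else 0.3
    xb0 = float(np.clip(xb0, 1e-3, 10.0))
    mean_F, mean_lr = F.mean(), np.exp(np.mean(np.log(r)))
    koff0 = mean_lr * xb0 / kt * np.exp(-xb0 * mean_F / kt)
    koff0 = float(np.clip(koff0, 1e-12, 1e6))

    x0 = np.log([koff0, xb0])
    res = minimize(nll, x0, method="Nelder-Mead",
                   options={"xatol": 1e-9, "fatol": 1e-9, "maxiter": 2000})
    res2 = minimize(nll, res.x, method="BFGS",
                    options={"gtol": 1e-8, "maxiter": 500})
    best = res2 if res2.fun <= res.fun else res
    if not np.isfinite(best.fun):
        raise RuntimeError(f"Bell-Evans fit did not converge: {best}")

    koff, xb = np.exp(best.x)
    H = _fd_hessian(nll, best.x)
    try:
        cov = np.linalg.inv(H)
        se_log = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
    except np.linalg.LinAlgError:  # pragma: no cover
        se_log = np.full(2, np.nan)
    return BellEvansFit(
        koff=float(koff), x_beta=float(xb), temperature=temperature,
        log_likelihood=float(-best.fun),
        se_koff=float(koff * se_log[0]), se_x_beta=float(xb * se_log[1]),
        n_events=len(events),
    )
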