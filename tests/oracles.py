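"""Independent numerical oracles used by the test suite.

These deliberately avoid the implementation's code paths: rejection
sampling instead of inverse-CDF sampling, double numeric quadrature of
the mean-first-passage-time integral instead of the erf-reduced universal
integral, and plain finite differences for gradients.
"""

from __future__ import annotations

import numpy as np

from vwforce.constants import kbt


def rejection_sample_evans_ritchie(n, r, koff, x_beta, temperature, rng,
                                   f_max=500.0):
    """Rejection sampler for the Evans–Ritchie rupture-force density."""
    from vwforce.evans_ritchie import evans_ritchie_pdf
    grid = np.linspace(0, f_max, 4001)
    box = 1.05 * evans_ritchie_pdf(grid, r, koff, x_beta, temperature).max()
    out = []
    while len(out) < n:
        f = rng.uniform(0, f_max, 4 * n)
        u = rng.uniform(0, box, 4 * n)
        acc = f[u < evans_ritchie_pdf(f, r, koff, x_beta, temperature)]
        out.extend(acc.tolist())
    return np.array(out[:n])


def cusp_mfpt_rate(F, E_kt, x_b, D, temperature=298.0,
                   n_y=1500, n_z=3000):
    """Escape rate over the force-tilted cusp by double numeric quadrature.

    tau(F) = (1/D) int_{x_min}^{x_b} dy e^{U(y)} int_{-inf}^{y} dz e^{-U(z)}
    with U(x) = E*(x/x_b)^2 - F x / kBT (in kBT units), starting from the
    tilted well minimum, absorbing at the cusp x_b.
    """
    kt = kbt(temperature)
    alpha = E_kt / x_b**2
    c = F / kt / (2 * alpha)  # tilted well minimum

    def beta_u(x):
        return alpha * x**2 - (F / kt) * x

    z_lo = c - 8.0 / np.sqrt(alpha)
    z = np.linspace(z_lo, x_b, n_z)
    ez = np.exp(-(beta_u(z) - beta_u(c)))
    Iz = np.concatenate([[0.0], np.cumsum(0.5 * (ez[1:] + ez[:-1])
                                          * np.diff(z))])
    y = np.linspace(c, x_b, n_y)
    ey = np.exp(beta_u(y) - beta_u(c))
    inner = np.interp(y, z, Iz)
    tau = np.trapezoid(ey * inner, y) / D
    return 1.0 / tau


def cusp_mfpt_pdf(F_grid, loading_rate, E_kt, x_b, D, temperature=298.0):
    """Rupture-force density from the MFPT rate by direct survival quadrature."""
    k = np.array([cusp_mfpt_rate(F, E_kt, x_b, D, temperature)
                  for F in F_grid])
    lam = np.concatenate([[0.0], np.cumsum(0.5 * (k[1:] + k[:-1])
                                           * np.diff(F_grid))])
    S = np.exp(-lam / loading_rate)
    return k * S / loading_rate


def numeric_gradient(fun, x, h=1e-5):
    """Central finite-difference gradient of a scalar function."""
    x = np.asarray(x, dtype=float)
    g = np.zeros_like(x)
    for i in range(x.size):
        e = np.zeros_like(x)
        e[i] = h
        g[i] = (fun(x + e) - fun(x - e)) / (2 * h)
    return g
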