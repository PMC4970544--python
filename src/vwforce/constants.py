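"""Physical constants and unit helpers.

All public APIs in this package use AFM-friendly units: forces in pN,
lengths in nm, times in s, temperatures in K, energies in units of kBT.
"""

from __future__ import annotations

import math

#: Boltzmann constant in pN nm / K (1.38e-23 J/K), so kBT(298 K) = 4.1124 pN nm.
KB = 0.0138

#: Dynamic viscosity of water at room temperature, Pa s.
WATER_VISCOSITY = 0.89e-3


def kbt(temperature: float = 298.0) -> float:
    """Thermal energy kB*T in pN nm."""
    if temperature <= 0:
        raise ValueError("temperature must be positive (K)")
    return KB * temperature


def stokes_mobility(a_nm: float, viscosity: float = WATER_VISCOSITY) -> float:
    """Stokes mobility mu0 = 1/(6 pi eta a) of a sphere, in nm/(pN s).

    Parameters
    ----------
    a_nm : bead radius in nm.
    viscosity : solvent viscosity in Pa s.
    """
    if a_nm <= 0 or viscosity <= 0:
        raise ValueError("radius and viscosity must be positive")
    # 1/(Pa s * nm) = 1e6 nm/(pN s)
    return 1e6 / (6.0 * math.pi * viscosity * a_nm)
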