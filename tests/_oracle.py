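"""Independent high-precision oracle for the elliptical conduit law.

Evaluates the effective fourth-power radius in exact rational arithmetic
(``fractions.Fraction``) and multiplies by the float prefactor only at
the end — a separate code path from the package's float implementation.
"""

import math
from fractions import Fraction

RHO = Fraction("998.205")          # kg m^-3
ETA = Fraction("1.002e-9")         # MPa s
_MICRON = Fraction(1, 10**6)


def oracle_conductivity(d_max_um, d_min_um) -> float:
    """k_t for an elliptical lumen, diameters given in µm (exact rationals)."""
    dmax = Fraction(str(d_max_um)) * _MICRON
    dmin = Fraction(str(d_min_um)) * _MICRON
    r4 = dmax**3 * dmin**3 / (8 * (dmax**2 + dmin**2))
    return math.pi * float(RHO / (8 * ETA) * r4)


def oracle_circular(d_um) -> float:
    """Circular Hagen-Poiseuille: (pi rho / 8 eta) * (d/2)^4."""
    d = Fraction(str(d_um)) * _MICRON
    return math.pi * float(RHO / (8 * ETA) * (d / 2) ** 4)
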