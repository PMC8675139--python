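"""Physical constants and unit conversions.

Internal units throughout the package are Angstrom (length), eV (energy),
eV/A (force), amu (mass) and fs (time).  Values are CODATA 2018.
"""

from __future__ import annotations

# CODATA 2018
EV = 1.602176634e-19          # J
AMU = 1.66053906660e-27       # kg
HBAR = 1.054571817e-34        # J s
C_CM_PER_S = 2.99792458e10    # speed of light, cm/s
KB_EV = 8.617333262e-5        # Boltzmann constant, eV/K

# acceleration unit: (eV/A)/amu expressed in A/fs^2
#   1 eV/(A amu) = EV / (1e-10 m * AMU) [m/s^2] = ... * 1e-20 [A/fs^2]
ACC_EV_PER_A_AMU_TO_A_FS2 = EV / (1e-10 * AMU) * 1e-20

# sqrt(eV / (A^2 amu)) -> angular frequency in rad/s
_OMEGA_SI = (EV / (1e-20 * AMU)) ** 0.5
# harmonic frequency conversion: wavenumber[cm^-1] = SQRT_EV_A2_AMU_TO_INVCM * sqrt(lambda)
# with lambda an eigenvalue of the mass-weighted Hessian in eV/(A^2 amu)
SQRT_EV_A2_AMU_TO_INVCM = _OMEGA_SI / (2.0 * 3.141592653589793 * C_CM_PER_S)

# standard atomic weights (amu), most common isotopic mixture
ATOMIC_MASSES = {
    "H": 1.008,
    "He": 4.002602,
    "Li": 6.94,
    "B": 10.81,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998403163,
    "Ne": 20.1797,
    "Na": 22.98976928,
    "Mg": 24.305,
    "Si": 28.085,
    "P": 30.973761998,
    "S": 32.06,
    "Cl": 35.45,
    "Ar": 39.948,
    "K": 39.0983,
    "Ca": 40.078,
    "Br": 79.904,
    "I": 126.90447,
}


def atomic_mass(symbol: str) -> float:
    try:
        return ATOMIC_MASSES[symbol]
    except KeyError:
        raise KeyError(f"no tabulated mass for element {symbol!r}") from None
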