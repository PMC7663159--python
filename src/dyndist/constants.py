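"""Physical constants and the repository-wide unit system.

Units used throughout: lengths in Å, time in fs, masses in amu,
energies in kJ/mol, temperatures in K.  In this system a velocity is
Å/fs and the "internal" kinetic-energy unit amu·Å²/fs² equals
1.0e4 kJ/mol to within 4e-10 relative, which we adopt exactly.
"""

from __future__ import annotations

#: Boltzmann constant, kJ/mol/K.
KB = 0.0083144621

#: kJ/mol per amu·Å²/fs² (internal kinetic-energy unit).
EUNIT = 1.0e4

#: Acceleration conversion: (kJ/mol/Å) / amu -> Å/fs².
FCONV = 1.0 / EUNIT

#: Coulomb prefactor, kJ·Å/mol/e².
KE_COULOMB = 1389.35458

#: Standard atomic weights (amu) for every element the toy models use.
ATOMIC_MASS = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.973761998,
    "NA": 22.98976928,
    "CL": 35.45,
    "HG": 200.592,
}


def mass_of(element: str) -> float:
    """Standard atomic weight of ``element`` (case-insensitive symbol)."""
    try:
        return ATOMIC_MASS[element.upper()]
    except KeyError:
        raise KeyError(f"no standard atomic weight tabulated for element {element!r}")


def reduced_mass(m1: float, m2: float) -> float:
    """Reduced mass m1·m2/(m1+m2) of a two-body pair, amu."""
    return m1 * m2 / (m1 + m2)
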