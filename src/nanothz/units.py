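"""Unit system and physical constants.

File formats and public APIs use MD-native units (Å, ps, amu, e); the
dielectric chain converts to SI internally so that the prefactor of the
imaginary-permittivity formula is unambiguous.  Constants are CODATA 2018.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Boltzmann constant, J/K (exact, SI 2019).
K_B = 1.380649e-23
#: Vacuum permittivity, F/m.
EPS0 = 8.8541878128e-12
#: Speed of light in vacuum, m/s (exact).
C_LIGHT = 299792458.0
#: Elementary charge, C (exact).
E_CHARGE = 1.602176634e-19
#: One e·Å expressed in C·m.
E_ANGSTROM_TO_CM = E_CHARGE * 1e-10
#: Atomic mass unit, kg.
AMU_TO_KG = 1.66053906660e-27
#: One debye in C·m.
DEBYE_TO_CM = 1e-21 / C_LIGHT
#: One e·Å in debye (≈ 4.8032).
E_ANGSTROM_TO_DEBYE = E_ANGSTROM_TO_CM / DEBYE_TO_CM

#: Scale factors to SI.
ANGSTROM = 1e-10   # m
PS = 1e-12         # s
THZ = 1e12         # Hz
ANGSTROM_PER_PS = ANGSTROM / PS  # m/s per Å/ps (= 100 m/s)


@dataclass(frozen=True)
class UnitContext:
    """Bundle of the physical constants entering the dielectric equations.

    Frozen so a context threaded through a computation cannot drift; the
    defaults are the CODATA values above and there is rarely a reason to
    override them outside of unit tests.
    """

    k_B: float = K_B
    eps0: float = EPS0
    c: float = C_LIGHT
    e_angstrom_to_Cm: float = E_ANGSTROM_TO_CM
    amu_to_kg: float = AMU_TO_KG

    def dipole_to_si(self, m_e_angstrom):
        """Convert a dipole moment (or array thereof) from e·Å to C·m."""
        return m_e_angstrom * self.e_angstrom_to_Cm

    def dipole_from_si(self, m_Cm):
        """Inverse of :meth:`dipole_to_si`."""
        return m_Cm / self.e_angstrom_to_Cm


DEFAULT_UNITS = UnitContext()
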