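"""Reduced-unit system and continuum-electrostatics helpers.

The simulation works in reduced units: the unit of length is the effective
ion diameter sigma (0.355 nm by default), the unit of energy is the thermal
energy k_B*T (so beta = 1), and the particle mass is 1.  Concentrations are
referred to the standard concentration c_std = 1 mol/L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

# CODATA constants (SI)
ELEMENTARY_CHARGE = 1.602176634e-19  # C
VACUUM_PERMITTIVITY = 8.8541878128e-12  # F/m
BOLTZMANN = 1.380649e-23  # J/K
AVOGADRO = 6.02214076e23  # 1/mol

#: number density (nm^-3) of a 1 mol/L solution
_DENSITY_PER_MOLAR_NM3 = AVOGADRO / 1.0e24


@dataclass(frozen=True)
class UnitSystem:
    """Conversion between reduced simulation units and SI.

    Parameters
    ----------
    length_unit_nm : float
        Nanometres per reduced length unit (default: ion diameter 0.355 nm).
    temperature_K : float
        Absolute temperature used for every SI energy conversion.
    reference_concentration_M : float
        The standard concentration c_std in mol/L to which equilibrium
        constants are referred.
    """

    length_unit_nm: float = 0.355
    temperature_K: float = 298.15
    reference_concentration_M: float = 1.0

    def __post_init__(self) -> None:
        if self.length_unit_nm <= 0:
            raise ValueError("length unit must be positive")
        if self.temperature_K <= 0:
            raise ValueError("temperature must be positive")

    # --- lengths -----------------------------------------------------
    def to_reduced_length(self, nm: float) -> float:
        return nm / self.length_unit_nm

    def to_nm(self, reduced: float) -> float:
        return reduced * self.length_unit_nm

    # --- energies ----------------------------------------------------
    @property
    def kT_joule(self) -> float:
        return BOLTZMANN * self.temperature_K

    def energy_per_nm2_to_reduced(self, value_kT_per_nm2: float) -> float:
        """Convert a spring constant given in kT/nm^2 to kT per reduced length^2."""
        return value_kT_per_nm2 * self.length_unit_nm**2

    # --- concentrations ----------------------------------------------
    def molar_to_reduced_density(self, molar: float) -> float:
        """mol/L -> number per reduced volume (sigma^3)."""
        return molar * _DENSITY_PER_MOLAR_NM3 * self.length_unit_nm**3

    def reduced_density_to_molar(self, rho: float) -> float:
        return rho / (_DENSITY_PER_MOLAR_NM3 * self.length_unit_nm**3)

    @property
    def reference_density_reduced(self) -> float:
        """c_std expressed as a reduced number density."""
        return self.molar_to_reduced_density(self.reference_concentration_M)


DEFAULT_UNITS = UnitSystem()


def bjerrum_from_permittivity(eps_r: float, temperature_K: float = 298.15) -> float:
    """Bjerrum length l_B = e^2 / (4 pi eps0 eps_r kB T), returned in nm.

    At this distance two unit charges interact with exactly k_B*T.  With
    eps_r ~ 78 (water at room temperature) this gives ~0.71 nm; the denser,
    lower-permittivity complex phase (eps_r ~ 62) gives ~0.9 nm.
    """
    if eps_r <= 0 or temperature_K <= 0:
        raise ValueError("permittivity and temperature must be positive")
    lb_m = ELEMENTARY_CHARGE**2 / (
        4.0 * math.pi * VACUUM_PERMITTIVITY * eps_r * BOLTZMANN * temperature_K
    )
    return lb_m * 1.0e9


def permittivity_from_bjerrum(lb_nm: float, temperature_K: float = 298.15) -> float:
    """Inverse of :func:`bjerrum_from_permittivity`."""
    if lb_nm <= 0 or temperature_K <= 0:
        raise ValueError("Bjerrum length and temperature must be positive")
    lb_m = lb_nm * 1.0e-9
    return ELEMENTARY_CHARGE**2 / (
        4.0 * math.pi * VACUUM_PERMITTIVITY * lb_m * BOLTZMANN * temperature_K
    )


def born_transfer_factor(z: int, r0_nm: float, lb_pec_nm: float, lb_sup_nm: float) -> float:
    """Born-equation estimate of the solvation bias on a partition coefficient.

    Transferring an ion of valency ``z`` and radius ``r0`` from the
    supernatant (Bjerrum length ``lb_sup``) into the complex phase
    (``lb_pec``) changes its chemical potential by
    beta*mu_S = z^2 (lb_pec - lb_sup) / (2 r0).  The returned value is
    exp(beta*mu_S), the multiplicative factor by which neglecting solvation
    could bias a per-ion partition coefficient.
    """
    if r0_nm <= 0:
        raise ValueError("ion radius must be positive")
    beta_mu = z**2 * (lb_pec_nm - lb_sup_nm) / (2.0 * r0_nm)
    return math.exp(beta_mu)
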