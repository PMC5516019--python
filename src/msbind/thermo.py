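"""Thermodynamic context and unit conventions.

All energies are in kcal/mol, lengths in Å, and reservoir concentrations in
mM externally / Å⁻³ internally.  The converters below are the only places
where units cross, so every other module can stay unit-agnostic.

The standard state is the conventional 1 M reference, taken as a number
density of one molecule per 1660 Å³.  The millimolar↔Å⁻³ conversion factor
is derived from that same volume so that concentration round-trips and the
standard free energy are exactly independent of the internal unit choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "BOLTZMANN_KCAL_MOL_K",
    "STANDARD_VOLUME_A3",
    "MM_TO_INV_A3",
    "ThermoContext",
    "LigandReservoir",
    "make_context",
    "concentration_to_density",
    "density_to_concentration",
]

#: Boltzmann constant in kcal/mol/K.
BOLTZMANN_KCAL_MOL_K = 1.987204e-3

#: Volume per molecule at the 1 M standard concentration, Å³.
STANDARD_VOLUME_A3 = 1660.0

#: Number density (Å⁻³) of a 1 mM solution; 1/(1660 Å³ × 1000) ≈ 6.02e−7.
MM_TO_INV_A3 = 1.0 / (STANDARD_VOLUME_A3 * 1e3)

#: Default absolute temperature (K) when none is configured.
DEFAULT_TEMPERATURE_K = 298.15


@dataclass(frozen=True)
class ThermoContext:
    """Temperature-dependent constants shared by all calculations.

    Attributes
    ----------
    temperature : float
        Absolute temperature in K.
    beta : float
        Inverse thermal energy 1/(k_B·T) in mol/kcal.
    standard_concentration : float
        The 1 M reference concentration expressed as a number density, Å⁻³.
    """

    temperature: float
    beta: float = field(init=False)
    standard_concentration: float = field(
        init=False, default=1.0 / STANDARD_VOLUME_A3
    )

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError(
                f"temperature must be positive, got {self.temperature!r} K"
            )
        object.__setattr__(
            self, "beta", 1.0 / (BOLTZMANN_KCAL_MOL_K * self.temperature)
        )

    @property
    def kT(self) -> float:
        """Thermal energy k_B·T in kcal/mol."""
        return 1.0 / self.beta


@dataclass(frozen=True)
class LigandReservoir:
    """Homogeneous dilute ligand reservoir.

    The membrane-aqueous region is treated as one homogeneous phase holding
    the free ligands at constant density.  ``excess_chemical_potential`` is
    the ligand's solvation free energy μ̄ (kcal/mol) — the reversible work of
    inserting one ligand anywhere in the reservoir.
    """

    excess_chemical_potential: float
    concentration: float  # mM

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError(
                f"concentration must be >= 0 mM, got {self.concentration!r}"
            )

    @property
    def number_density(self) -> float:
        """Reservoir density ρ̄ in Å⁻³."""
        return concentration_to_density(self.concentration)

    def at_concentration(self, c_mM: float) -> "LigandReservoir":
        """Same reservoir chemistry at a different concentration."""
        return LigandReservoir(self.excess_chemical_potential, c_mM)


def make_context(temperature: float = DEFAULT_TEMPERATURE_K) -> ThermoContext:
    """Build a :class:`ThermoContext` for the given temperature (K)."""
    return ThermoContext(temperature=float(temperature))


def concentration_to_density(c_mM: float) -> float:
    """Convert a molar concentration (mM) to number density (Å⁻³)."""
    if c_mM < 0:
        raise ValueError(f"concentration must be >= 0 mM, got {c_mM!r}")
    return c_mM * MM_TO_INV_A3


def density_to_concentration(rho_inv_A3: float) -> float:
    """Convert a number density (Å⁻³) back to molar concentration (mM)."""
    if rho_inv_A3 < 0:
        raise ValueError(f"density must be >= 0, got {rho_inv_A3!r}")
    return rho_inv_A3 / MM_TO_INV_A3
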