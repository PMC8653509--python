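"""Physical constants and unit helpers shared across the package.

All internal computation is in SI (Pa, m, s, kg, mol/m^3); unit conversion
happens only at I/O boundaries.  Osmolality is expressed in mOsm/kg H2O with
the dilute-solution identification mol/m^3 == mmol/L == mOsm/kg H2O.
"""
from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

from .errors import InvalidInputError

#: Viscosity of 0.15 mol/L NaCl at 298.15 K, Pa s.  Only used when a caller
#: supplies intrinsic permeabilities (m^2) and asks for hydraulic form.
DEFAULT_VISCOSITY = 8.9e-4


@dataclass(frozen=True)
class PhysicalConstants:
    """Thermodynamic constants for the bath/tissue system.

    Parameters
    ----------
    gas_constant : float
        Universal gas constant R, J/(mol K).
    temperature : float
        Absolute temperature, K (room temperature by default).
    osmotic_coefficient : float
        Osmotic coefficient phi of NaCl, applied to both the bath and the
        intra-tissue ion concentrations.
    bath_concentration : float
        NaCl concentration of the equilibration bath and probe fill, mol/L.
    tissue_density : float
        Tissue density used to convert wet mass to volume, kg/m^3.
    """

    gas_constant: float = 8.314
    temperature: float = 298.15
    osmotic_coefficient: float = 0.93
    bath_concentration: float = 0.15
    tissue_density: float = 1000.0
    viscosity: float = DEFAULT_VISCOSITY

    def __post_init__(self) -> None:
        if min(self.gas_constant, self.temperature, self.bath_concentration,
               self.tissue_density, self.viscosity) <= 0:
            raise InvalidInputError("physical constants must be positive")
        if not 0 < self.osmotic_coefficient <= 1:
            raise InvalidInputError(
                f"osmotic coefficient must lie in (0, 1], got "
                f"{self.osmotic_coefficient}")

    @property
    def rt(self) -> float:
        """R*T, J/mol (equivalently Pa per mol/m^3)."""
        return self.gas_constant * self.temperature

    @property
    def bath_osmolarity(self) -> float:
        """Total osmotically active ion concentration of the bath,
        mol/m^3 (== mOsm/kg H2O): 2 * phi * c_ext."""
        return 2.0 * self.osmotic_coefficient * self.bath_concentration * 1000.0

    @property
    def bath_osmotic_pressure(self) -> float:
        """Osmotic pressure of the bath / probe fill, Pa."""
        return self.bath_osmolarity * self.rt


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (the convention of printed tables),
    avoiding the banker's rounding of builtin :func:`round`."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
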