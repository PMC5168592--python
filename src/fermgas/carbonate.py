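"""Dissolved CO2 speciation at culture temperature.

The carbonate system in the liquid phase of a sparged bioreactor is described
by a Henry-type solubility relation and the two dissociation equilibria of
carbonic acid,

    [CO2]aq           = K0 * pCO2
    [HCO3-] * [H+]    = K1 * [CO2]aq
    [CO3 2-] * [H+]   = K2 * [HCO3-]
    [H+]              = 10**(-pH)

so that, given the headspace CO2 partial pressure and the (regulated) culture
pH, the total dissolved inorganic carbon follows in closed form.  The default
constants are for a hot (80 degC) saline culture medium; they can be
overridden for other temperatures, but no interpolation in temperature is
attempted.  Activity corrections for the 20 g/L NaCl medium are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import InvalidConfigError, InvalidInputError

__all__ = ["CarbonateConstants", "CarbonateSpeciation", "speciate"]


@dataclass(frozen=True)
class CarbonateConstants:
    """Equilibrium constants of the carbonate system at a fixed temperature.

    Attributes
    ----------
    K0 : float
        Henry-type solubility coefficient, mol L-1 bar-1.
    K1 : float
        First dissociation constant of carbonic acid, mol L-1.
    K2 : float
        Second dissociation constant, mol L-1.
    T : float
        Temperature the constants refer to, degC (informational).
    """

    K0: float = 0.0127
    K1: float = 4.93e-7
    K2: float = 8.18e-11
    T: float = 80.0

    def __post_init__(self) -> None:
        for name in ("K0", "K1", "K2"):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be > 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class CarbonateSpeciation:
    """Concentrations of the three dissolved carbonate species, mol L-1."""

    co2_aq: float
    hco3: float
    co3: float

    @property
    def total(self) -> float:
        """Total dissolved inorganic carbon, mol L-1."""
        return self.co2_aq + self.hco3 + self.co3


def speciate(
    pco2: float, ph: float, constants: CarbonateConstants | None = None
) -> CarbonateSpeciation:
    """Speciate dissolved CO2 from headspace partial pressure and pH.

    Parameters
    ----------
    pco2 : float
        CO2 partial pressure in the headspace, bar. Must be >= 0.
    ph : float
        Culture pH, in (0, 14).
    constants : CarbonateConstants, optional
        Equilibrium constants; defaults are for 80 degC.

    Returns
    -------
    CarbonateSpeciation
        [CO2]aq, [HCO3-] and [CO3 2-] in mol L-1.
    """
    if constants is None:
        constants = CarbonateConstants()
    if pco2 < 0:
        raise InvalidInputError(f"pCO2 must be >= 0 bar, got {pco2}")
    if not 0 < ph < 14:
        raise InvalidInputError(f"pH must be in (0, 14), got {ph}")
    h = 10.0 ** (-ph)
    co2_aq = constants.K0 * pco2
    hco3 = constants.K1 * co2_aq / h
    co3 = constants.K2 * hco3 / h
    return CarbonateSpeciation(co2_aq=co2_aq, hco3=hco3, co3=co3)
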