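"""Shared chemical vocabulary and free-energy conversions.

Intracellular metal availability is expressed as the free energy of forming
a metal complex that would be half-saturated at the buffered available metal
concentration,

    dG = R * T * ln[M]      (kJ mol^-1, [M] in molar)

The identical relationship converts a molecule's metal dissociation constant
K_D into the free energy of forming its half-saturated complex
(dG = RT ln K_D = -RT ln K_A).  Natural logarithms and kJ mol^-1 are used
throughout the package; temperature defaults to standard conditions even
though cultures are typically grown warmer, because availability ladders are
conventionally tabulated at 298.15 K.  Both constants are overridable via
:class:`ThermoConstants` for sensitivity analysis.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

__all__ = [
    "Metal",
    "ThermoConstants",
    "DEFAULT_CONSTANTS",
    "concentration_to_free_energy",
    "free_energy_to_concentration",
    "kd_to_free_energy",
]


class Metal(enum.Enum):
    """The six exchangeable cytosolic metals the calculators handle.

    Declaration order follows the customary weakest-to-tightest (Irving-
    Williams) presentation: Mn2+ < Fe2+ < Co2+ < Ni2+, with Zn2+ and
    monovalent Cu+ appended.  Copper is modelled exclusively as Cu+ since
    the cytosol is reducing.
    """

    MN = "Mn2+"
    FE = "Fe2+"
    CO = "Co2+"
    NI = "Ni2+"
    ZN = "Zn2+"
    CU = "Cu1+"

    @property
    def label(self) -> str:
        """Unicode display label, e.g. ``Mn²⁺``."""
        sup = {"1": "¹", "2": "²", "+": "⁺"}
        sym = self.value
        return sym[:2] + "".join(sup[c] for c in sym[2:])

    @classmethod
    def parse(cls, text: str) -> "Metal":
        """Parse ``Mn2+``-style symbols (case-insensitive, ``Cu+`` accepted)."""
        norm = text.strip()
        aliases = {"cu+": "Cu1+", "cu1+": "Cu1+"}
        norm = aliases.get(norm.lower(), norm)
        for m in cls:
            if m.value.lower() == norm.lower():
                return m
        raise ValueError(
            f"unknown metal {text!r}; expected one of "
            f"{', '.join(m.value for m in cls)}"
        )


@dataclass(frozen=True)
class ThermoConstants:
    """Gas constant (kJ K^-1 mol^-1) and absolute temperature (K)."""

    R: float = 8.314e-3
    T: float = 298.15

    def __post_init__(self) -> None:
        if not (self.R > 0 and math.isfinite(self.R)):
            raise ValueError(f"gas constant must be positive, got {self.R}")
        if not (self.T > 0 and math.isfinite(self.T)):
            raise ValueError(f"temperature must be positive, got {self.T}")

    @property
    def RT(self) -> float:
        """Thermal energy R*T in kJ mol^-1 (~2.479 at 298.15 K)."""
        return self.R * self.T


DEFAULT_CONSTANTS = ThermoConstants()


def concentration_to_free_energy(
    c: float, constants: ThermoConstants = DEFAULT_CONSTANTS
) -> float:
    """Free energy (kJ mol^-1) of forming a complex half-saturated at ``c``.

    ``dG = RT ln(c)``.  Negative whenever ``c`` < 1 M.  Also applicable to a
    dissociation constant in place of ``c`` (see :func:`kd_to_free_energy`).

    Raises
    ------
    ValueError
        If ``c`` is not a positive finite concentration.
    """
    if not (isinstance(c, (int, float)) and math.isfinite(c) and c > 0):
        raise ValueError(f"concentration must be positive and finite, got {c!r}")
    return constants.RT * math.log(c)


def kd_to_free_energy(
    kd: float, constants: ThermoConstants = DEFAULT_CONSTANTS
) -> float:
    """Free energy of forming the half-saturated metal-protein complex.

    ``dG = RT ln K_D = -RT ln K_A``; identical arithmetic to
    :func:`concentration_to_free_energy`, provided as a named operation
    because affinities are entered as dissociation constants.
    """
    return concentration_to_free_energy(kd, constants)


def free_energy_to_concentration(
    g: float, constants: ThermoConstants = DEFAULT_CONSTANTS
) -> float:
    """Invert ``dG = RT ln[M]``: return ``exp(g / RT)`` in molar.

    Round-trips with :func:`concentration_to_free_energy` to floating
    tolerance.  Overflow for unphysically large ``g`` is reported rather
    than returned as ``inf``.
    """
    if not (isinstance(g, (int, float)) and math.isfinite(g)):
        raise ValueError(f"free energy must be finite, got {g!r}")
    try:
        c = math.exp(g / constants.RT)
    except OverflowError as exc:
        raise OverflowError(
            f"free energy {g} kJ/mol overflows the concentration scale"
        ) from exc
    if math.isinf(c):
        raise OverflowError(
            f"free energy {g} kJ/mol overflows the concentration scale"
        )
    return c
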