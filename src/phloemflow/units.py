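"""Internal unit system and boundary conversions.

Everything downstream of this module is evaluated in a single consistent
system chosen so that the microscopic flow formulas need no hidden factors:

=============  ==========================
quantity       internal unit
=============  ==========================
length         nanometre (nm)
pressure       megapascal (MPa)
time           second (s)
viscosity      MPa s
volume flow    nm^3 s^-1
amount         mole (reported in nmol)
concentration  mol nm^-3
=============  ==========================

Laboratory-facing interfaces accept the units in which phloem physiology is
reported (uL day^-1 organ import rates, millimolar sucrose, Pa s viscosity)
and convert here, at the boundary.  All conversion factors are exact decimal
constants, so conversions are linear and invertible to round-off.
"""

from __future__ import annotations

import math

from .errors import InvalidQuantityError

#: seconds per day (exact)
SECONDS_PER_DAY = 86_400.0
#: nm^3 per microlitre: 1 uL = 1 mm^3 = (1e6 nm)^3 = 1e18 nm^3 (exact)
NM3_PER_MICROLITRE = 1.0e18
#: nm^3 per litre (exact)
NM3_PER_LITRE = 1.0e24
#: MPa per Pa (exact)
MPA_PER_PA = 1.0e-6
#: mol L^-1 per millimolar (exact)
MOLAR_PER_MILLIMOLAR = 1.0e-3
#: nmol per mol (exact)
NMOL_PER_MOL = 1.0e9


def _require_finite(value: float, name: str) -> float:
    if not math.isfinite(value):
        raise InvalidQuantityError(f"{name} must be finite, got {value!r}")
    return float(value)


def volume_flow_to_internal(value_ul_per_day: float) -> float:
    """Convert a volume flow from uL day^-1 to nm^3 s^-1.

    The wheat-grain import rate of 10 uL day^-1 converts to
    1.157e14 nm^3 s^-1 (commonly quoted rounded as 11.6e13).

    Parameters
    ----------
    value_ul_per_day
        Non-negative volume flow in microlitres per day.
    """
    v = _require_finite(value_ul_per_day, "volume flow")
    if v < 0:
        raise InvalidQuantityError(f"volume flow must be >= 0, got {v}")
    return v * NM3_PER_MICROLITRE / SECONDS_PER_DAY


def volume_flow_to_lab(value_nm3_per_s: float) -> float:
    """Inverse of :func:`volume_flow_to_internal` (nm^3 s^-1 -> uL day^-1)."""
    v = _require_finite(value_nm3_per_s, "volume flow")
    return v * SECONDS_PER_DAY / NM3_PER_MICROLITRE


def concentration_to_internal(value_mm: float) -> float:
    """Convert a solute concentration from millimolar to mol nm^-3.

    200 mM sucrose (vascular parenchyma of a developing wheat grain)
    becomes 2e-25 mol nm^-3.
    """
    v = _require_finite(value_mm, "concentration")
    if v < 0:
        raise InvalidQuantityError(f"concentration must be >= 0, got {v}")
    return v * MOLAR_PER_MILLIMOLAR / NM3_PER_LITRE


def concentration_to_lab(value_mol_nm3: float) -> float:
    """Inverse of :func:`concentration_to_internal` (mol nm^-3 -> mM)."""
    v = _require_finite(value_mol_nm3, "concentration")
    return v * NM3_PER_LITRE / MOLAR_PER_MILLIMOLAR


def viscosity_to_internal(value_pa_s: float) -> float:
    """Convert a dynamic viscosity from Pa s to MPa s.

    Phloem sap at 2e-3 Pa s becomes 2e-9 MPa s.
    """
    v = _require_finite(value_pa_s, "viscosity")
    if v <= 0:
        raise InvalidQuantityError(f"viscosity must be > 0, got {v}")
    return v * MPA_PER_PA


def viscosity_to_lab(value_mpa_s: float) -> float:
    """Inverse of :func:`viscosity_to_internal` (MPa s -> Pa s)."""
    v = _require_finite(value_mpa_s, "viscosity")
    if v <= 0:
        raise InvalidQuantityError(f"viscosity must be > 0, got {v}")
    return v / MPA_PER_PA


def amount_rate_to_nmol(value_mol_per_s: float) -> float:
    """Convert an amount flux from mol s^-1 to nmol s^-1 (reporting unit)."""
    return _require_finite(value_mol_per_s, "amount rate") * NMOL_PER_MOL
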