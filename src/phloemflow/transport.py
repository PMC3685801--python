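"""Governing transport laws for cylindrical channels.

Three microscopic laws drive every calculation in this package:

* Hagen-Poiseuille volume flow through a cylinder,
  ``R_v = pi r^4 dP / (8 eta L)``;
* the corresponding hydraulic conductance ``L_o = pi r^4 / (8 eta L)``,
  so that ``R_v = L_o * dP`` exactly;
* Fick's first law of diffusion, ``R_i = D A dC / dx`` with ``A = pi r^2``
  and the diffusion path ``dx`` equal to the channel length.

On top of these, the advected solute rate carried by a bulk flow is
``R_v * C`` (volume flow times the concentration of the sap it carries),
and the mean axial velocity is ``R_v / (pi r^2)``.

Radii and lengths are in nm, pressures in MPa, viscosities in MPa s
(see :mod:`phloemflow.units`); concentrations enter in millimolar and are
converted internally.  Driving forces may be negative, in which case flows
and fluxes carry the corresponding sign — the conductance-network module
relies on this symmetry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from . import units
from .errors import InvalidMediumError, InvalidQuantityError

#: Sucrose diffusion coefficient in water at 25 degC, nm^2 s^-1.
SUCROSE_DIFFUSIVITY_NM2_S = 0.52e9

#: Phloem sap viscosity, MPa s (about twice that of water at 25 degC).
PHLOEM_SAP_VISCOSITY_MPA_S = 2.0e-9


@dataclass(frozen=True)
class CylindricalChannel:
    """A cylindrical flow conduit (sieve pore or plasmodesmal microchannel).

    Parameters
    ----------
    radius_nm
        Channel radius ``r`` in nm; must be positive and finite.
    length_nm
        Channel length ``L`` in nm, which also serves as the diffusion
        path length; must be positive and finite.
    """

    radius_nm: float
    length_nm: float

    def __post_init__(self) -> None:
        for name in ("radius_nm", "length_nm"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise InvalidQuantityError(f"{name} must be positive and finite, got {v!r}")

    @property
    def cross_section_nm2(self) -> float:
        """Internal cross-sectional area ``A = pi r^2`` in nm^2."""
        return math.pi * self.radius_nm**2


@dataclass(frozen=True)
class TransportMedium:
    """Fluid properties of the sap plus one tracked solute.

    ``diffusion_coefficient_nm2_s`` may be ``None`` for purely hydraulic
    calculations; evaluating diffusion without it raises
    :class:`~phloemflow.errors.InvalidMediumError`.
    """

    viscosity_mpa_s: float = PHLOEM_SAP_VISCOSITY_MPA_S
    solute: str = "sucrose"
    diffusion_coefficient_nm2_s: float | None = SUCROSE_DIFFUSIVITY_NM2_S

    def __post_init__(self) -> None:
        if not (math.isfinite(self.viscosity_mpa_s) and self.viscosity_mpa_s > 0):
            raise InvalidMediumError(
                f"viscosity must be positive and finite, got {self.viscosity_mpa_s!r}"
            )
        d = self.diffusion_coefficient_nm2_s
        if d is not None and not (math.isfinite(d) and d > 0):
            raise InvalidMediumError(f"diffusion coefficient must be positive, got {d!r}")


@dataclass(frozen=True)
class DrivingForces:
    """Driving terms for one channel: dP (MPa), dC and carried C (mM)."""

    pressure_differential_mpa: float = 0.0
    concentration_difference_mm: float = 0.0
    carried_concentration_mm: float = 0.0


def poiseuille_volume_flow(
    channel: CylindricalChannel,
    dp_mpa: float,
    eta_mpa_s: float = PHLOEM_SAP_VISCOSITY_MPA_S,
    enhancement: float = 1.0,
) -> float:
    """Volume flow ``pi r^4 dP / (8 eta L)`` in nm^3 s^-1.

    ``enhancement`` is an optional multiplicative factor (default 1) for
    slip-flow regimes in which nanoconfined water moves faster than the
    no-slip law predicts; it rescales the result and nothing else.
    """
    if not (math.isfinite(eta_mpa_s) and eta_mpa_s > 0):
        raise InvalidMediumError(f"viscosity must be positive, got {eta_mpa_s!r}")
    if not math.isfinite(dp_mpa):
        raise InvalidQuantityError(f"pressure differential must be finite, got {dp_mpa!r}")
    return (
        enhancement
        * math.pi
        * channel.radius_nm**4
        * dp_mpa
        / (8.0 * eta_mpa_s * channel.length_nm)
    )


def hydraulic_conductance(
    channel: CylindricalChannel,
    eta_mpa_s: float = PHLOEM_SAP_VISCOSITY_MPA_S,
) -> float:
    """Hydraulic conductance ``L_o = pi r^4 / (8 eta L)`` in nm^3 s^-1 MPa^-1."""
    if not (math.isfinite(eta_mpa_s) and eta_mpa_s > 0):
        raise InvalidMediumError(f"viscosity must be positive, got {eta_mpa_s!r}")
    return math.pi * channel.radius_nm**4 / (8.0 * eta_mpa_s * channel.length_nm)


def fick_diffusion_rate(
    channel: CylindricalChannel,
    medium: TransportMedium,
    dc_mm: float,
) -> float:
    """Diffusive solute rate ``D A dC / dx`` in nmol s^-1.

    ``dc_mm`` is the end-to-end concentration difference in millimolar;
    a negative value yields a flux of the opposite sign.
    """
    if medium.diffusion_coefficient_nm2_s is None:
        raise InvalidMediumError(f"medium for {medium.solute!r} has no diffusion coefficient")
    if not math.isfinite(dc_mm):
        raise InvalidQuantityError(f"concentration difference must be finite, got {dc_mm!r}")
    sign = -1.0 if dc_mm < 0 else 1.0
    dc_internal = sign * units.concentration_to_internal(abs(dc_mm))
    rate_mol_s = (
        medium.diffusion_coefficient_nm2_s
        * channel.cross_section_nm2
        * dc_internal
        / channel.length_nm
    )
    return units.amount_rate_to_nmol(rate_mol_s)


def advective_solute_rate(volume_flow_nm3_s: float, carried_concentration_mm: float) -> float:
    """Solute rate carried by a bulk flow, ``R_v * C``, in nmol s^-1."""
    if carried_concentration_mm < 0:
        raise InvalidQuantityError(
            f"carried concentration must be >= 0, got {carried_concentration_mm}"
        )
    c_internal = units.concentration_to_internal(carried_concentration_mm)
    return units.amount_rate_to_nmol(volume_flow_nm3_s * c_internal)


def mean_velocity(volume_flow_nm3_s: float, channel: CylindricalChannel) -> float:
    """Mean axial velocity ``R_v / (pi r^2)`` in nm s^-1."""
    return volume_flow_nm3_s / channel.cross_section_nm2
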