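"""Diffusion versus bulk flow through plasmodesmal microchannels.

For a microchannel of radius r and length L the two candidate unloading
mechanisms scale differently with radius:

* diffusion (Fick): ``R_i = D pi r^2 dC / L``  — proportional to r^2;
* bulk flow (Poiseuille, advecting sap at concentration C):
  ``R = (pi r^4 dP / 8 eta L) * C``  — proportional to r^4.

Their ratio ``bulk/diffusion = dP C r^2 / (8 eta D dC)`` grows as r^2, so
diffusion dominates in narrow channels and bulk flow in wide ones, with a
single crossover radius ``r* = sqrt(8 eta D dC / (dP C))``.  For the wheat
grain (dP = 1 MPa, SE sucrose 450-600 mM, parenchyma 200-260 mM) the two
mechanisms are comparable near r = 2 nm and bulk flow dominates for the
4-8 nm radii inferred for phloem symplasmic domains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import pandas as pd
from scipy.optimize import brentq

from .errors import InvalidQuantityError, NoCrossoverError
from .transport import (
    CylindricalChannel,
    TransportMedium,
    advective_solute_rate,
    fick_diffusion_rate,
    poiseuille_volume_flow,
)

DominantMode = Literal["diffusion", "bulk", "comparable"]

#: default channel (= plasmodesma wall) length, nm
DEFAULT_CHANNEL_LENGTH_NM = 500.0

#: default comparability threshold: ratio within [1/2, 2] counts as comparable
DEFAULT_COMPARABLE_THRESHOLD = 2.0

#: default pairing of driving terms for the dominance classification (mM)
DEFAULT_DC_MM = 400.0
DEFAULT_C_MM = 450.0


@dataclass(frozen=True)
class ModeComparisonRow:
    """Diffusion and bulk-flow sucrose rates for one microchannel radius.

    Rates are nmol s^-1 per channel; ``ratio`` is bulk/diffusion at the
    pairing (``dc_mm``, ``c_mm``) used for classification.
    """

    microchannel_radius_nm: float
    diffusion_rates: Mapping[float, float]
    bulk_rates: Mapping[float, float]
    dc_mm: float
    c_mm: float
    ratio: float
    dominant_mode: DominantMode


def classify_ratio(ratio: float, threshold: float = DEFAULT_COMPARABLE_THRESHOLD) -> DominantMode:
    """Classify a bulk/diffusion ratio against a factor-``threshold`` band."""
    if threshold <= 1:
        raise InvalidQuantityError(f"comparability threshold must exceed 1, got {threshold}")
    if ratio > threshold:
        return "bulk"
    if ratio < 1.0 / threshold:
        return "diffusion"
    return "comparable"


def bulk_to_diffusion_ratio(
    radius_nm: float,
    dc_mm: float,
    c_mm: float,
    dp_mpa: float = 1.0,
    medium: TransportMedium = TransportMedium(),
) -> float:
    """Closed-form ratio ``dP C r^2 / (8 eta D dC)`` (dimensionless)."""
    if medium.diffusion_coefficient_nm2_s is None:
        raise InvalidQuantityError("medium has no diffusion coefficient")
    if dc_mm <= 0:
        return math.inf
    return (
        dp_mpa
        * c_mm
        * radius_nm**2
        / (8.0 * medium.viscosity_mpa_s * medium.diffusion_coefficient_nm2_s * dc_mm)
    )


def compare_modes(
    radius_nm: float,
    dc_values_mm: Sequence[float] = (200.0, 400.0),
    c_values_mm: Sequence[float] = (450.0, 600.0),
    dp_mpa: float = 1.0,
    medium: TransportMedium = TransportMedium(),
    length_nm: float = DEFAULT_CHANNEL_LENGTH_NM,
    dc_mm: float = DEFAULT_DC_MM,
    c_mm: float = DEFAULT_C_MM,
    threshold: float = DEFAULT_COMPARABLE_THRESHOLD,
) -> ModeComparisonRow:
    """Evaluate both transport modes for one radius over concentration grids."""
    channel = CylindricalChannel(radius_nm=radius_nm, length_nm=length_nm)
    flow = poiseuille_volume_flow(channel, dp_mpa, medium.viscosity_mpa_s)
    diffusion = {dc: fick_diffusion_rate(channel, medium, dc) for dc in dc_values_mm}
    bulk = {c: advective_solute_rate(flow, c) for c in c_values_mm}
    ratio = bulk_to_diffusion_ratio(radius_nm, dc_mm, c_mm, dp_mpa, medium)
    return ModeComparisonRow(
        microchannel_radius_nm=radius_nm,
        diffusion_rates=diffusion,
        bulk_rates=bulk,
        dc_mm=dc_mm,
        c_mm=c_mm,
        ratio=ratio,
        dominant_mode=classify_ratio(ratio, threshold),
    )


def reproduce_table4(
    radii_nm: Sequence[float] = (0.5, 1.0, 1.5, 2.0, 4.0, 8.0),
    dc_values_mm: Sequence[float] = (200.0, 400.0),
    c_values_mm: Sequence[float] = (450.0, 600.0),
    dp_mpa: float = 1.0,
    medium: TransportMedium = TransportMedium(),
    **kwargs,
) -> list[ModeComparisonRow]:
    """Mode-comparison rows over a radius grid (wheat-grain defaults)."""
    return [
        compare_modes(r, dc_values_mm, c_values_mm, dp_mpa, medium, **kwargs) for r in radii_nm
    ]


def comparison_frame(rows: Sequence[ModeComparisonRow]) -> pd.DataFrame:
    """Tabulate mode-comparison rows; rate columns in nmol s^-1."""
    records = []
    for row in rows:
        rec: dict[str, object] = {"radius_nm": row.microchannel_radius_nm}
        for dc, v in row.diffusion_rates.items():
            rec[f"diff_{dc:g}"] = v
        for c, v in row.bulk_rates.items():
            rec[f"bulk_{c:g}"] = v
        rec["ratio"] = row.ratio
        rec["dominant"] = row.dominant_mode
        records.append(rec)
    return pd.DataFrame(records)


def crossover_radius(
    dc_mm: float,
    c_mm: float,
    dp_mpa: float = 1.0,
    medium: TransportMedium = TransportMedium(),
    bracket_nm: tuple[float, float] = (0.1, 20.0),
    length_nm: float = DEFAULT_CHANNEL_LENGTH_NM,
    tol_nm: float = 1e-3,
) -> float:
    """Radius at which diffusion and bulk-flow rates are equal, in nm.

    Found by root bracketing on the log-ratio; the closed form
    ``r* = sqrt(8 eta D dC / (dP C))`` exists and is used as a cross-check
    in the test suite, not here.
    """
    if dc_mm <= 0:
        raise NoCrossoverError("no crossover: zero or negative dC means bulk flow dominates everywhere")
    if c_mm <= 0 or dp_mpa <= 0:
        raise NoCrossoverError("no crossover: bulk flow vanishes without positive dP and C")

    def log_ratio(r: float) -> float:
        return math.log(bulk_to_diffusion_ratio(r, dc_mm, c_mm, dp_mpa, medium))

    lo, hi = bracket_nm
    if log_ratio(lo) >= 0 or log_ratio(hi) <= 0:
        raise NoCrossoverError(
            f"no sign change in bracket {bracket_nm}: diffusion must dominate at "
            f"{lo} nm and bulk flow at {hi} nm"
        )
    return float(brentq(log_ratio, lo, hi, xtol=tol_nm))


def closed_form_crossover_radius(
    dc_mm: float,
    c_mm: float,
    dp_mpa: float = 1.0,
    medium: TransportMedium = TransportMedium(),
) -> float:
    """Analytic crossover radius ``sqrt(8 eta D dC / (dP C))`` in nm."""
    if dc_mm <= 0 or c_mm <= 0 or dp_mpa <= 0:
        raise NoCrossoverError("closed-form crossover needs positive dC, C and dP")
    assert medium.diffusion_coefficient_nm2_s is not None
    return math.sqrt(
        8.0
        * medium.viscosity_mpa_s
        * medium.diffusion_coefficient_nm2_s
        * dc_mm
        / (dp_mpa * c_mm)
    )


def dominance_profile(
    radii_nm: Sequence[float],
    dc_mm: float = DEFAULT_DC_MM,
    c_mm: float = DEFAULT_C_MM,
    dp_mpa: float = 1.0,
    medium: TransportMedium = TransportMedium(),
    threshold: float = DEFAULT_COMPARABLE_THRESHOLD,
) -> list[tuple[float, DominantMode]]:
    """Classify each radius; monotone in r (one diffusion->bulk transition)."""
    return [
        (
            r,
            classify_ratio(bulk_to_diffusion_ratio(r, dc_mm, c_mm, dp_mpa, medium), threshold),
        )
        for r in radii_nm
    ]


def radius_change_for_flow_gain(gain: float) -> float:
    """Fractional radius increase producing a fractional bulk-flow gain.

    Inverts the r^4 law: ``(1 + gain)**(1/4) - 1``.  A 10 % flow gain needs
    a 2.41 % radius increase (a published figure of 1.3 % for the same gain
    does not follow from the r^4 law and is reported alongside, never
    asserted — see the deviation annotations in the reports).
    """
    if gain <= -1:
        raise InvalidQuantityError(f"flow gain must exceed -1, got {gain}")
    return (1.0 + gain) ** 0.25 - 1.0


# Published wheat-grain comparison grid (rates x1e-10 nmol s^-1 as printed),
# with one-unit-in-last-digit (ulp) columns.  The (r=0.5, C=450) cell prints
# 0.22 where R_v * C gives 0.11; it is flagged as anomalous and excluded
# from agreement checks.
PUBLISHED_TABLE4 = pd.DataFrame(
    [
        (0.5, 1.64, 0.01, 3.28, 0.01, 0.22, 0.01, 0.14, 0.01, True),
        (1.0, 6.53, 0.01, 13.1, 0.1, 1.77, 0.01, 2.36, 0.01, False),
        (1.5, 14.7, 0.1, 29.4, 0.1, 8.95, 0.01, 11.9, 0.1, False),
        (2.0, 26.2, 0.1, 52.3, 0.1, 28.2, 0.1, 37.7, 0.1, False),
        (4.0, 105.0, 1.0, 209.0, 1.0, 453.0, 1.0, 603.0, 1.0, False),
        (8.0, 418.0, 1.0, 837.0, 1.0, 7_241.0, 1.0, 9_655.0, 1.0, False),
    ],
    columns=[
        "radius_nm",
        "printed_diff_200",
        "diff_200_ulp",
        "printed_diff_400",
        "diff_400_ulp",
        "printed_bulk_450",
        "bulk_450_ulp",
        "printed_bulk_600",
        "bulk_600_ulp",
        "bulk_450_anomalous",
    ],
)

#: relative agreement demanded of reproduced published values
GOLDEN_RTOL = 0.01

#: scale of the printed rates, nmol s^-1
PRINTED_RATE_SCALE = 1e-10


def _within(computed: float, printed: float, ulp: float) -> bool:
    return abs(computed - printed) <= max(GOLDEN_RTOL * abs(printed), ulp)


def compare_table4(rows: Sequence[ModeComparisonRow] | None = None) -> pd.DataFrame:
    """Reproduced mode-comparison grid beside the published one.

    Rates are scaled to the printed unit (1e-10 nmol s^-1).  Agreement is
    printed-precision-aware (max of 1 % and one unit in the last printed
    digit); the anomalous (r=0.5, C=450) cell is annotated and excluded
    from the agreement verdict rather than reproduced.
    """
    pub = PUBLISHED_TABLE4
    if rows is None:
        rows = reproduce_table4(pub["radius_nm"].tolist())
    if len(rows) != len(pub):
        raise InvalidQuantityError(
            f"expected {len(pub)} rows matching the published radius grid, got {len(rows)}"
        )
    records = []
    for row, (_, p) in zip(rows, pub.iterrows()):
        cells = {
            "diff_200": row.diffusion_rates[200.0] / PRINTED_RATE_SCALE,
            "diff_400": row.diffusion_rates[400.0] / PRINTED_RATE_SCALE,
            "bulk_450": row.bulk_rates[450.0] / PRINTED_RATE_SCALE,
            "bulk_600": row.bulk_rates[600.0] / PRINTED_RATE_SCALE,
        }
        anomalous = bool(p["bulk_450_anomalous"])
        agree = all(
            _within(cells[name], p[f"printed_{name}"], p[f"{name}_ulp"])
            for name in cells
            if not (anomalous and name == "bulk_450")
        )
        rec = {"radius_nm": row.microchannel_radius_nm}
        for name, value in cells.items():
            rec[name] = value
            rec[f"printed_{name}"] = p[f"printed_{name}"]
        rec["ratio"] = row.ratio
        rec["dominant"] = row.dominant_mode
        rec["bulk_450_printed_differs_from_formula"] = anomalous
        rec["agrees_with_printed"] = agree
        records.append(rec)
    return pd.DataFrame(records)
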