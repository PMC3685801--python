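"""Parameter fixtures and randomized measurement bundles.

Two sources of inputs let the whole pipeline run with no external data:

* **Fixtures** — the published measurements (turgor pairs, sap viscosity,
  plasmodesma counts, sucrose ranges) packaged as an immutable JSON
  resource, each value with units and a provenance citation.
* **Synthetic bundles** — randomized but physiologically plausible
  measurement sets drawn uniformly from the measured ranges (SE pressures
  0.5-2.4 MPa, parenchyma turgors 0.08-0.33 MPa, SE sucrose 450-600 mM,
  parenchyma sucrose 200-260 mM, microchannel radii 0.5-10 nm).  Sampling
  is a pure function of the seed; bundle invariants (positive pressure
  differential, SE sucrose above parenchyma sucrose) are enforced by
  rejection.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from importlib import resources
from types import MappingProxyType
from typing import Any, Mapping

import numpy as np

from .errors import SamplingError, UnknownFixtureError
from .plasmodesmata import PlasmodesmaGeometry, microchannels_per_pd
from .transport import CylindricalChannel, hydraulic_conductance

#: default sampling ranges (uniform unless noted); pd_count is log-uniform
DEFAULT_RANGES: Mapping[str, tuple[float, float]] = MappingProxyType(
    {
        "se_pressure_mpa": (0.5, 2.4),
        "sink_turgor_mpa": (0.08, 0.33),
        "sucrose_se_mm": (450.0, 600.0),
        "sucrose_parenchyma_mm": (200.0, 260.0),
        "microchannel_radius_nm": (0.5, 10.0),
        "pd_count": (1.0e7, 1.0e8),
        "import_rate_ul_day": (5.0, 15.0),
    }
)

_MAX_REJECTIONS = 1000


@dataclass(frozen=True)
class ParameterFixture:
    """An immutable named bundle of cited parameter values."""

    key: str
    description: str
    values: Mapping[str, Mapping[str, Any]]

    def value(self, name: str) -> float:
        """Scalar value of a named quantity (raises KeyError for ranges)."""
        return float(self.values[name]["value"])


@dataclass(frozen=True)
class SyntheticBundle:
    """One randomized measurement bundle for a sink-unloading scenario."""

    seed: int
    se_pressure_mpa: float
    sink_turgor_mpa: float
    sucrose_se_mm: float
    sucrose_parenchyma_mm: float
    microchannel_radius_nm: float
    pd_count: float
    import_rate_ul_day: float

    def to_dict(self) -> dict[str, float]:
        return asdict(self)


def _load_registry() -> dict[str, ParameterFixture]:
    raw = json.loads(
        resources.files("phloemflow").joinpath("data/fixtures.json").read_text()
    )
    registry = {}
    for key, body in raw["fixtures"].items():
        registry[key] = ParameterFixture(
            key=key,
            description=body["description"],
            values=MappingProxyType(
                {name: MappingProxyType(entry) for name, entry in body["values"].items()}
            ),
        )
    return registry


_REGISTRY = _load_registry()


def available_fixtures() -> list[str]:
    """Sorted keys of all registered fixtures."""
    return sorted(_REGISTRY)


def load_fixture(key: str) -> ParameterFixture:
    """Fetch a registered fixture by key.

    Raises :class:`~phloemflow.errors.UnknownFixtureError` listing the
    available keys if the key is not registered.
    """
    try:
        return _REGISTRY[key]
    except KeyError:
        raise UnknownFixtureError(
            f"unknown fixture {key!r}; available: {', '.join(available_fixtures())}"
        ) from None


def sample_bundle(
    seed: int,
    ranges: Mapping[str, tuple[float, float]] | None = None,
) -> SyntheticBundle:
    """Draw one synthetic measurement bundle, deterministically per seed.

    ``ranges`` overrides any subset of :data:`DEFAULT_RANGES`.  Bundles
    violating the physical invariants (SE pressure above sink turgor, SE
    sucrose above parenchyma sucrose) are rejected and redrawn; override
    ranges that make the invariants unsatisfiable raise
    :class:`~phloemflow.errors.SamplingError`.
    """
    merged = dict(DEFAULT_RANGES)
    if ranges:
        unknown = set(ranges) - set(merged)
        if unknown:
            raise SamplingError(f"unknown range keys: {sorted(unknown)}")
        merged.update(ranges)
    for name, (lo, hi) in merged.items():
        if not (math.isfinite(lo) and math.isfinite(hi) and lo <= hi and lo > 0):
            raise SamplingError(f"invalid range for {name}: ({lo}, {hi})")

    rng = np.random.default_rng(seed)
    for _ in range(_MAX_REJECTIONS):
        draw = {
            name: float(rng.uniform(lo, hi)) for name, (lo, hi) in merged.items()
            if name != "pd_count"
        }
        lo, hi = merged["pd_count"]
        draw["pd_count"] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        if (
            draw["se_pressure_mpa"] > draw["sink_turgor_mpa"]
            and draw["sucrose_se_mm"] > draw["sucrose_parenchyma_mm"]
        ):
            return SyntheticBundle(seed=seed, **draw)
    raise SamplingError(
        "could not satisfy bundle invariants (positive pressure differential, "
        f"SE sucrose above parenchyma) within {_MAX_REJECTIONS} draws; "
        "check override ranges"
    )


def make_network_bundle(
    seed: int,
    n_sinks: int,
    geometry: PlasmodesmaGeometry = PlasmodesmaGeometry(),
    viscosity_mpa_s: float = 2.0e-9,
    axial_multiplier_range: tuple[float, float] = (1.0, 1.0e3),
) -> dict[str, Any]:
    """Sample inputs for :func:`phloemflow.network.build_manifold`.

    Each sink's interface conductance is built physically: a sampled
    plasmodesma count times the microchannels per plasmodesma times the
    Poiseuille conductance of one microchannel.  Axial segment
    conductances are sampled as log-uniform multiples of the summed sink
    conductance, spanning the sink-dominated to manifold regimes.
    """
    if n_sinks < 1:
        raise SamplingError(f"need at least one sink, got {n_sinks}")
    rng = np.random.default_rng(seed)
    sink_conductances = []
    sink_turgors = []
    radii_lo, radii_hi = 0.5, 8.0
    for i in range(n_sinks):
        sub = sample_bundle(
            int(rng.integers(0, 2**31 - 1)),
            ranges={"microchannel_radius_nm": (radii_lo, radii_hi)},
        )
        channel = CylindricalChannel(
            radius_nm=sub.microchannel_radius_nm, length_nm=geometry.wall_thickness_nm
        )
        per_channel = hydraulic_conductance(channel, viscosity_mpa_s)
        per_pd = microchannels_per_pd(sub.microchannel_radius_nm, geometry)
        sink_conductances.append(sub.pd_count * per_pd * per_channel)
        sink_turgors.append(sub.sink_turgor_mpa)
    total_sink_g = sum(sink_conductances)
    lo, hi = axial_multiplier_range
    axial = [
        float(total_sink_g * np.exp(rng.uniform(np.log(lo), np.log(hi))))
        for _ in range(n_sinks)
    ]
    source_pressure = float(rng.uniform(max(sink_turgors) + 0.2, 2.4))
    return {
        "n_sinks": n_sinks,
        "axial_conductances": axial,
        "sink_interface_conductances": sink_conductances,
        "source_pressure_mpa": source_pressure,
        "sink_turgors_mpa": sink_turgors,
    }
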