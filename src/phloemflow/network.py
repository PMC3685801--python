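"""Steady-state conductance network for the source-path-sink manifold.

The high-pressure manifold picture of phloem transport says: the sieve-tube
system is held near source pressure along its whole length (high axial
hydraulic conductance), and the narrow plasmodesmal interfaces at each sink
(low conductance) are where the pressure is dropped — so each sink's share
of the exported resource is set by its interface conductance relative to
the others, not by its position along the path.

This module makes that quantitative.  A manifold is a comb graph::

    source -- j1 -- j2 -- ... -- jn        (axial sieve-tube segments)
               |     |            |
             sink1 sink2  ...   sinkn      (plasmodesmal interfaces)

Every edge obeys the linear law ``flow = L_o * (P_u - P_v)`` with a fixed
hydraulic conductance ``L_o`` (nm^3 s^-1 MPa^-1, from the Poiseuille
conductance of the conduits it lumps).  Source pressure and sink-cell
turgors are fixed Dirichlet boundaries; interior junction pressures come
from Kirchhoff conservation, a direct dense linear solve with a fixed node
ordering (deterministic, no iteration).

In the manifold limit (axial conductance >> summed sink conductance) the
solved partition fractions converge to the normalized sink conductances
and the axial pressure drop vanishes; :func:`manifold_regime_check`
measures how far a given network is from that limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .errors import NetworkConstructionError, SingularNetworkError

SOURCE = "source"


def _junction(i: int) -> str:
    return f"junction_{i}"


def _sink(i: int) -> str:
    return f"sink_{i}"


@dataclass(frozen=True)
class ManifoldNetwork:
    """A conductance network with fixed-pressure boundary nodes.

    ``graph`` holds one ``conductance`` attribute per edge
    (nm^3 s^-1 MPa^-1); ``boundary_pressures`` maps boundary node names to
    fixed pressures in MPa.  ``sink_nodes`` lists the terminals whose
    import rates define the partitioning; ``axial_nodes`` the ordered chain
    from the source along the path.
    """

    graph: nx.Graph
    boundary_pressures: Mapping[str, float]
    sink_nodes: tuple[str, ...]
    axial_nodes: tuple[str, ...]

    def __post_init__(self) -> None:
        for u, v, data in self.graph.edges(data=True):
            g = data.get("conductance")
            if g is None or not (math.isfinite(g) and g > 0):
                raise NetworkConstructionError(
                    f"edge ({u}, {v}) needs a positive finite conductance, got {g!r}"
                )
        missing = [n for n in self.boundary_pressures if n not in self.graph]
        if missing:
            raise NetworkConstructionError(f"boundary nodes absent from graph: {missing}")
        if not nx.is_connected(self.graph):
            raise NetworkConstructionError("manifold network must be connected")

    @property
    def interior_nodes(self) -> list[str]:
        return [n for n in self.graph.nodes if n not in self.boundary_pressures]


@dataclass(frozen=True)
class FlowSolution:
    """Solved node pressures, edge flows and sink partitioning.

    ``edge_flows[(u, v)]`` is the signed volume flow from ``u`` to ``v``
    in nm^3 s^-1.  ``partition_fractions`` sum to 1 over the sinks.
    ``axial_pressure_drop_mpa`` is the pressure lost along the axial chain
    from the source to its far end.
    """

    node_pressures: Mapping[str, float]
    edge_flows: Mapping[tuple[str, str], float]
    sink_imports: Mapping[str, float]
    partition_fractions: Mapping[str, float]
    axial_pressure_drop_mpa: float


def build_manifold(
    n_sinks: int,
    axial_conductances: Sequence[float],
    sink_interface_conductances: Sequence[float],
    source_pressure_mpa: float,
    sink_turgors_mpa: Sequence[float],
) -> ManifoldNetwork:
    """Assemble the comb-topology manifold network.

    ``axial_conductances[i]`` is the conductance of the sieve-tube segment
    ending at junction i; ``sink_interface_conductances[i]`` that of the
    plasmodesmal interface from junction i to sink i.
    """
    if n_sinks < 1:
        raise NetworkConstructionError(f"need at least one sink, got {n_sinks}")
    if not (
        len(axial_conductances) == len(sink_interface_conductances)
        == len(sink_turgors_mpa) == n_sinks
    ):
        raise NetworkConstructionError(
            "axial conductances, sink conductances and sink turgors must all "
            f"have length n_sinks={n_sinks}; got "
            f"{len(axial_conductances)}/{len(sink_interface_conductances)}/"
            f"{len(sink_turgors_mpa)}"
        )
    g = nx.Graph()
    prev = SOURCE
    boundaries: dict[str, float] = {SOURCE: float(source_pressure_mpa)}
    axial = [SOURCE]
    sinks = []
    for i in range(n_sinks):
        j, s = _junction(i), _sink(i)
        g.add_edge(prev, j, conductance=float(axial_conductances[i]))
        g.add_edge(j, s, conductance=float(sink_interface_conductances[i]))
        boundaries[s] = float(sink_turgors_mpa[i])
        axial.append(j)
        sinks.append(s)
        prev = j
    return ManifoldNetwork(
        graph=g,
        boundary_pressures=boundaries,
        sink_nodes=tuple(sinks),
        axial_nodes=tuple(axial),
    )


def solve_steady_state(network: ManifoldNetwork) -> FlowSolution:
    """Solve Kirchhoff conservation for interior pressures and all flows.

    Interior node pressures satisfy ``sum_k G_ik (P_k - P_i) = 0``; the
    reduced system ``A p = b`` (weighted-Laplacian block for interior
    nodes, boundary terms moved to the right-hand side) is solved densely
    with a fixed node ordering.
    """
    interior = network.interior_nodes
    index = {n: i for i, n in enumerate(interior)}
    n = len(interior)
    pressures = dict(network.boundary_pressures)
    if n:
        a = np.zeros((n, n))
        b = np.zeros(n)
        for u, v, data in network.graph.edges(data=True):
            g = data["conductance"]
            for x, y in ((u, v), (v, u)):
                if x in index:
                    i = index[x]
                    a[i, i] += g
                    if y in index:
                        a[i, index[y]] -= g
                    else:
                        b[i] += g * pressures[y]
        try:
            p = np.linalg.solve(a, b)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by connectivity
            raise SingularNetworkError(str(exc)) from exc
        pressures.update({node: float(p[i]) for node, i in index.items()})

    flows = {
        (u, v): data["conductance"] * (pressures[u] - pressures[v])
        for u, v, data in network.graph.edges(data=True)
    }
    sink_imports = {}
    for s in network.sink_nodes:
        total = 0.0
        for nbr in network.graph.neighbors(s):
            g = network.graph[s][nbr]["conductance"]
            total += g * (pressures[nbr] - pressures[s])
        sink_imports[s] = total
    total_import = sum(sink_imports.values())
    if total_import == 0:
        fractions = {s: math.nan for s in network.sink_nodes}
    else:
        fractions = {s: v / total_import for s, v in sink_imports.items()}
    axial_drop = pressures[network.axial_nodes[0]] - pressures[network.axial_nodes[-1]]
    return FlowSolution(
        node_pressures=pressures,
        edge_flows=flows,
        sink_imports=sink_imports,
        partition_fractions=fractions,
        axial_pressure_drop_mpa=axial_drop,
    )


def conservation_residual(network: ManifoldNetwork, solution: FlowSolution) -> float:
    """Worst interior-node flow imbalance relative to the node's gross flow."""
    worst = 0.0
    for node in network.interior_nodes:
        net = 0.0
        gross = 0.0
        for nbr in network.graph.neighbors(node):
            g = network.graph[node][nbr]["conductance"]
            f = g * (solution.node_pressures[nbr] - solution.node_pressures[node])
            net += f
            gross += abs(f)
        if gross > 0:
            worst = max(worst, abs(net) / gross)
    return worst


def manifold_regime_check(network: ManifoldNetwork, solution: FlowSolution) -> dict[str, float]:
    """Quantify proximity to the manifold operating regime.

    Returns ``axial_drop_fraction`` — the axial pressure drop normalized by
    the overall source-to-sink differential (source pressure minus mean
    sink turgor) — and ``partition_vs_conductance_deviation`` — the worst
    absolute difference between a sink's solved partition fraction and its
    normalized interface conductance.  Both approach 0 as the axial
    conductance outgrows the summed sink conductances.
    """
    source_p = network.boundary_pressures[network.axial_nodes[0]]
    mean_turgor = float(
        np.mean([network.boundary_pressures[s] for s in network.sink_nodes])
    )
    overall_dp = source_p - mean_turgor
    conductances = {
        s: network.graph[s][next(iter(network.graph.neighbors(s)))]["conductance"]
        for s in network.sink_nodes
    }
    total_g = sum(conductances.values())
    deviation = max(
        abs(solution.partition_fractions[s] - conductances[s] / total_g)
        for s in network.sink_nodes
    )
    return {
        "axial_drop_fraction": solution.axial_pressure_drop_mpa / overall_dp,
        "partition_vs_conductance_deviation": deviation,
    }


def network_from_config(config: Mapping) -> ManifoldNetwork:
    """Build a manifold network from a plain config mapping.

    Expected keys: ``n_sinks``, ``axial_conductances``,
    ``sink_interface_conductances``, ``source_pressure_mpa``,
    ``sink_turgors_mpa``.  Raises
    :class:`~phloemflow.errors.NetworkConstructionError` naming any
    missing field.
    """
    required = (
        "n_sinks",
        "axial_conductances",
        "sink_interface_conductances",
        "source_pressure_mpa",
        "sink_turgors_mpa",
    )
    missing = [k for k in required if k not in config]
    if missing:
        raise NetworkConstructionError(f"network config missing fields: {missing}")
    return build_manifold(
        n_sinks=int(config["n_sinks"]),
        axial_conductances=list(config["axial_conductances"]),
        sink_interface_conductances=list(config["sink_interface_conductances"]),
        source_pressure_mpa=float(config["source_pressure_mpa"]),
        sink_turgors_mpa=list(config["sink_turgors_mpa"]),
    )
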