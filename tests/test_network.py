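"""Manifold conductance network: solver correctness and regime behaviour."""

import math

import networkx as nx
import numpy as np
import pytest

from phloemflow import (
    CylindricalChannel,
    ManifoldNetwork,
    NetworkConstructionError,
    OrganImportSpec,
    build_manifold,
    conservation_residual,
    hydraulic_conductance,
    manifold_regime_check,
    microchannels_per_pd,
    network_from_config,
    required_pd_count,
    solve_steady_state,
)


def oracle_pressures(graph, boundaries):
    """Independent dense solve of the full nodal system.

    One equation per node: identity rows for boundary nodes, Kirchhoff
    conservation rows for the rest; assembled and solved as a single
    square dense system (a different path from the package's reduced
    interior-block assembly).
    """
    nodes = sorted(graph.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    a = np.zeros((n, n))
    b = np.zeros(n)
    for node in nodes:
        i = idx[node]
        if node in boundaries:
            a[i, i] = 1.0
            b[i] = boundaries[node]
        else:
            for nbr in graph.neighbors(node):
                g = graph[node][nbr]["conductance"]
                a[i, i] -= g
                a[i, idx[nbr]] += g
    return dict(zip(nodes, np.linalg.solve(a, b)))


class TestConstruction:
    def test_single_sink_is_a_three_node_series(self):
        net = build_manifold(1, [1e10], [1e8], 1.0, [0.1])
        assert net.graph.number_of_nodes() == 3
        assert net.graph.number_of_edges() == 2

    def test_length_mismatch_rejected(self):
        with pytest.raises(NetworkConstructionError):
            build_manifold(3, [1e10, 1e10], [1e8] * 3, 1.0, [0.1] * 3)

    def test_nonpositive_conductance_rejected(self):
        with pytest.raises(NetworkConstructionError):
            build_manifold(1, [0.0], [1e8], 1.0, [0.1])

    def test_zero_sinks_rejected(self):
        with pytest.raises(NetworkConstructionError):
            build_manifold(0, [], [], 1.0, [])

    def test_config_round_trip_and_missing_fields(self):
        config = {
            "n_sinks": 2,
            "axial_conductances": [1e10, 1e10],
            "sink_interface_conductances": [1e8, 2e8],
            "source_pressure_mpa": 1.0,
            "sink_turgors_mpa": [0.1, 0.2],
        }
        net = network_from_config(config)
        assert net.graph.number_of_nodes() == 5
        with pytest.raises(NetworkConstructionError, match="sink_turgors_mpa"):
            network_from_config({k: v for k, v in config.items() if k != "sink_turgors_mpa"})


class TestSolver:
    def test_two_edges_in_series_closed_form(self):
        l1, l2, ps, pt = 3e9, 7e8, 1.2, 0.15
        net = build_manifold(1, [l1], [l2], ps, [pt])
        sol = solve_steady_state(net)
        expected = (ps - pt) / (1 / l1 + 1 / l2)
        assert sol.sink_imports["sink_0"] == pytest.approx(expected, rel=1e-12)

    def test_identical_sinks_split_evenly_in_the_manifold_limit(self):
        """The comb chain is not literally symmetric (the far sink sits
        behind more axial resistance); equal sinks split 50/50 only as the
        axial conductance dominates, and the near sink always gets more."""
        net = build_manifold(2, [1e14, 1e14], [1e8, 1e8], 1.0, [0.1, 0.1])
        sol = solve_steady_state(net)
        assert sol.partition_fractions["sink_0"] == pytest.approx(0.5, abs=1e-5)
        assert sol.partition_fractions["sink_1"] == pytest.approx(0.5, abs=1e-5)
        assert sol.partition_fractions["sink_0"] > sol.partition_fractions["sink_1"]

    def test_single_sink_takes_everything(self):
        net = build_manifold(1, [5e9], [3e7], 1.0, [0.1])
        sol = solve_steady_state(net)
        assert sol.partition_fractions["sink_0"] == pytest.approx(1.0, rel=1e-12)

    def test_matches_dense_oracle_on_random_networks(self):
        """Solved pressures agree with an independent full dense solve to 1e-10."""
        rng = np.random.default_rng(7)
        for _ in range(25):
            n_sinks = int(rng.integers(1, 3))  # up to 6 nodes, comb topology
            net = build_manifold(
                n_sinks,
                rng.uniform(1e6, 1e12, n_sinks).tolist(),
                rng.uniform(1e6, 1e12, n_sinks).tolist(),
                float(rng.uniform(0.8, 2.4)),
                rng.uniform(0.05, 0.4, n_sinks).tolist(),
            )
            sol = solve_steady_state(net)
            ref = oracle_pressures(net.graph, net.boundary_pressures)
            for node, p in sol.node_pressures.items():
                assert p == pytest.approx(ref[node], rel=1e-10, abs=1e-10)

    def test_matches_oracle_on_a_random_mesh_graph(self):
        """Non-comb topology: a random connected 6-node mesh."""
        rng = np.random.default_rng(11)
        g = nx.Graph()
        nodes = ["source", "a", "b", "c", "sink_x", "sink_y"]
        while not (g.number_of_nodes() == 6 and nx.is_connected(g)):
            g = nx.Graph()
            g.add_nodes_from(nodes)
            for i, u in enumerate(nodes):
                for v in nodes[i + 1:]:
                    if rng.random() < 0.6:
                        g.add_edge(u, v, conductance=float(rng.uniform(1e6, 1e10)))
        net = ManifoldNetwork(
            graph=g,
            boundary_pressures={"source": 1.5, "sink_x": 0.1, "sink_y": 0.3},
            sink_nodes=("sink_x", "sink_y"),
            axial_nodes=("source",),
        )
        sol = solve_steady_state(net)
        ref = oracle_pressures(g, net.boundary_pressures)
        for node, p in sol.node_pressures.items():
            assert p == pytest.approx(ref[node], rel=1e-10, abs=1e-10)

    def test_kirchhoff_conservation(self):
        rng = np.random.default_rng(3)
        net = build_manifold(
            4,
            rng.uniform(1e8, 1e12, 4).tolist(),
            rng.uniform(1e6, 1e10, 4).tolist(),
            1.4,
            rng.uniform(0.05, 0.3, 4).tolist(),
        )
        sol = solve_steady_state(net)
        assert conservation_residual(net, sol) <= 1e-9

    def test_partition_fractions_sum_to_one(self):
        net = build_manifold(3, [1e11] * 3, [1e8, 3e8, 6e8], 1.2, [0.1, 0.2, 0.15])
        sol = solve_steady_state(net)
        assert sum(sol.partition_fractions.values()) == pytest.approx(1.0, abs=1e-12)


class TestRegime:
    def test_monotone_response_to_one_sink_conductance(self):
        """Raising one sink's interface conductance raises its share and
        weakly lowers everyone else's."""
        base_g = [1e8, 1e8, 1e8]
        shares = []
        others = []
        for scale in (1.0, 2.0, 5.0, 20.0):
            g = list(base_g)
            g[1] = base_g[1] * scale
            net = build_manifold(3, [1e10] * 3, g, 1.0, [0.1] * 3)
            sol = solve_steady_state(net)
            shares.append(sol.partition_fractions["sink_1"])
            others.append(sol.partition_fractions["sink_0"])
        assert all(a < b for a, b in zip(shares, shares[1:]))
        assert all(a >= b for a, b in zip(others, others[1:]))

    def test_manifold_limit_convergence(self):
        """As axial conductance outgrows sink conductance, partitioning
        converges to conductance ratios and the axial drop vanishes."""
        sink_g = [1e8, 2e8, 3e8]
        deviations, drops = [], []
        for ratio in (1.0, 10.0, 100.0, 1000.0):
            axial = [ratio * sum(sink_g)] * 3
            net = build_manifold(3, axial, sink_g, 1.2, [0.1] * 3)
            sol = solve_steady_state(net)
            regime = manifold_regime_check(net, sol)
            deviations.append(regime["partition_vs_conductance_deviation"])
            drops.append(regime["axial_drop_fraction"])
        assert all(a > b for a, b in zip(deviations, deviations[1:]))
        assert all(a > b for a, b in zip(drops, drops[1:]))
        assert deviations[-1] < 0.02 and drops[-1] < 0.02

    def test_high_axial_ratio_reaches_manifold_regime(self):
        sink_g = [1e8, 5e8]
        net = build_manifold(2, [100 * sum(sink_g)] * 2, sink_g, 1.0, [0.1, 0.1])
        sol = solve_steady_state(net)
        regime = manifold_regime_check(net, sol)
        assert regime["axial_drop_fraction"] < 0.02
        assert regime["partition_vs_conductance_deviation"] < 0.02

    def test_wheat_grain_operating_point(self):
        """A single-sink network built from the feasibility-table counts at
        r = 1 nm carries the grain's import flow at a 1.0 MPa differential."""
        spec = OrganImportSpec()
        row = required_pd_count(spec, 1.0)
        per_channel_g = hydraulic_conductance(
            CylindricalChannel(radius_nm=1.0, length_nm=500.0)
        )
        sink_g = row.pd_required * row.microchannels_per_pd * per_channel_g
        net = build_manifold(1, [1e6 * sink_g], [sink_g], 1.1, [0.1])
        sol = solve_steady_state(net)
        assert sol.sink_imports["sink_0"] == pytest.approx(
            spec.target_flow_nm3_s, rel=0.01
        )
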