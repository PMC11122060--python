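"""Shared fixtures: reference m-graphs and a brute-force d-separation oracle."""

from __future__ import annotations

import itertools

import networkx as nx
import pytest

from misscen import build_graph


@pytest.fixture
def fig3a():
    """Bivariate collection-policy graph: X1->X2, R1 exogenous, R2 <- {R1, X1}."""
    return build_graph(
        {
            "variables": ["X1", "X2"],
            "edges": [["X1", "X2"]],
            "mechanisms": {
                "R_X1": {"parents": [], "link": "constant", "probability": 0.8},
                "R_X2": {
                    "parents": ["R_X1", "X1"],
                    "link": "logistic",
                    "intercept": 1.0,
                    "weights": [1.0, 2.0],
                },
            },
        }
    )


@pytest.fixture
def self_masking_graph():
    """A variable driving its own indicator: the canonical unidentifiable case."""
    return build_graph(
        {
            "variables": ["Y"],
            "edges": [],
            "mechanisms": {
                "R_Y": {"parents": ["Y"], "link": "logistic", "intercept": 0.0, "weights": [1.5]}
            },
        }
    )


@pytest.fixture
def mcar_graph():
    """Three variables, all indicators exogenous constants."""
    return build_graph(
        {
            "variables": ["A", "B", "C"],
            "edges": [["A", "B"], ["B", "C"]],
            "mechanisms": {
                f"R_{v}": {"parents": [], "link": "constant", "probability": p}
                for v, p in (("A", 0.9), ("B", 0.7), ("C", 0.5))
            },
        }
    )


def brute_force_d_separated(g: nx.DiGraph, a: str, b: str, z: set[str]) -> bool:
    """Path-enumeration d-separation oracle (singleton endpoints).

    A path is blocked given Z iff it carries a non-collider node in Z, or
    a collider node with no descendant (itself included) in Z. Separated
    means every undirected simple path is blocked.
    """
    undirected = g.to_undirected()
    desc = {n: nx.descendants(g, n) | {n} for n in g.nodes}
    for path in nx.all_simple_paths(undirected, a, b):
        blocked = False
        for i in range(1, len(path) - 1):
            prev, node, nxt = path[i - 1], path[i], path[i + 1]
            is_collider = g.has_edge(prev, node) and g.has_edge(nxt, node)
            if is_collider:
                if not (desc[node] & z):
                    blocked = True
                    break
            elif node in z:
                blocked = True
                break
        if not blocked:
            return False
    return True


def dsep_fixture_suite():
    """Small graphs (<= 6 nodes) exercising chains, forks, colliders, m-graphs."""
    graphs = {}
    graphs["chain"] = nx.DiGraph([("A", "B"), ("B", "C")])
    graphs["fork"] = nx.DiGraph([("B", "A"), ("B", "C")])
    graphs["collider"] = nx.DiGraph([("A", "C"), ("B", "C")])
    graphs["collider_desc"] = nx.DiGraph([("A", "C"), ("B", "C"), ("C", "D")])
    graphs["m_structure"] = nx.DiGraph(
        [("U1", "A"), ("U1", "C"), ("U2", "C"), ("U2", "B")]
    )
    graphs["fig3a"] = nx.DiGraph(
        [
            ("X1", "X2"),
            ("X1", "X1s"),
            ("R1", "X1s"),
            ("X1", "R2"),
            ("R1", "R2"),
            ("X2", "X2s"),
            ("R2", "X2s"),
        ]
    )
    graphs["selection"] = nx.DiGraph(
        [("X", "Y"), ("Y", "Rd"), ("Rd", "R1"), ("Rd", "R2"), ("X", "R1")]
    )
    graphs["two_isolated"] = nx.DiGraph()
    graphs["two_isolated"].add_nodes_from(["A", "B"])
    return graphs


def all_dsep_triples(nodes):
    """Every (a, b, Z) with singleton endpoints and Z over the rest."""
    for a, b in itertools.combinations(nodes, 2):
        rest = [n for n in nodes if n not in (a, b)]
        for r in range(len(rest) + 1):
            for z in itertools.combinations(rest, r):
                yield a, b, set(z)
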