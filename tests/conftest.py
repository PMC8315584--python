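"""Shared fixtures and oracle helpers for the test suite."""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import pytest

from cohesionet import from_edges


def net_with_counts(targets):
    """Build a temporal network whose cumulative (N, E) per month hit
    ``targets = [(N_1, E_1), (N_2, E_2), ...]`` exactly.

    Edges are taken in lexicographic pair order among the first N_m
    nodes, so every node is touched as soon as its month requires it.
    Used as an exact scaffold for scaling-law tests where only the
    counts matter.
    """
    n_final = targets[-1][0]
    names = [f"n{i:04d}" for i in range(n_final)]
    used = set()
    edges = []
    for month, (n_m, e_m) in enumerate(targets, start=1):
        if e_m > n_m * (n_m - 1) // 2:
            raise ValueError("edge target exceeds simple-graph capacity")
        # make sure every node up to n_m appears: pair it with node 0 first
        for pair in [(0, j) for j in range(1, n_m)] + list(combinations(range(n_m), 2)):
            if len(edges) >= e_m:
                break
            if pair in used:
                continue
            used.add(pair)
            edges.append((names[pair[0]], names[pair[1]], month))
        assert len(edges) == e_m, "could not reach edge target"
        g = nx.Graph((u, v) for u, v, _ in edges)
        assert g.number_of_nodes() == n_m
    return from_edges(edges)


@pytest.fixture
def triangle_plus_pendant():
    g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"), ("a", "d")])
    return g


@pytest.fixture
def toy_temporal():
    """Edges a-b at month 1, b-c at month 3."""
    return from_edges([("a", "b", 1), ("b", "c", 3)])
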