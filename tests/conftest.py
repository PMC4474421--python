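"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's own graph code: path
enumeration goes through ``networkx.all_simple_paths`` and the filter
oracle applies the elimination rules literally to raw edge lists.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

from cypnet import (
    Entity,
    InteractionRecord,
    InteractionTable,
    SignedNetwork,
)

ROLES = ("compound", "regulator", "enzyme")


@pytest.fixture
def ra_table() -> InteractionTable:
    """The retinoic-acid motif: RA activates DAX1, DAX1 inhibits CYP19A1."""
    entities = {
        "RA": Entity("RA", "retinoic acid", "compound"),
        "DAX1": Entity("DAX1", "DAX1", "regulator"),
        "CYP19A1": Entity("CYP19A1", "aromatase", "enzyme"),
    }
    records = [
        InteractionRecord("RA", "DAX1", +1),
        InteractionRecord("DAX1", "CYP19A1", -1),
    ]
    return InteractionTable(entities=entities, records=records)


@pytest.fixture
def ra_network(ra_table) -> SignedNetwork:
    net = SignedNetwork(ra_table.entities.values())
    for rec in ra_table.records:
        net.add_edge(rec.source_id, rec.target_id, rec.sign)
    return net


def make_network(
    nodes: dict[str, str], edges: list[tuple[str, str, int]]
) -> SignedNetwork:
    """Build a SignedNetwork from {id: role} and signed edge triples."""
    net = SignedNetwork(Entity(nid, nid, role) for nid, role in nodes.items())
    for u, v, s in edges:
        net.add_edge(u, v, s)
    return net


def random_network(
    rng: np.random.Generator,
    n_nodes: int = 10,
    edge_prob: float = 0.25,
    acyclic: bool = False,
    roles: dict[str, str] | None = None,
) -> SignedNetwork:
    """A random role-annotated signed digraph (simple, no self-loops).

    Pass ``roles`` to share one role annotation across several networks
    (required for merging them)."""
    ids = [f"n{i:02d}" for i in range(n_nodes)]
    if roles is None:
        roles = {nid: ROLES[rng.integers(0, 3)] for nid in ids}
    edges = []
    for i, u in enumerate(ids):
        for j, v in enumerate(ids):
            if i == j or (acyclic and j <= i):
                continue
            if rng.random() < edge_prob:
                edges.append((u, v, int(rng.choice([-1, 0, 1]))))
    return make_network(roles, edges)


# -- independent oracles ----------------------------------------------------


def oracle_simple_paths(
    net: SignedNetwork, source: str, max_depth: int
) -> set[tuple[tuple[str, ...], int]]:
    """All simple paths from source to out-degree-0 nodes, with net signs,
    enumerated via networkx.all_simple_paths."""
    g = net.graph
    leaves = [n for n in g.nodes if g.out_degree(n) == 0 and n != source]
    found = set()
    for leaf in leaves:
        for path in nx.all_simple_paths(g, source, leaf, cutoff=max_depth):
            signs = [g[a][b]["sign"] for a, b in itertools.pairwise(path)]
            net_sign = 0 if 0 in signs else int(np.prod(signs))
            found.add((tuple(path), net_sign))
    return found


def oracle_filter(
    nodes: dict[str, str],
    edges: list[tuple[str, str, int]],
    min_compound_edges: int,
    drop_orphan_regulators: bool = True,
    iterate: bool = False,
) -> set[str]:
    """Literal application of the elimination rules to raw edge lists;
    returns the surviving node ids."""
    alive = set(nodes)

    def degree(n: str) -> int:
        return sum(
            1 for u, v, _ in edges if (u == n or v == n) and u in alive and v in alive
        )

    def has_compound_neighbor(n: str) -> bool:
        for u, v, _ in edges:
            if u not in alive or v not in alive:
                continue
            if u == n and nodes[v] == "compound":
                return True
            if v == n and nodes[u] == "compound":
                return True
        return False

    while True:
        weak = {
            n for n in alive
            if nodes[n] == "compound" and degree(n) < min_compound_edges
        }
        alive -= weak
        orphans: set[str] = set()
        if drop_orphan_regulators:
            orphans = {
                n for n in alive
                if nodes[n] == "regulator" and not has_compound_neighbor(n)
            }
            alive -= orphans
        if not iterate or (not weak and not orphans):
            return alive
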