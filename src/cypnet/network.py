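"""Signed regulatory-network construction, filtering, merging and tracing.

The discovery pipeline models a layered system: compounds act on CYP
regulators (transcription factors and nuclear receptors), which in turn
act on CYP enzymes.  Edges carry a sign — +1 activation, -1 inhibition,
0 unknown — and the predicted effect of a compound on a downstream gene
is the product of the edge signs along a path, with 0 absorbing.

The pipeline stages mirror how such networks are curated in practice:

1. :func:`build_network` — project an interaction table onto the node
   roles of interest (e.g. compound -> regulator).
2. :func:`filter_network` — drop weakly connected compounds (fewer than a
   threshold of distinct incident edges) and regulators with no compound
   neighbours.
3. :func:`merge_networks` — union the compound-regulator and
   regulator-enzyme layers into the final network.
4. :func:`find_clusters` — rank regulator hubs by how many compounds
   target them.
5. :func:`trace_paths` / :func:`predict_interactions` — enumerate simple
   directed paths from each compound to its terminal leaves and compose
   signs to predict compound-enzyme interactions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import networkx as nx
import pandas as pd

from .errors import ArgumentError, ValidationError
from .io import ROLES, Entity, InteractionTable

logger = logging.getLogger(__name__)


class SignedNetwork:
    """A directed graph of role-annotated entities with signed edges.

    At most one edge exists per ordered node pair; self-loops are
    rejected.  Backed by a :class:`networkx.DiGraph` exposed as
    :attr:`graph` for interoperability.
    """

    def __init__(self, entities: Iterable[Entity] = ()):
        self._g = nx.DiGraph()
        for ent in entities:
            self.add_entity(ent)

    # -- construction -------------------------------------------------
    def add_entity(self, entity: Entity) -> None:
        existing = self._g.nodes.get(entity.id)
        if existing is not None and existing["role"] != entity.role:
            raise ValidationError(
                f"entity {entity.id!r} annotated with conflicting roles "
                f"{existing['role']!r} and {entity.role!r}"
            )
        self._g.add_node(entity.id, name=entity.name, role=entity.role)

    def add_edge(self, source_id: str, target_id: str, sign: int) -> None:
        """Add a signed edge; a conflicting sign for an existing edge
        collapses to 0 (unknown) with a logged warning."""
        if source_id == target_id:
            raise ValidationError(f"self-loop on {source_id!r} is not allowed")
        for eid in (source_id, target_id):
            if eid not in self._g:
                raise ValidationError(f"edge endpoint {eid!r} is not a node")
        if sign not in (+1, -1, 0):
            raise ValidationError(f"invalid sign {sign!r}")
        if self._g.has_edge(source_id, target_id):
            old = self._g[source_id][target_id]["sign"]
            if old != sign:
                logger.warning(
                    "conflicting signs %+d/%+d for edge %s->%s; set to 0 (unknown)",
                    old, sign, source_id, target_id,
                )
                self._g[source_id][target_id]["sign"] = 0
        else:
            self._g.add_edge(source_id, target_id, sign=sign)

    # -- inspection ----------------------------------------------------
    @property
    def graph(self) -> nx.DiGraph:
        return self._g

    def nodes(self) -> list[str]:
        return list(self._g.nodes)

    def entity(self, node_id: str) -> Entity:
        data = self._g.nodes[node_id]
        return Entity(id=node_id, name=data["name"], role=data["role"])

    def entities(self) -> Iterator[Entity]:
        for nid in self._g.nodes:
            yield self.entity(nid)

    def role(self, node_id: str) -> str:
        return self._g.nodes[node_id]["role"]

    def edges(self) -> list[tuple[str, str, int]]:
        return [(u, v, d["sign"]) for u, v, d in self._g.edges(data=True)]

    def sign(self, source_id: str, target_id: str) -> int:
        return self._g[source_id][target_id]["sign"]

    def has_node(self, node_id: str) -> bool:
        return node_id in self._g

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def nodes_with_role(self, role: str) -> list[str]:
        return [n for n, d in self._g.nodes(data=True) if d["role"] == role]

    def copy(self) -> "SignedNetwork":
        out = SignedNetwork()
        out._g = self._g.copy()
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignedNetwork):
            return NotImplemented
        mine = {(n, d["role"]) for n, d in self._g.nodes(data=True)}
        theirs = {(n, d["role"]) for n, d in other._g.nodes(data=True)}
        return mine == theirs and set(self.edges()) == set(other.edges())

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"SignedNetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


@dataclass(frozen=True)
class FilterConfig:
    """Elimination thresholds for :func:`filter_network`.

    ``min_compound_edges`` — minimum number of distinct incident edges a
    compound must have to survive (the curation heuristic that compounds
    with very few curated interactions are too thinly supported).
    ``drop_orphan_regulators`` — remove regulators with no compound
    neighbour.  ``iterate_to_fixpoint`` — repeat both passes until stable,
    since removals cascade.
    """

    min_compound_edges: int = 3
    drop_orphan_regulators: bool = True
    iterate_to_fixpoint: bool = False

    def __post_init__(self) -> None:
        if self.min_compound_edges < 0:
            raise ArgumentError("min_compound_edges must be >= 0")


@dataclass(frozen=True)
class RegulatorCluster:
    """A regulator hub and the set of compounds targeting it."""

    hub_id: str
    member_compound_ids: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.member_compound_ids)


@dataclass(frozen=True)
class PathPrediction:
    """A compound-to-terminal-leaf path with its composed net sign."""

    compound_id: str
    terminal_id: str
    node_sequence: tuple[str, ...]
    edge_signs: tuple[int, ...]

    @property
    def net_sign(self) -> int:
        sign = 1
        for s in self.edge_signs:
            if s == 0:
                return 0
            sign *= s
        return sign


def build_network(
    table: InteractionTable,
    allowed_source_roles: Iterable[str],
    allowed_target_roles: Iterable[str],
) -> SignedNetwork:
    """Project an interaction table onto the roles of interest.

    Keeps exactly the records whose source role is in
    ``allowed_source_roles`` and target role in ``allowed_target_roles``.
    Records for the same ordered pair with conflicting signs collapse to a
    single sign-0 edge (logged).
    """
    src_roles = frozenset(allowed_source_roles)
    tgt_roles = frozenset(allowed_target_roles)
    for roles, label in ((src_roles, "source"), (tgt_roles, "target")):
        if not roles:
            raise ArgumentError(f"allowed {label} role set must be non-empty")
        bad = roles - set(ROLES)
        if bad:
            raise ArgumentError(f"unknown {label} roles: {sorted(bad)}")

    net = SignedNetwork()
    for rec in table.records:
        if (
            table.role(rec.source_id) in src_roles
            and table.role(rec.target_id) in tgt_roles
        ):
            net.add_entity(table.entities[rec.source_id])
            net.add_entity(table.entities[rec.target_id])
            net.add_edge(rec.source_id, rec.target_id, rec.sign)
    return net


def _compound_degree(g: nx.DiGraph, node: str) -> int:
    # distinct incident edges in a simple digraph: in-degree + out-degree
    return g.in_degree(node) + g.out_degree(node)


def _has_compound_neighbor(g: nx.DiGraph, node: str) -> bool:
    neighbors = set(g.predecessors(node)) | set(g.successors(node))
    return any(g.nodes[n]["role"] == "compound" for n in neighbors)


def filter_network(net: SignedNetwork, cfg: FilterConfig = FilterConfig()) -> SignedNetwork:
    """Apply the two elimination rules; the input network is not mutated.

    Pass 1 removes every compound with fewer than
    ``cfg.min_compound_edges`` distinct incident edges; pass 2 removes
    every regulator left without a compound neighbour.  With
    ``iterate_to_fixpoint`` the passes repeat until no node is removed.
    """
    out = net.copy()
    g = out.graph
    while True:
        weak = [
            n
            for n, d in g.nodes(data=True)
            if d["role"] == "compound"
            and _compound_degree(g, n) < cfg.min_compound_edges
        ]
        g.remove_nodes_from(weak)
        orphans: list[str] = []
        if cfg.drop_orphan_regulators:
            orphans = [
                n
                for n, d in g.nodes(data=True)
                if d["role"] == "regulator" and not _has_compound_neighbor(g, n)
            ]
            g.remove_nodes_from(orphans)
        if not cfg.iterate_to_fixpoint or (not weak and not orphans):
            break
    return out


def merge_networks(a: SignedNetwork, b: SignedNetwork) -> SignedNetwork:
    """Union of nodes and edges; conflicting edge signs collapse to 0.

    A node id present in both networks must carry the same role in each
    (otherwise a validation error is raised).  Merging is commutative,
    associative and idempotent up to node/edge set equality.
    """
    out = SignedNetwork()
    for net in (a, b):
        for ent in net.entities():
            out.add_entity(ent)  # raises on role conflict
    for net in (a, b):
        for u, v, sign in net.edges():
            out.add_edge(u, v, sign)
    return out


def find_clusters(net: SignedNetwork) -> list[RegulatorCluster]:
    """One cluster per regulator with at least one compound in-neighbour.

    Members are the regulator's compound in-neighbours; a compound that
    targets several regulators belongs to several clusters.  Sorted by
    size descending, ties broken by hub id ascending.
    """
    g = net.graph
    clusters = []
    for node, data in g.nodes(data=True):
        if data["role"] != "regulator":
            continue
        members = frozenset(
            p for p in g.predecessors(node) if g.nodes[p]["role"] == "compound"
        )
        if members:
            clusters.append(
                RegulatorCluster(hub_id=node, member_compound_ids=members)
            )
    clusters.sort(key=lambda c: (-c.size, c.hub_id))
    return clusters


def trace_paths(
    net: SignedNetwork, compound_id: str, max_depth: int = 10
) -> list[PathPrediction]:
    """All simple directed paths from a compound to terminal leaves.

    A terminal leaf is any node with out-degree 0.  Paths have at least
    one edge, at most ``max_depth`` edges, and no repeated nodes; the
    output is ordered lexicographically by node sequence.  Cycles are
    handled by the simple-path restriction plus the depth cap.
    """
    g = net.graph
    if compound_id not in g:
        raise KeyError(f"unknown compound id {compound_id!r}")
    if g.nodes[compound_id]["role"] != "compound":
        raise ArgumentError(
            f"{compound_id!r} has role {g.nodes[compound_id]['role']!r}, "
            "expected 'compound'"
        )
    if max_depth < 1:
        raise ArgumentError("max_depth must be >= 1")

    results: list[PathPrediction] = []
    path = [compound_id]
    signs: list[int] = []
    on_path = {compound_id}

    def dfs(node: str) -> None:
        successors = sorted(s for s in g.successors(node) if s not in on_path)
        if g.out_degree(node) == 0 and len(path) > 1:
            results.append(
                PathPrediction(
                    compound_id=compound_id,
                    terminal_id=node,
                    node_sequence=tuple(path),
                    edge_signs=tuple(signs),
                )
            )
            return
        if len(signs) >= max_depth:
            return
        for nxt in successors:
            path.append(nxt)
            signs.append(g[node][nxt]["sign"])
            on_path.add(nxt)
            dfs(nxt)
            on_path.discard(nxt)
            signs.pop()
            path.pop()

    dfs(compound_id)
    return results


def predict_interactions(net: SignedNetwork, max_depth: int = 10) -> pd.DataFrame:
    """Aggregate sign-composed paths into compound-enzyme predictions.

    For every compound, traces all simple paths to terminal leaves and
    keeps those ending at an enzyme.  Paths to the same enzyme that
    disagree in net sign aggregate to 0 (unknown); all contributing paths
    are reported.  Returns a DataFrame with columns
    ``compound, enzyme, net_sign, n_paths, paths``.
    """
    rows = []
    for compound in sorted(net.nodes_with_role("compound")):
        by_enzyme: dict[str, list[PathPrediction]] = {}
        for pred in trace_paths(net, compound, max_depth=max_depth):
            if net.role(pred.terminal_id) == "enzyme":
                by_enzyme.setdefault(pred.terminal_id, []).append(pred)
        for enzyme in sorted(by_enzyme):
            preds = by_enzyme[enzyme]
            signs = {p.net_sign for p in preds}
            agg = signs.pop() if len(signs) == 1 else 0
            rows.append(
                {
                    "compound": compound,
                    "enzyme": enzyme,
                    "net_sign": agg,
                    "n_paths": len(preds),
                    "paths": ";".join(
                        "->".join(p.node_sequence) for p in preds
                    ),
                }
            )
    return pd.DataFrame(
        rows, columns=["compound", "enzyme", "net_sign", "n_paths", "paths"]
    )


def network_summary(net: SignedNetwork) -> dict[str, int]:
    """Node counts by role, edge count and cluster count."""
    counts = {role: len(net.nodes_with_role(role)) for role in ROLES}
    return {
        "n_compounds": counts["compound"],
        "n_regulators": counts["regulator"],
        "n_enzymes": counts["enzyme"],
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "n_clusters": len(find_clusters(net)),
    }
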