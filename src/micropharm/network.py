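"""Signed, directed microbe-microbe interaction network construction.

Two mechanisms are encoded.  Competition: the more metabolites two microbes
both consume, the stronger their mutual negative effect; its extent is the
Jaccard similarity of the two consumption sets and is symmetric.
Cross-feeding: microbe ``u`` helps microbe ``v`` when ``v`` consumes what
``u`` produces; its extent is the Jaccard similarity of ``v``'s consumption
set with ``u``'s production set and is directional.  The directed edge
``u -> v`` carries the effect OF ``u`` ON ``v``: its positive extent is
``J(C_v, P_u)``, its negative extent ``J(C_u, C_v)``, and its net weight
aggregates the two (default: their difference, in [-1, 1]).

Nodes may carry a health label: +1 commensal, -1 pathogenic, or None
(unknown).  The sign pair of the two opposing net weights types each
unordered microbe pair as competition (-,-), mutualism (+,+), commensalism
(+,0), parasitism (+,-), amensalism (-,0) or none (0,0).
"""

from __future__ import annotations

import math
from collections.abc import Callable, Iterable, Mapping
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import networkx as nx
import pandas as pd

from .profiles import MetaboliteProfile

__all__ = [
    "SignedEdge",
    "SignedNetwork",
    "RelationshipType",
    "negative_extent",
    "positive_extent",
    "aggregate_edge_weight",
    "build_network",
    "classify_relationship",
    "largest_strongly_connected_component",
    "filter_edges_by_weight",
]


def _jaccard(a: frozenset | set, b: frozenset | set) -> float:
    # 0/0 := 0 -- no shared resource means no interaction.
    if not a and not b:
        return 0.0
    inter = len(a & b)
    if inter == 0:
        return 0.0
    return inter / (len(a) + len(b) - inter)


def negative_extent(ca: Iterable[str], cb: Iterable[str]) -> float:
    """Competition extent: Jaccard similarity of two consumption sets (symmetric)."""
    return _jaccard(frozenset(ca), frozenset(cb))


def positive_extent(ca: Iterable[str], pb: Iterable[str]) -> float:
    """Cross-feeding extent of producer ``b`` on consumer ``a``: ``J(C_a, P_b)``.

    Not symmetric: a's consumption against b's production.
    """
    return _jaccard(frozenset(ca), frozenset(pb))


def aggregate_edge_weight(
    positive: float,
    negative: float,
    rule: str | Callable[[float, float], float] = "difference",
) -> float:
    """Collapse positive and negative extents into one signed weight.

    The default (and only built-in) rule is the difference
    ``positive - negative``, bounded in [-1, 1] and sign-interpretable.
    A callable may be supplied for experimentation.
    """
    for name, val in (("positive", positive), ("negative", negative)):
        if not (0.0 <= val <= 1.0) or math.isnan(val):
            raise ValueError(f"{name} extent {val!r} outside [0, 1]")
    if callable(rule):
        return rule(positive, negative)
    if rule == "difference":
        return positive - negative
    raise ValueError(f"unknown aggregation rule {rule!r}")


@dataclass(frozen=True)
class SignedEdge:
    """Directed effect of ``source`` on ``target``."""

    source: str
    target: str
    negative_extent: float
    positive_extent: float
    weight: float


class RelationshipType(Enum):
    COMPETITION = "competition"
    MUTUALISM = "mutualism"
    COMMENSALISM = "commensalism"
    PARASITISM = "parasitism"
    AMENSALISM = "amensalism"
    NONE = "none"


class SignedNetwork:
    """Directed graph over microbes with signed edges and optional +/-1 labels.

    A thin convenience wrapper around a :class:`networkx.DiGraph` whose node
    attribute ``label`` is +1, -1 or absent, and whose edge attributes are
    ``negative_extent``, ``positive_extent`` and ``weight``.
    """

    def __init__(self, graph: nx.DiGraph | None = None):
        self.graph = graph if graph is not None else nx.DiGraph()

    # -- nodes / labels ----------------------------------------------------
    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def label(self, node: str) -> int | None:
        return self.graph.nodes[node].get("label")

    @property
    def labels(self) -> dict[str, int]:
        """Mapping of every labeled node to its +/-1 label."""
        return {
            n: d["label"] for n, d in self.graph.nodes(data=True) if d.get("label") is not None
        }

    def set_labels(self, labels: Mapping[str, int]) -> None:
        for microbe, label in labels.items():
            if microbe not in self.graph:
                raise KeyError(f"label given for unknown microbe {microbe!r}")
            if label not in (1, -1):
                raise ValueError(f"label for {microbe!r} must be +1 or -1, got {label!r}")
            self.graph.nodes[microbe]["label"] = int(label)

    # -- edges -------------------------------------------------------------
    def add_edge(self, edge: SignedEdge) -> None:
        if edge.source == edge.target:
            raise ValueError("self-edges are not allowed")
        self.graph.add_edge(
            edge.source,
            edge.target,
            negative_extent=edge.negative_extent,
            positive_extent=edge.positive_extent,
            weight=edge.weight,
        )

    def edge(self, u: str, v: str) -> SignedEdge | None:
        data = self.graph.get_edge_data(u, v)
        if data is None:
            return None
        return SignedEdge(u, v, data["negative_extent"], data["positive_extent"], data["weight"])

    def weight(self, u: str, v: str, default: float = 0.0) -> float:
        data = self.graph.get_edge_data(u, v)
        return default if data is None else data["weight"]

    @property
    def edges(self) -> list[SignedEdge]:
        return [
            SignedEdge(u, v, d["negative_extent"], d["positive_extent"], d["weight"])
            for u, v, d in self.graph.edges(data=True)
        ]

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()

    def induced(self, nodes: Iterable[str]) -> "SignedNetwork":
        return SignedNetwork(self.graph.subgraph(nodes).copy())

    def copy(self) -> "SignedNetwork":
        return SignedNetwork(self.graph.copy())

    # -- IO ----------------------------------------------------------------
    def to_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, str(path))

    @classmethod
    def from_graphml(cls, path: str | Path) -> "SignedNetwork":
        graph = nx.read_graphml(str(path))
        out = nx.DiGraph()
        for node, data in graph.nodes(data=True):
            attrs = {}
            if "label" in data:
                attrs["label"] = int(data["label"])
            out.add_node(node, **attrs)
        for u, v, d in graph.edges(data=True):
            out.add_edge(
                u,
                v,
                negative_extent=float(d["negative_extent"]),
                positive_extent=float(d["positive_extent"]),
                weight=float(d["weight"]),
            )
        return cls(out)

    def to_edgelist(self, path: str | Path) -> None:
        rows = [
            {
                "source": e.source,
                "target": e.target,
                "negative_extent": e.negative_extent,
                "positive_extent": e.positive_extent,
                "weight": e.weight,
            }
            for e in self.edges
        ]
        pd.DataFrame(
            rows, columns=["source", "target", "negative_extent", "positive_extent", "weight"]
        ).to_csv(path, sep="\t", index=False)


def build_network(
    profiles: Iterable[MetaboliteProfile],
    labels: Mapping[str, int] | None = None,
    rule: str | Callable[[float, float], float] = "difference",
) -> SignedNetwork:
    """Infer the signed directed network from metabolite profiles.

    For every ordered pair ``(u, v)`` an edge is materialized iff its
    positive or negative extent is nonzero; pairs with neither shared
    consumption nor cross-feeding have no relationship and no edge.
    """
    profiles = list(profiles)
    if len(profiles) < 2:
        raise ValueError("build_network requires at least two profiles")
    ids = [p.microbe_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate microbe ids in profile collection")

    net = SignedNetwork()
    net.graph.add_nodes_from(ids)
    for pu in profiles:
        for pv in profiles:
            if pu.microbe_id == pv.microbe_id:
                continue
            neg = negative_extent(pu.consumed, pv.consumed)
            pos = positive_extent(pv.consumed, pu.produced)  # effect of u on v
            if neg == 0.0 and pos == 0.0:
                continue
            weight = aggregate_edge_weight(pos, neg, rule=rule)
            net.add_edge(SignedEdge(pu.microbe_id, pv.microbe_id, neg, pos, weight))
    if labels:
        net.set_labels(labels)
    return net


def _sign(weight: float, epsilon: float) -> int:
    if abs(weight) <= epsilon:
        return 0
    return 1 if weight > 0 else -1


def classify_relationship(
    network: SignedNetwork, u: str, v: str, epsilon: float = 0.0
) -> RelationshipType:
    """Type the unordered pair (u, v) from the sign pair of the two net weights.

    ``epsilon`` is the magnitude at or below which a net weight counts as no
    effect (default 0: exact zero / missing edge only).
    """
    if u == v:
        raise ValueError("relationship is defined for distinct microbes")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    for node in (u, v):
        if node not in network.graph:
            raise KeyError(f"microbe {node!r} not in network")
    signs = frozenset(
        (_sign(network.weight(u, v), epsilon), _sign(network.weight(v, u), epsilon))
    )
    if signs == {-1}:
        return RelationshipType.COMPETITION
    if signs == {1}:
        return RelationshipType.MUTUALISM
    if signs == {1, 0}:
        return RelationshipType.COMMENSALISM
    if signs == {1, -1}:
        return RelationshipType.PARASITISM
    if signs == {-1, 0}:
        return RelationshipType.AMENSALISM
    return RelationshipType.NONE


def largest_strongly_connected_component(network: SignedNetwork) -> SignedNetwork:
    """Induced subnetwork on the largest SCC of the nonzero-weight digraph.

    Size ties are broken toward the component containing the
    lexicographically smallest microbe id.
    """
    if network.graph.number_of_nodes() == 0:
        raise ValueError("empty network has no strongly connected component")
    skeleton = nx.DiGraph()
    skeleton.add_nodes_from(network.graph.nodes)
    skeleton.add_edges_from(
        (u, v) for u, v, d in network.graph.edges(data=True) if d["weight"] != 0.0
    )
    components = list(nx.strongly_connected_components(skeleton))
    biggest = max(len(c) for c in components)
    candidates = [c for c in components if len(c) == biggest]
    best = min(candidates, key=min)
    return network.induced(best)


def filter_edges_by_weight(
    network: SignedNetwork,
    min_weight: float | None = None,
    max_weight: float | None = None,
) -> SignedNetwork:
    """Drop edges with weight outside [min_weight, max_weight]; keep all nodes."""
    if min_weight is not None and max_weight is not None and min_weight > max_weight:
        raise ValueError("min_weight must not exceed max_weight")
    out = nx.DiGraph()
    out.add_nodes_from(network.graph.nodes(data=True))
    for u, v, d in network.graph.edges(data=True):
        if min_weight is not None and d["weight"] < min_weight:
            continue
        if max_weight is not None and d["weight"] > max_weight:
            continue
        out.add_edge(u, v, **d)
    return SignedNetwork(out)
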