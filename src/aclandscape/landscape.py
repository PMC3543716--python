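"""The Always-Correlated landscape: edges significant in every network.

Edge identity is the unordered gene pair only; the per-network correlation
values need not agree.  Each surviving edge carries the full vector of
per-network correlations, an assigned correlation taken from a designated
reference network (by default the Overall group), the sign of that value,
and a flag recording whether all networks agree on the sign.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import networkx as nx

from .types import ACEdge, ACLandscape, CorrelationNetwork

DEFAULT_REFERENCE = "Overall"

POSITIVE = "positive"
NEGATIVE = "negative"


def intersect_networks(
    networks: Sequence[CorrelationNetwork],
    reference_group: str = DEFAULT_REFERENCE,
) -> ACLandscape:
    """Intersect edge sets across all condition networks.

    The resulting landscape keeps only gene pairs significant in every
    input network; its node set is exactly the endpoints of those edges.
    """
    if not networks:
        raise ValueError("need at least one network to intersect")
    names = [n.group_name for n in networks]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate group names: {names}")
    if reference_group not in names:
        raise ValueError(
            f"reference group {reference_group!r} not among inputs {names}"
        )
    by_name = {n.group_name: n for n in networks}
    common = set(networks[0].edges)
    for net in networks[1:]:
        common &= set(net.edges)
    edges: dict = {}
    for pair in common:
        per = {name: by_name[name].edges[pair] for name in names}
        assigned = per[reference_group]
        signs = {w > 0 for w in per.values() if w != 0}
        edges[pair] = ACEdge(
            per_network_r=per,
            assigned_r=assigned,
            sign=POSITIVE if assigned > 0 else NEGATIVE,
            sign_consistent=len(signs) <= 1 and all(w != 0 for w in per.values()),
        )
    nodes = {g for pair in edges for g in pair}
    return ACLandscape(
        nodes=nodes,
        edges=edges,
        source_groups=tuple(names),
        reference_group=reference_group,
    )


def to_graph(landscape: ACLandscape) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(landscape.nodes)
    for (a, b), edge in landscape.edges.items():
        g.add_edge(a, b, weight=edge.assigned_r)
    return g


def components(landscape: ACLandscape) -> list[set[str]]:
    """Connected components, largest first; ties by smallest gene ID."""
    comps = list(nx.connected_components(to_graph(landscape)))
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def _pct(count: int, total: int) -> float:
    """Percentage with one decimal, round half up (26.328 -> 26.3)."""
    if total == 0:
        return 0.0
    pct = Decimal(count) * 100 / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class ComponentReport:
    component_sizes: list[int]
    edge_count: int
    negative_edges: int
    negative_pct: float
    positive_edges: int
    positive_pct: float

    def to_dict(self) -> dict:
        return {
            "component_sizes": self.component_sizes,
            "n_components": len(self.component_sizes),
            "edge_count": self.edge_count,
            "negative_edges": self.negative_edges,
            "negative_pct": self.negative_pct,
            "positive_edges": self.positive_edges,
            "positive_pct": self.positive_pct,
        }


def sign_report(landscape: ACLandscape) -> ComponentReport:
    """Edge-sign composition and component sizes of a landscape."""
    neg = sum(1 for e in landscape.edges.values() if e.sign == NEGATIVE)
    pos = len(landscape.edges) - neg
    total = len(landscape.edges)
    sizes = [len(c) for c in components(landscape)]
    return ComponentReport(
        component_sizes=sizes,
        edge_count=total,
        negative_edges=neg,
        negative_pct=_pct(neg, total),
        positive_edges=pos,
        positive_pct=_pct(pos, total),
    )


def landscape_from_edge_signs(
    signed_edges: Iterable[tuple[str, str, float]],
    group_name: str = "assigned",
) -> ACLandscape:
    """Build a one-network landscape directly from (a, b, r) triples.

    Convenience for sign/component reporting on an edge list that did not
    come from a fresh intersection (e.g. published edge counts).
    """
    from .types import ordered_pair

    edges = {}
    for a, b, r in signed_edges:
        pair = ordered_pair(a, b)
        edges[pair] = ACEdge(
            per_network_r={group_name: r},
            assigned_r=r,
            sign=POSITIVE if r > 0 else NEGATIVE,
            sign_consistent=True,
        )
    nodes = {g for pair in edges for g in pair}
    return ACLandscape(nodes, edges, (group_name,), group_name)
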