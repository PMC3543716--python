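"""MCODE-style dense-module detection with a correlation cut-off sweep.

Vertex weighting: weight(v) = k_max * density of the highest-k-core
subgraph of v's closed neighborhood, where k_max is that subgraph's core
index.  Seeded expansion: unvisited vertices are seeded in decreasing
weight order (ties: smallest gene ID) and grown breadth-first, admitting a
neighbor when its weight is at least seed_weight * (1 - vwp); every vertex
joins at most one module.  Post-processing: haircut iteratively removes
vertices with fewer than two neighbours inside the module (the module's
2-core); fluff optionally adds boundary neighbours whose closed
neighbourhood is denser than fluff_density.  A module's score is its
density times its size.

The sweep applies the detection at a decreasing grid of |r| cut-offs,
tracks module lineages across adjacent cut-offs by best Jaccard overlap,
and selects for each lineage the cut-off giving the largest module among
those reached before the module's connectivity into the surrounding
network jumps (boundary/internal edge ratio growing by at least
jump_factor between adjacent cut-offs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx

from .landscape import to_graph
from .types import ACLandscape


@dataclass(frozen=True)
class MCODEParams:
    vwp: float = 0.2  # vertex weight percentage
    haircut: bool = True
    fluff: bool = False
    fluff_density: float = 0.5
    max_depth: int = 100

    def __post_init__(self) -> None:
        if not 0.0 <= self.vwp <= 1.0:
            raise ValueError(f"vwp outside [0, 1]: {self.vwp}")
        if not 0.0 <= self.fluff_density <= 1.0:
            raise ValueError(f"fluff_density outside [0, 1]: {self.fluff_density}")
        if self.max_depth < 1:
            raise ValueError(f"max_depth < 1: {self.max_depth}")


@dataclass
class Module:
    genes: frozenset[str]
    cutoff: float | None
    score: float
    internal_edges: int
    boundary_edges: int

    @property
    def size(self) -> int:
        return len(self.genes)

    @property
    def connectivity_ratio(self) -> float:
        if self.internal_edges == 0:
            return math.inf
        return self.boundary_edges / self.internal_edges


def apply_cutoff(landscape: ACLandscape, cutoff: float | None) -> nx.Graph:
    """Graph of edges with |assigned_r| strictly above the cut-off.

    ``cutoff=None`` keeps every edge.  Nodes left isolated are dropped.
    """
    if cutoff is not None and not 0.0 <= cutoff < 1.0:
        raise ValueError(f"cutoff outside [0, 1): {cutoff}")
    g = nx.Graph()
    for (a, b), edge in landscape.edges.items():
        if cutoff is None or abs(edge.assigned_r) > cutoff:
            g.add_edge(a, b, weight=edge.assigned_r)
    return g


def core_numbers(graph: nx.Graph) -> dict[str, int]:
    """k-core index of every vertex (iterative peeling)."""
    if graph.number_of_nodes() == 0:
        return {}
    return nx.core_number(graph)


def _density(n_nodes: int, n_edges: int) -> float:
    if n_nodes < 2:
        return 0.0
    return 2.0 * n_edges / (n_nodes * (n_nodes - 1))


def mcode_vertex_weights(graph: nx.Graph) -> dict[str, float]:
    """Core-weighted local density for every vertex."""
    weights: dict[str, float] = {}
    for v in graph.nodes:
        nbhd = set(graph.adj[v]) | {v}
        if len(nbhd) == 1:
            weights[v] = 0.0
            continue
        sub = graph.subgraph(nbhd)
        cores = nx.core_number(sub)
        k_max = max(cores.values())
        core_nodes = [u for u, k in cores.items() if k >= k_max]
        core_sub = sub.subgraph(core_nodes)
        weights[v] = k_max * _density(
            core_sub.number_of_nodes(), core_sub.number_of_edges()
        )
    return weights


def _expand_from_seed(
    graph: nx.Graph,
    seed: str,
    weights: dict[str, float],
    visited: set[str],
    params: MCODEParams,
) -> set[str]:
    """Breadth-first growth from a seed.

    A candidate neighbour joins when its weight is within vwp of the seed's
    weight and, once the module has at least two members, it is adjacent to
    at least two of them.  The connectivity guard keeps a single bridge
    edge between two dense cores from chaining them into one module.
    """
    threshold = weights[seed] * (1.0 - params.vwp)
    module = {seed}
    frontier = [seed]
    depth = 0
    while frontier and depth < params.max_depth:
        candidates = sorted(
            {
                w
                for u in frontier
                for w in graph.adj[u]
                if w not in visited and w not in module
            },
            key=lambda v: (-weights[v], v),
        )
        nxt = []
        for w in candidates:
            if weights[w] < threshold:
                continue
            if len(module) >= 2:
                links = sum(1 for u in graph.adj[w] if u in module)
                if links < 2:
                    continue
            module.add(w)
            nxt.append(w)
        frontier = nxt
        depth += 1
    return module


def _haircut(graph: nx.Graph, module: set[str]) -> set[str]:
    # iterate to the 2-core of the module subgraph
    mod = set(module)
    while True:
        sub = graph.subgraph(mod)
        drop = [v for v in mod if sub.degree(v) < 2]
        if not drop:
            return mod
        mod -= set(drop)
        if not mod:
            return mod


def _fluff(
    graph: nx.Graph, module: set[str], weights: dict[str, float], params: MCODEParams
) -> set[str]:
    extra = set()
    for v in module:
        for w in graph.adj[v]:
            if w in module or w in extra:
                continue
            nbhd = set(graph.adj[w]) | {w}
            sub = graph.subgraph(nbhd)
            if _density(sub.number_of_nodes(), sub.number_of_edges()) > (
                params.fluff_density
            ):
                extra.add(w)
    return module | extra


def _finalize(graph: nx.Graph, genes: set[str], cutoff: float | None) -> Module:
    sub = graph.subgraph(genes)
    internal = sub.number_of_edges()
    boundary = sum(
        1 for v in genes for w in graph.adj[v] if w not in genes
    )
    return Module(
        genes=frozenset(genes),
        cutoff=cutoff,
        score=_density(len(genes), internal) * len(genes),
        internal_edges=internal,
        boundary_edges=boundary,
    )


def mcode_find_modules(
    graph: nx.Graph,
    params: MCODEParams = MCODEParams(),
    cutoff: float | None = None,
) -> list[Module]:
    """Seeded-expansion module detection on an unweighted graph.

    Returns modules of size >= 2 sorted by decreasing score (ties by
    smallest gene ID).  Before fluff, modules are vertex-disjoint.
    """
    weights = mcode_vertex_weights(graph)
    seeds = sorted(graph.nodes, key=lambda v: (-weights[v], v))
    visited: set[str] = set()
    modules: list[Module] = []
    for seed in seeds:
        if seed in visited:
            continue
        module = _expand_from_seed(graph, seed, weights, visited, params)
        if params.haircut:
            # vertices trimmed by the haircut never joined a module and
            # stay available for later seeds
            module = _haircut(graph, module)
        if len(module) < 2:
            continue
        visited |= module
        if params.fluff:
            module = _fluff(graph, module, weights, params)
        modules.append(_finalize(graph, module, cutoff))
    return sorted(modules, key=lambda m: (-m.score, min(m.genes)))


def jaccard(a: frozenset[str] | set[str], b: frozenset[str] | set[str]) -> float:
    if not a and not b:
        return 1.0
    return len(set(a) & set(b)) / len(set(a) | set(b))


@dataclass
class Lineage:
    """One module tracked across the cut-off grid."""

    lineage_id: int
    history: dict[float | None, Module] = field(default_factory=dict)
    chosen_cutoff: float | None = None
    choice_made: bool = False

    @property
    def chosen_module(self) -> Module | None:
        if not self.choice_made:
            return None
        return self.history.get(self.chosen_cutoff)


@dataclass
class SweepResult:
    cutoffs: list[float | None]
    lineages: list[Lineage]
    modules_per_cutoff: dict[float | None, list[Module]]

    def table(self) -> list[dict]:
        """Module-lineage x cut-off size table (long form)."""
        rows = []
        for lin in self.lineages:
            for cutoff, module in lin.history.items():
                rows.append(
                    {
                        "lineage": lin.lineage_id,
                        "cutoff": cutoff,
                        "size": module.size,
                        "connectivity_ratio": module.connectivity_ratio,
                        "chosen": lin.choice_made and cutoff == lin.chosen_cutoff,
                    }
                )
        return rows


JACCARD_TRACK_THRESHOLD = 0.3


def _choose_cutoff(
    lin: Lineage, grid: list[float | None], jump_factor: float
) -> float | None:
    """Largest module among cut-offs reached before a connectivity jump."""
    seen = [c for c in grid if c in lin.history]
    eligible: list[float | None] = []
    prev_ratio: float | None = None
    for c in seen:
        ratio = lin.history[c].connectivity_ratio
        if prev_ratio is None:
            jumped = False
        elif prev_ratio == 0.0:
            jumped = ratio > 0.0
        elif math.isinf(prev_ratio):
            jumped = False
        else:
            jumped = ratio / prev_ratio >= jump_factor
        if not jumped:
            eligible.append(c)
        prev_ratio = ratio
    if not eligible:
        return seen[0] if seen else None
    # ties on size resolve toward the most relaxed cut-off
    return max(eligible, key=lambda c: (lin.history[c].size, grid.index(c)))


def sweep(
    landscape: ACLandscape,
    cutoffs: list[float | None],
    params: MCODEParams = MCODEParams(),
    jump_factor: float = 2.0,
) -> SweepResult:
    """Cut-off sweep with lineage tracking and per-lineage cut-off choice.

    ``cutoffs`` must be sorted from strictest (largest) to most relaxed;
    ``None`` (no cut-off) belongs last.
    """
    numeric = [c for c in cutoffs if c is not None]
    if numeric != sorted(numeric, reverse=True):
        raise ValueError("cutoffs must be sorted decreasing")
    if None in cutoffs and cutoffs[-1] is not None:
        raise ValueError("the no-cutoff entry (None) must come last")

    modules_per_cutoff: dict[float | None, list[Module]] = {}
    lineages: list[Lineage] = []
    prev_assignment: dict[int, Module] = {}  # lineage id -> module at prev cutoff
    for cutoff in cutoffs:
        graph = apply_cutoff(landscape, cutoff)
        modules = mcode_find_modules(graph, params, cutoff)
        modules_per_cutoff[cutoff] = modules
        # greedy best-Jaccard matching against the previous cutoff's modules
        candidates = []
        for mi, module in enumerate(modules):
            for lid, prev_mod in prev_assignment.items():
                j = jaccard(module.genes, prev_mod.genes)
                if j >= JACCARD_TRACK_THRESHOLD:
                    candidates.append((-j, mi, lid))
        candidates.sort()
        matched_modules: set[int] = set()
        matched_lineages: set[int] = set()
        assignment: dict[int, Module] = {}
        for negj, mi, lid in candidates:
            if mi in matched_modules or lid in matched_lineages:
                continue
            matched_modules.add(mi)
            matched_lineages.add(lid)
            lineages[lid].history[cutoff] = modules[mi]
            assignment[lid] = modules[mi]
        for mi, module in enumerate(modules):
            if mi in matched_modules:
                continue
            lid = len(lineages)
            lin = Lineage(lineage_id=lid)
            lin.history[cutoff] = module
            lineages.append(lin)
            assignment[lid] = module
        prev_assignment = assignment

    if len(cutoffs) >= 2:
        for lin in lineages:
            lin.chosen_cutoff = _choose_cutoff(lin, cutoffs, jump_factor)
            lin.choice_made = True
    return SweepResult(
        cutoffs=list(cutoffs), lineages=lineages, modules_per_cutoff=modules_per_cutoff
    )
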