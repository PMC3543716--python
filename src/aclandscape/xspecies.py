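"""Cross-platform / cross-species comparison of two AC landscapes.

Comparability is limited to genes confidently linked 1:1 between the two
platforms (the mapping universe): a symbol annotated confidently on both
sides, with exactly one candidate probe/gene per side, contributes one
mapped pair.  Node overlap is scored with the hypergeometric upper-tail
test inside that universe; an edge is shared when its mapped unordered
gene pair is an edge in both landscapes (sign agreement is reported, not
required); per paired module, the gene composition splits into a-only /
both / b-only counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .enrichment import hypergeom_upper_tail
from .types import ACLandscape, IdMapping, ordered_pair
from .preprocess import CONFIDENT


def build_mapping(annot_a: pd.DataFrame, annot_b: pd.DataFrame) -> IdMapping:
    """Confident 1:1 gene map from two annotation tables.

    Each table needs columns gene_id, symbol and (optionally) status; rows
    with status other than "confident" are ignored.  A symbol carried by
    more than one gene on either side is a conflict: it is dropped and
    recorded in ``dropped_conflicts``.
    """

    def confident_symbols(t: pd.DataFrame) -> pd.DataFrame:
        for col in ("gene_id", "symbol"):
            if col not in t.columns:
                raise ValueError(f"annotation table missing column {col!r}")
        if "status" in t.columns:
            t = t[t["status"] == CONFIDENT]
        return t[t["symbol"].astype(bool)]

    a = confident_symbols(annot_a)
    b = confident_symbols(annot_b)
    dup_a = set(a.loc[a["symbol"].duplicated(keep=False), "symbol"])
    dup_b = set(b.loc[b["symbol"].duplicated(keep=False), "symbol"])
    shared = set(a["symbol"]) & set(b["symbol"])
    conflicts = sorted((dup_a | dup_b) & shared)
    usable = shared - set(conflicts)
    map_a = a.set_index("symbol")["gene_id"]
    map_b = b.set_index("symbol")["gene_id"]
    pairs = {map_a[s]: map_b[s] for s in sorted(usable)}
    return IdMapping(pairs, tuple(conflicts))


@dataclass
class ModuleOverlapRow:
    module_a: str
    module_b: str
    a_only: int
    both: int
    b_only: int


@dataclass
class LandscapeComparison:
    universe_size: int
    nodes_a_in_universe: int
    nodes_b_in_universe: int
    nodes_shared: int
    nodes_a_only: int
    nodes_b_only: int
    node_overlap_expected: float
    node_overlap_p: float
    shared_edges: int
    shared_edges_sign_agree: int
    module_rows: list[ModuleOverlapRow] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "universe_size": self.universe_size,
            "nodes_a_in_universe": self.nodes_a_in_universe,
            "nodes_b_in_universe": self.nodes_b_in_universe,
            "nodes_shared": self.nodes_shared,
            "nodes_a_only": self.nodes_a_only,
            "nodes_b_only": self.nodes_b_only,
            "node_overlap_expected": self.node_overlap_expected,
            "node_overlap_p": self.node_overlap_p,
            "shared_edges": self.shared_edges,
            "shared_edges_sign_agree": self.shared_edges_sign_agree,
            "modules": [
                {
                    "module_a": r.module_a,
                    "module_b": r.module_b,
                    "a_only": r.a_only,
                    "both": r.both,
                    "b_only": r.b_only,
                }
                for r in self.module_rows
            ],
        }


def compare_landscapes(
    land_a: ACLandscape,
    land_b: ACLandscape,
    mapping: IdMapping,
    modules_a: dict[str, set[str]] | None = None,
    modules_b: dict[str, set[str]] | None = None,
    module_pairing: list[tuple[str, str]] | None = None,
) -> LandscapeComparison:
    """Node, edge and per-module composition overlap of two landscapes
    inside the confident mapping universe."""
    if mapping.universe_size == 0:
        raise ValueError("empty ID mapping")
    fwd = dict(mapping.pairs)
    universe_a = set(fwd)
    universe_b = set(fwd.values())

    a_nodes = land_a.nodes & universe_a
    b_nodes = land_b.nodes & universe_b
    mapped_a = {fwd[g] for g in a_nodes}
    shared_nodes = mapped_a & b_nodes
    n_shared = len(shared_nodes)
    N = mapping.universe_size
    expected = len(a_nodes) * len(b_nodes) / N if N else 0.0
    p = hypergeom_upper_tail(n_shared, len(a_nodes), len(b_nodes), N)

    shared_edges = 0
    sign_agree = 0
    for (a1, a2), edge in land_a.edges.items():
        if a1 not in fwd or a2 not in fwd:
            continue
        pair_b = ordered_pair(fwd[a1], fwd[a2])
        other = land_b.edges.get(pair_b)
        if other is None:
            continue
        shared_edges += 1
        if edge.sign == other.sign:
            sign_agree += 1

    module_rows: list[ModuleOverlapRow] = []
    if module_pairing:
        modules_a = modules_a or {}
        modules_b = modules_b or {}
        unpaired = [
            (ma, mb)
            for ma, mb in module_pairing
            if ma not in modules_a or mb not in modules_b
        ]
        if unpaired:
            raise KeyError(f"unpaired module IDs: {unpaired}")
        for ma, mb in module_pairing:
            ga = modules_a[ma] & universe_a
            gb = modules_b[mb] & universe_b
            mapped_ga = {fwd[g] for g in ga}
            both = len(mapped_ga & gb)
            module_rows.append(
                ModuleOverlapRow(
                    module_a=ma,
                    module_b=mb,
                    a_only=len(ga) - both,
                    both=both,
                    b_only=len(gb) - both,
                )
            )

    return LandscapeComparison(
        universe_size=N,
        nodes_a_in_universe=len(a_nodes),
        nodes_b_in_universe=len(b_nodes),
        nodes_shared=n_shared,
        nodes_a_only=len(a_nodes) - n_shared,
        nodes_b_only=len(b_nodes) - n_shared,
        node_overlap_expected=expected,
        node_overlap_p=p,
        shared_edges=shared_edges,
        shared_edges_sign_agree=sign_agree,
        module_rows=module_rows,
    )
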