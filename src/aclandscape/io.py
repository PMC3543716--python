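"""Plain-text readers and writers for every pipeline artifact.

Formats: expression and detection matrices as TSV (first column gene ID,
header row of sample IDs); sample groups as a two-column TSV; probe
annotation as CSV; TF catalogs as one-column TSV; gene sets as GMT;
networks as edge-list TSV (gene_a < gene_b) and SIF plus an
edge-attribute TSV; reports as JSON.  Every writer round-trips through
its reader.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

from .enrichment import GeneSet, GeneSetCollection
from .preprocess import ProbeAnnotation
from .regulators import RegulatorCatalog
from .synthetic import GroundTruth
from .types import (
    ACEdge,
    ACLandscape,
    CorrelationNetwork,
    ExpressionMatrix,
    IdMapping,
    ordered_pair,
)


# -- expression ---------------------------------------------------------------

def write_expression(expr: ExpressionMatrix, values_path, detection_path,
                     groups_path=None) -> None:
    expr.values.to_csv(values_path, sep="\t", index_label="gene_id")
    expr.detection.to_csv(detection_path, sep="\t", index_label="gene_id")
    if groups_path is not None:
        write_groups(expr.sample_group, groups_path)


def read_expression(values_path, detection_path, groups_path=None,
                    log2_transform: bool = False) -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.index.name = None
    if log2_transform:
        import numpy as np

        values = np.log2(values + 1.0)
    detection = pd.read_csv(detection_path, sep="\t", index_col=0)
    detection.index = detection.index.astype(str)
    detection.index.name = None
    sample_group = read_groups(groups_path) if groups_path is not None else {}
    return ExpressionMatrix(values, detection, sample_group)


def write_groups(sample_group: dict[str, str], path) -> None:
    pd.DataFrame(
        {"sample": list(sample_group), "group": list(sample_group.values())}
    ).to_csv(path, sep="\t", index=False)


def read_groups(path) -> dict[str, str]:
    t = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(t["sample"], t["group"]))


# -- annotation / catalogs / gene sets ---------------------------------------

def write_annotation(annot: ProbeAnnotation, path) -> None:
    annot.table.to_csv(path, index=False)


def read_annotation(path) -> ProbeAnnotation:
    t = pd.read_csv(path, dtype=str).fillna("")
    return ProbeAnnotation(t)


def write_tf_catalog(catalog: RegulatorCatalog, path) -> None:
    Path(path).write_text("".join(f"{t}\n" for t in sorted(catalog.tf_ids)))


def read_tf_catalog(path) -> RegulatorCatalog:
    ids = [line.strip() for line in Path(path).read_text().splitlines()]
    return RegulatorCatalog(frozenset(i for i in ids if i))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for tid in sorted(collection.sets):
            gs = collection.sets[tid]
            genes = "\t".join(sorted(gs.genes))
            fh.write(f"{gs.term_id}\t{gs.term_name}\t{genes}\n")


def read_gmt(path) -> GeneSetCollection:
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        tid, name, genes = parts[0], parts[1], parts[2:]
        sets[tid] = GeneSet(tid, name, frozenset(g for g in genes if g))
    return GeneSetCollection(sets)


# -- networks and landscapes --------------------------------------------------

def write_edge_list(network: CorrelationNetwork, path) -> None:
    rows = [
        {"gene_a": a, "gene_b": b, "r": r}
        for (a, b), r in sorted(network.edges.items())
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "r"]).to_csv(
        path, sep="\t", index=False
    )


def read_edge_list(path, group_name: str) -> CorrelationNetwork:
    t = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    edges = {
        ordered_pair(a, b): float(r)
        for a, b, r in zip(t["gene_a"], t["gene_b"], t["r"])
    }
    nodes = {g for pair in edges for g in pair}
    return CorrelationNetwork(group_name, nodes, edges)


def write_sif(landscape: ACLandscape, path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(landscape.edges):
            fh.write(f"{a}\tpp\t{b}\n")


def write_edge_attributes(landscape: ACLandscape, path) -> None:
    groups = list(landscape.source_groups)
    rows = []
    for (a, b), e in sorted(landscape.edges.items()):
        row = {"gene_a": a, "gene_b": b}
        for g in groups:
            row[f"r_{g}"] = e.per_network_r[g]
        row.update(
            assigned_r=e.assigned_r, sign=e.sign, sign_consistent=e.sign_consistent
        )
        rows.append(row)
    cols = ["gene_a", "gene_b", *(f"r_{g}" for g in groups), "assigned_r",
            "sign", "sign_consistent"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_edge_attributes(path, reference_group: str) -> ACLandscape:
    t = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    groups = [c[2:] for c in t.columns if c.startswith("r_")]
    edges = {}
    for _, row in t.iterrows():
        pair = ordered_pair(row["gene_a"], row["gene_b"])
        per = {g: float(row[f"r_{g}"]) for g in groups}
        edges[pair] = ACEdge(
            per_network_r=per,
            assigned_r=float(row["assigned_r"]),
            sign=str(row["sign"]),
            sign_consistent=bool(row["sign_consistent"]),
        )
    nodes = {g for pair in edges for g in pair}
    return ACLandscape(nodes, edges, tuple(groups), reference_group)


def write_mapping(mapping: IdMapping, path) -> None:
    pd.DataFrame(
        {"gene_a": list(mapping.pairs), "gene_b": list(mapping.pairs.values())}
    ).to_csv(path, sep="\t", index=False)


def read_mapping(path) -> IdMapping:
    t = pd.read_csv(path, sep="\t", dtype=str)
    return IdMapping(dict(zip(t["gene_a"], t["gene_b"])))


# -- ground truth and reports -------------------------------------------------

def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "module_membership": truth.module_membership,
        "always_pairs": sorted(list(p) for p in truth.always_pairs),
        "conditional_pairs": sorted(list(p) for p in truth.conditional_pairs),
        "flat_genes": sorted(truth.flat_genes),
        "regulator_map": truth.regulator_map,
        "loadings": truth.loadings,
        "module_active_groups": {
            str(k): list(v) for k, v in truth.module_active_groups.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_ground_truth(path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(
        module_membership={g: int(m) for g, m in d["module_membership"].items()},
        always_pairs={tuple(p) for p in d["always_pairs"]},
        conditional_pairs={tuple(p) for p in d["conditional_pairs"]},
        flat_genes=set(d["flat_genes"]),
        regulator_map={g: int(m) for g, m in d["regulator_map"].items()},
        loadings={g: float(v) for g, v in d.get("loadings", {}).items()},
        module_active_groups={
            int(k): tuple(v) for k, v in d.get("module_active_groups", {}).items()
        },
    )


def write_json(payload: dict, path) -> None:
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def write_yaml(payload: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def write_module_genes(modules: dict[str, Iterable[str]], path) -> None:
    rows = [
        {"module": mid, "gene": g}
        for mid in sorted(modules)
        for g in sorted(modules[mid])
    ]
    pd.DataFrame(rows, columns=["module", "gene"]).to_csv(path, sep="\t", index=False)


def read_module_genes(path) -> dict[str, set[str]]:
    t = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, set[str]] = {}
    for mid, g in zip(t["module"], t["gene"]):
        out.setdefault(mid, set()).add(g)
    return out
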