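"""End-to-end orchestration: filters -> per-group PCIT -> AC landscape ->
module sweep -> enrichment -> regulators, with a JSON run report.

Analysis groups are defined as unions of the base sample groups in the
group table; the Overall group ("*") contains every sample.  All stage
parameters and paths live in :class:`PipelineConfig`, which can be read
from / written to YAML.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__, io, mcode, pcit, preprocess, regulators
from .enrichment import enrich
from .landscape import intersect_networks, sign_report
from .types import ExpressionMatrix, SampleGroup

log = logging.getLogger("aclandscape")

ALL_SAMPLES = "*"

DEFAULT_ANALYSIS_GROUPS = {
    "Callipyge": ["Callipyge"],
    "Normal": ["Normal"],
    "Prenatal": ["Prenatal"],
    "Postnatal": ["Postnatal"],
    "HighLow": ["HighLow"],
    "Overall": [ALL_SAMPLES],
}

DEFAULT_CUTOFFS: list[float | None] = [0.95, 0.9, 0.85, 0.8, 0.7, None]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    expression: str = ""
    flags: str = ""
    groups: str = ""
    annotation: str | None = None
    tf_list: str | None = None
    gmt: str | None = None
    analysis_groups: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_ANALYSIS_GROUPS.items()}
    )
    reference_group: str = "Overall"
    k_sd: float = 1.0
    sd_mode: str = "global_sd"
    min_timepoints: int = 1
    log2_transform: bool = False
    ratio_mode: str = "signed"
    cutoffs: list[float | None] = field(default_factory=lambda: list(DEFAULT_CUTOFFS))
    vwp: float = 0.2
    haircut: bool = True
    fluff: bool = False
    fluff_density: float = 0.5
    max_depth: int = 100
    jump_factor: float = 2.0
    correction: str = "BH"
    top_n: int = 10
    seed: int = 0
    out_dir: str = "results/pipeline"

    def mcode_params(self) -> mcode.MCODEParams:
        return mcode.MCODEParams(
            vwp=self.vwp,
            haircut=self.haircut,
            fluff=self.fluff,
            fluff_density=self.fluff_density,
            max_depth=self.max_depth,
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = io.read_yaml(path)
        if "cutoffs" in d:
            d["cutoffs"] = [None if c in (None, "none") else float(c) for c in d["cutoffs"]]
        return cls(**d)

    def to_yaml(self, path) -> None:
        d = dict(self.__dict__)
        d["cutoffs"] = ["none" if c is None else c for c in self.cutoffs]
        io.write_yaml(d, path)


def resolve_analysis_groups(
    expr: ExpressionMatrix, analysis_groups: dict[str, list[str]]
) -> list[SampleGroup]:
    """Expand base-group unions into ordered sample lists."""
    base: dict[str, list[str]] = {}
    for s in expr.sample_ids:
        base.setdefault(expr.sample_group.get(s, ""), []).append(s)
    out = []
    for name, members in analysis_groups.items():
        if ALL_SAMPLES in members:
            samples = list(expr.sample_ids)
        else:
            unknown = [m for m in members if m not in base]
            if unknown:
                raise KeyError(f"analysis group {name}: unknown base groups {unknown}")
            samples = [s for m in members for s in base[m]]
        out.append(SampleGroup(name, tuple(samples)))
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write artifacts under ``config.out_dir``.

    Returns the run report (also written as report.json): per-stage gene
    and edge counts, landscape sign composition, chosen modules,
    enrichment and regulator summaries, version, seed and parameter echo.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "k_sd": config.k_sd,
            "sd_mode": config.sd_mode,
            "min_timepoints": config.min_timepoints,
            "ratio_mode": config.ratio_mode,
            "cutoffs": ["none" if c is None else c for c in config.cutoffs],
            "vwp": config.vwp,
            "haircut": config.haircut,
            "fluff": config.fluff,
            "jump_factor": config.jump_factor,
            "reference_group": config.reference_group,
            "correction": config.correction,
            "top_n": config.top_n,
        },
    }

    try:
        expr = io.read_expression(
            config.expression, config.flags, config.groups,
            log2_transform=config.log2_transform,
        )
        if config.annotation:
            annot = io.read_annotation(config.annotation)
            expr = preprocess.drop_dubious_probes(expr, annot)
            expr = preprocess.collapse_to_genes(expr, annot)
        report["input"] = {
            "n_rows": len(expr.row_ids),
            "n_samples": len(expr.sample_ids),
        }
        groups = resolve_analysis_groups(expr, config.analysis_groups)
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001 - stage boundary
        raise StageError("preprocess", e) from e

    networks = []
    per_group = {}
    overall_expr = None
    try:
        for group in groups:
            filtered = preprocess.preprocess_group(
                expr, group, config.k_sd, config.sd_mode, config.min_timepoints
            )
            log.info("group %s: %d genes survive filters", group.name,
                     len(filtered.row_ids))
            net = pcit.build_network(filtered, group, config.ratio_mode)
            per_group[group.name] = {
                "n_samples": len(group.sample_ids),
                "n_genes": len(filtered.row_ids),
                "n_edges": len(net.edges),
            }
            io.write_edge_list(net, out / f"edges_{group.name}.tsv")
            networks.append(net)
            if group.name == config.reference_group:
                overall_expr = filtered
        report["groups"] = per_group
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("pcit", e) from e

    try:
        land = intersect_networks(networks, config.reference_group)
        rep = sign_report(land)
        io.write_sif(land, out / "landscape.sif")
        io.write_edge_attributes(land, out / "landscape_edges.tsv")
        io.write_json(rep.to_dict(), out / "landscape_report.json")
        report["landscape"] = {
            "n_nodes": len(land.nodes),
            "n_edges": len(land.edges),
            **rep.to_dict(),
        }
    except Exception as e:  # noqa: BLE001
        raise StageError("landscape", e) from e

    try:
        result = mcode.sweep(
            land, config.cutoffs, config.mcode_params(), config.jump_factor
        )
        chosen = {
            f"M{lin.lineage_id}": set(lin.chosen_module.genes)
            for lin in result.lineages
            if lin.chosen_module is not None
        }
        io.write_module_genes(chosen, out / "modules.tsv")
        import pandas as pd

        pd.DataFrame(result.table()).to_csv(out / "sweep.tsv", sep="\t", index=False)
        report["modules"] = {
            mid: len(genes) for mid, genes in sorted(chosen.items())
        }
    except Exception as e:  # noqa: BLE001
        raise StageError("modules", e) from e

    if config.gmt:
        try:
            collection = io.read_gmt(config.gmt)
            universe = set(land.nodes)
            enr_rows = []
            for mid, genes in sorted(chosen.items()):
                for r in enrich(genes & universe, universe, collection,
                                config.correction):
                    enr_rows.append(
                        {"module": mid, "term_id": r.term_id, "term": r.term_name,
                         "k": r.k, "K": r.K, "n": r.n, "N": r.N,
                         "p": r.p, "p_adj": r.p_adj}
                    )
            import pandas as pd

            pd.DataFrame(
                enr_rows,
                columns=["module", "term_id", "term", "k", "K", "n", "N", "p", "p_adj"],
            ).to_csv(out / "enrichment.tsv", sep="\t", index=False)
            report["enrichment"] = {
                mid: min(
                    (r["p"] for r in enr_rows if r["module"] == mid), default=None
                )
                for mid in chosen
            }
        except Exception as e:  # noqa: BLE001
            raise StageError("enrichment", e) from e

    if config.tf_list:
        try:
            catalog = io.read_tf_catalog(config.tf_list)
            if overall_expr is None:
                raise ValueError(
                    f"reference group {config.reference_group!r} missing from groups"
                )
            ref_group = next(
                g for g in groups if g.name == config.reference_group
            )
            corr = pcit.correlation_matrix(overall_expr, ref_group)
            per_module_scores = {}
            for mid, genes in sorted(chosen.items()):
                in_matrix = genes & set(corr.gene_ids)
                if not in_matrix:
                    continue
                scores, _ = regulators.module_to_regulator(
                    corr, in_matrix, catalog, module_id=mid,
                    top_n=config.top_n, landscape=land,
                )
                per_module_scores[mid] = scores
            rows = regulators.regulator_table(per_module_scores, chosen, catalog)
            import pandas as pd

            pd.DataFrame(
                [
                    {
                        "module": r.module_id,
                        "in_module_and_top": ",".join(r.in_module_and_top),
                        "in_module_only": ",".join(r.in_module_only),
                        "top_only": ",".join(r.top_only),
                    }
                    for r in rows
                ]
            ).to_csv(out / "regulators.tsv", sep="\t", index=False)
            report["regulators"] = {
                r.module_id: {
                    "in_module_and_top": r.in_module_and_top,
                    "top_only": r.top_only,
                }
                for r in rows
            }
        except StageError:
            raise
        except Exception as e:  # noqa: BLE001
            raise StageError("regulators", e) from e

    io.write_json(report, out / "report.json")
    return report
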