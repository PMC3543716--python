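"""Module-to-Regulator analysis.

Transcription factors are ranked for each module by their mean absolute
Pearson correlation to the module's genes, taken from the Overall
network's correlation matrix (not restricted to PCIT-significant pairs).
The TF itself is always excluded from its own average, so a TF that is a
module member never scores from its self-correlation.  Alternative
statistics (mean signed r; restriction to PCIT-kept pairs) are available
via ``statistic`` / ``mask``.

The cross-tabulation partitions, per module, the union of module TFs and
top-ranked TFs into three disjoint columns: in the module and top-ranked,
in the module only, and top-ranked only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import ACLandscape, CorrelationMatrix, SignificanceMask


@dataclass(frozen=True)
class RegulatorCatalog:
    """The set of genes treated as transcription factors."""

    tf_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.tf_ids:
            raise ValueError("empty TF catalog")


@dataclass
class RegulatorScore:
    tf_id: str
    module_id: str
    score: float
    rank: int
    in_module: bool
    in_landscape: bool


def module_to_regulator(
    corr_overall: CorrelationMatrix,
    module_genes: set[str],
    catalog: RegulatorCatalog,
    module_id: str = "module",
    top_n: int = 10,
    landscape: ACLandscape | None = None,
    statistic: str = "mean_abs",
    mask: SignificanceMask | None = None,
) -> tuple[list[RegulatorScore], int]:
    """Rank catalog TFs against one module; returns (top_n scores, number
    of catalog TFs skipped because they are absent from the matrix).

    statistic="mean_abs" (default) averages |r|; "mean_signed" averages r
    as-is (scores may be negative).  With ``mask`` supplied, only
    PCIT-significant TF-gene pairs enter the average (others contribute 0).
    """
    if statistic not in ("mean_abs", "mean_signed"):
        raise ValueError(f"unknown statistic: {statistic!r}")
    if not module_genes:
        raise ValueError("empty module")
    index = {g: i for i, g in enumerate(corr_overall.gene_ids)}
    missing_module = sorted(g for g in module_genes if g not in index)
    if missing_module:
        raise KeyError(
            f"module genes absent from correlation matrix: {missing_module[:10]}"
        )
    if mask is not None and mask.gene_ids != corr_overall.gene_ids:
        raise ValueError("mask gene IDs differ from correlation matrix")

    tfs = sorted(catalog.tf_ids)
    present = [t for t in tfs if t in index]
    skipped = len(tfs) - len(present)
    land_nodes = landscape.nodes if landscape is not None else set()

    scored: list[tuple[float, str]] = []
    for tf in present:
        ti = index[tf]
        others = [index[g] for g in module_genes if g != tf]
        if not others:
            continue  # module == {tf}; nothing to average over
        r = corr_overall.r[ti, others]
        if mask is not None:
            r = r * mask.keep[ti, others]
        val = np.abs(r).mean() if statistic == "mean_abs" else r.mean()
        scored.append((float(val), tf))
    scored.sort(key=lambda t: (-t[0], t[1]))
    results = [
        RegulatorScore(
            tf_id=tf,
            module_id=module_id,
            score=score,
            rank=i + 1,
            in_module=tf in module_genes,
            in_landscape=tf in land_nodes,
        )
        for i, (score, tf) in enumerate(scored[:top_n])
    ]
    return results, skipped


@dataclass
class RegulatorTableRow:
    module_id: str
    in_module_and_top: list[str]
    in_module_only: list[str]
    top_only: list[str]


def regulator_table(
    per_module_scores: dict[str, list[RegulatorScore]],
    module_genes: dict[str, set[str]],
    catalog: RegulatorCatalog,
) -> list[RegulatorTableRow]:
    """Three-way partition of (module TFs | top-ranked TFs) per module."""
    rows = []
    for mid in sorted(per_module_scores):
        top = [s.tf_id for s in per_module_scores[mid]]
        module_tfs = sorted(module_genes.get(mid, set()) & catalog.tf_ids)
        top_set = set(top)
        rows.append(
            RegulatorTableRow(
                module_id=mid,
                in_module_and_top=[t for t in top if t in set(module_tfs)],
                in_module_only=[t for t in module_tfs if t not in top_set],
                top_only=[t for t in top if t not in set(module_tfs)],
            )
        )
    return rows
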