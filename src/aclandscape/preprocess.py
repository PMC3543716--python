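"""Microarray data-acquisition filters.

Four steps, applied in order before any correlation is computed:

1. drop probes with a dubious gene assignment (no gene, or several genes,
   predicted for the same probe set);
2. collapse probes to genes, keeping for each gene the probe with the
   highest mean expression over all samples;
3. keep genes called Present in at least one sample (optionally, in all
   replicates of at least one time point);
4. per analysis group, remove genes with no deviation of expression from
   the mean beyond one standard deviation ("flat" genes), restricting the
   matrix to the group's samples.

Every filter only removes rows (or columns); retained values are never
altered, so each filter is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import PRESENT, ExpressionMatrix, SampleGroup

CONFIDENT = "confident"
DUBIOUS = "dubious"

MIN_GROUP_SAMPLES = 3


@dataclass
class ProbeAnnotation:
    """Probe -> gene assignments with a confidence status.

    table : DataFrame with columns probe_id, gene_id, status; status is
    "dubious" exactly when the gene assignment is empty or ambiguous.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"probe_id", "gene_id", "status"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"annotation missing columns: {sorted(missing)}")
        if self.table["probe_id"].duplicated().any():
            dups = self.table.loc[self.table["probe_id"].duplicated(), "probe_id"]
            raise ValueError(f"duplicate probe IDs: {sorted(set(dups))[:5]}")
        bad = set(self.table["status"]) - {CONFIDENT, DUBIOUS}
        if bad:
            raise ValueError(f"unknown status values: {sorted(bad)}")

    def status_of(self) -> pd.Series:
        return self.table.set_index("probe_id")["status"]

    def gene_of(self) -> pd.Series:
        return self.table.set_index("probe_id")["gene_id"]


class UnannotatedProbeError(KeyError):
    """Expression rows without an annotation record."""

    def __init__(self, probe_ids):
        self.probe_ids = sorted(probe_ids)
        super().__init__(f"unannotated probes: {self.probe_ids[:10]}")


def _check_annotated(expr: ExpressionMatrix, annot: ProbeAnnotation) -> None:
    known = set(annot.table["probe_id"])
    missing = [p for p in expr.row_ids if p not in known]
    if missing:
        raise UnannotatedProbeError(missing)


def drop_dubious_probes(
    expr: ExpressionMatrix, annot: ProbeAnnotation
) -> ExpressionMatrix:
    """Remove probes whose gene assignment is dubious; row order preserved."""
    _check_annotated(expr, annot)
    status = annot.status_of()
    keep = [p for p in expr.row_ids if status[p] == CONFIDENT]
    return expr.subset_rows(keep)


def collapse_to_genes(
    expr: ExpressionMatrix, annot: ProbeAnnotation
) -> ExpressionMatrix:
    """One row per gene: keep the probe with the highest mean expression
    (averaged over ALL samples); ties broken by smallest probe ID.

    Rows are re-labelled with the gene ID and ordered by gene ID.
    """
    _check_annotated(expr, annot)
    status = annot.status_of()
    dubious = [p for p in expr.row_ids if status[p] != CONFIDENT]
    if dubious:
        raise ValueError(f"dubious probes present, drop them first: {dubious[:5]}")
    gene_of = annot.gene_of()
    means = expr.values.mean(axis=1)
    best: dict[str, str] = {}
    for probe in expr.row_ids:
        gene = gene_of[probe]
        cur = best.get(gene)
        if (
            cur is None
            or means[probe] > means[cur]
            or (means[probe] == means[cur] and probe < cur)
        ):
            best[gene] = probe
    genes = sorted(best)
    probes = [best[g] for g in genes]
    values = expr.values.loc[probes]
    detection = expr.detection.loc[probes]
    values.index = genes
    detection.index = genes
    return ExpressionMatrix(values, detection, dict(expr.sample_group))


def filter_present(
    expr: ExpressionMatrix,
    min_timepoints: int = 1,
    sample_timepoint: dict[str, str] | None = None,
) -> ExpressionMatrix:
    """Keep genes with a Present call in at least ``min_timepoints`` samples.

    With ``sample_timepoint`` supplied, the stricter reading applies: a
    time point counts only when every one of its replicate samples is
    Present, and the gene needs at least ``min_timepoints`` such time
    points.
    """
    present = expr.detection == PRESENT
    if sample_timepoint is None:
        keep_mask = present.sum(axis=1) >= min_timepoints
    else:
        unknown = [s for s in expr.sample_ids if s not in sample_timepoint]
        if unknown:
            raise KeyError(f"samples without a time point: {unknown[:5]}")
        tps = pd.Series({s: sample_timepoint[s] for s in expr.sample_ids})
        per_tp_all = present.T.groupby(tps).all().T  # gene x timepoint
        keep_mask = per_tp_all.sum(axis=1) >= min_timepoints
    keep = [g for g, k in keep_mask.items() if k]
    return expr.subset_rows(keep)


def filter_low_variation(
    expr: ExpressionMatrix,
    group: SampleGroup,
    k_sd: float = 1.0,
    mode: str = "global_sd",
) -> ExpressionMatrix:
    """Remove genes with no deviation beyond ``k_sd`` standard deviations
    within the group, returning the matrix restricted to the group's
    samples and the surviving genes.

    mode="global_sd" (default): the SD is the standard deviation of the
    pooled value distribution of all genes over the group's samples, a
    dataset-level scale.  mode="gene_sd": each gene is compared against its
    own SD over the group.  A gene survives when the largest absolute
    deviation from its group mean exceeds the chosen threshold.
    """
    if mode not in ("global_sd", "gene_sd"):
        raise ValueError(f"unknown mode: {mode!r}")
    missing = [s for s in group.sample_ids if s not in set(expr.sample_ids)]
    if missing:
        raise KeyError(f"group {group.name}: samples not in matrix: {missing[:5]}")
    if len(group.sample_ids) < MIN_GROUP_SAMPLES:
        raise ValueError(
            f"group {group.name}: {len(group.sample_ids)} samples "
            f"(need >= {MIN_GROUP_SAMPLES})"
        )
    sub = expr.subset_samples(group.sample_ids)
    vals = sub.values.to_numpy(float)
    dev = np.abs(vals - vals.mean(axis=1, keepdims=True)).max(axis=1)
    if mode == "global_sd":
        threshold = k_sd * vals.std(ddof=1)
        keep_mask = dev > threshold
    else:
        threshold = k_sd * vals.std(axis=1, ddof=1)
        keep_mask = dev > threshold
    keep = [g for g, k in zip(sub.row_ids, keep_mask) if k]
    return sub.subset_rows(keep)


def preprocess_group(
    expr: ExpressionMatrix,
    group: SampleGroup,
    k_sd: float = 1.0,
    mode: str = "global_sd",
    min_timepoints: int = 1,
) -> ExpressionMatrix:
    """Present-flag filter followed by the group variation filter."""
    return filter_low_variation(
        filter_present(expr, min_timepoints), group, k_sd, mode
    )
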