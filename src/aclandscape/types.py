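"""Core in-memory containers shared by all pipeline stages.

Expression data lives in pandas DataFrames (genes x samples); networks are
kept as explicit edge dictionaries keyed by lexicographically ordered gene
pairs, which makes set intersection across condition networks trivial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

Pair = tuple[str, str]

PRESENT = "P"
ABSENT = "A"
MARGINAL = "M"


def ordered_pair(a: str, b: str) -> Pair:
    """Canonical unordered-pair key: lexicographically smallest first."""
    if a == b:
        raise ValueError(f"self-pair not allowed: {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass
class ExpressionMatrix:
    """Gene/probe x sample expression values with detection flags.

    values : DataFrame, rows are probe or gene IDs, columns are sample IDs,
        entries are normalized intensities assumed log2-scale.
    detection : DataFrame of the same shape with P/A/M detection calls
        (Present / Absent / Marginal).
    sample_group : mapping sample ID -> base group name.
    """

    values: pd.DataFrame
    detection: pd.DataFrame
    sample_group: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.shape != self.detection.shape:
            raise ValueError(
                "values and detection shapes differ: "
                f"{self.values.shape} vs {self.detection.shape}"
            )
        if not self.values.index.equals(self.detection.index) or not (
            self.values.columns.equals(self.detection.columns)
        ):
            raise ValueError("values and detection must share index/columns")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate row IDs: {sorted(dups)[:5]}")
        if not np.isfinite(self.values.to_numpy(float)).all():
            raise ValueError("non-finite expression values")

    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_rows(self, rows) -> "ExpressionMatrix":
        rows = list(rows)
        return ExpressionMatrix(
            self.values.loc[rows], self.detection.loc[rows], dict(self.sample_group)
        )

    def subset_samples(self, samples) -> "ExpressionMatrix":
        samples = list(samples)
        return ExpressionMatrix(
            self.values[samples],
            self.detection[samples],
            {s: g for s, g in self.sample_group.items() if s in set(samples)},
        )


@dataclass(frozen=True)
class SampleGroup:
    """One analysis group: a named, ordered set of sample IDs.

    Analysis groups may overlap (the Overall group contains every sample).
    """

    name: str
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError(f"group {self.name}: duplicate sample IDs")


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson correlation matrix with unit diagonal."""

    gene_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        if self.r.shape != (n, n):
            raise ValueError(f"matrix shape {self.r.shape} != ({n}, {n})")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise ValueError("correlation matrix not symmetric to 1e-12")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-12):
            raise ValueError("diagonal not 1")
        if np.abs(self.r).max() > 1 + 1e-12:
            raise ValueError("|r| > 1")

    def lookup(self, a: str, b: str) -> float:
        i = self.gene_ids.index(a)
        j = self.gene_ids.index(b)
        return float(self.r[i, j])


@dataclass
class SignificanceMask:
    """Boolean PCIT keep-mask over gene pairs (false diagonal)."""

    gene_ids: list[str]
    keep: np.ndarray
    skipped_trios: int = 0

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        if self.keep.shape != (n, n):
            raise ValueError("mask shape mismatch")
        if not (self.keep == self.keep.T).all():
            raise ValueError("mask not symmetric")
        if self.keep.diagonal().any():
            raise ValueError("mask diagonal must be false")


@dataclass
class CorrelationNetwork:
    """One condition group's PCIT-significant weighted edge set.

    edges maps the ordered gene pair to the Pearson correlation used as the
    edge weight.
    """

    group_name: str
    nodes: set[str]
    edges: dict[Pair, float]

    def __post_init__(self) -> None:
        for (a, b), w in self.edges.items():
            if a >= b:
                raise ValueError(f"edge pair not ordered: {(a, b)}")
            if a not in self.nodes or b not in self.nodes:
                raise ValueError(f"edge endpoint outside node set: {(a, b)}")
            if abs(w) > 1:
                raise ValueError(f"edge weight out of range: {(a, b)} -> {w}")


@dataclass
class ACEdge:
    """One Always-Correlated edge with its per-network evidence."""

    per_network_r: dict[str, float]
    assigned_r: float
    sign: str  # "positive" | "negative"
    sign_consistent: bool


@dataclass
class ACLandscape:
    """Edges significant in every condition network.

    assigned_r (and hence sign) comes from the reference group's network;
    sign_consistent records whether every per-network correlation shares
    one sign.
    """

    nodes: set[str]
    edges: dict[Pair, ACEdge]
    source_groups: tuple[str, ...]
    reference_group: str

    def __post_init__(self) -> None:
        endpoints = {g for pair in self.edges for g in pair}
        if self.nodes != endpoints:
            raise ValueError("landscape nodes must equal edge endpoints")


@dataclass(frozen=True)
class IdMapping:
    """Confident, strictly 1:1 partial gene-ID map between two platforms."""

    pairs: Mapping[str, str]
    dropped_conflicts: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.pairs.values())) != len(self.pairs):
            raise ValueError("mapping not 1:1 on the target side")

    @property
    def universe_size(self) -> int:
        return len(self.pairs)

    def inverse(self) -> "IdMapping":
        return IdMapping({b: a for a, b in self.pairs.items()}, self.dropped_conflicts)
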