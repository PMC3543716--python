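"""Hypergeometric over-representation of gene sets in modules.

Flat gene-set enrichment over a supplied collection (e.g. a pre-propagated
GO slim in GMT form): for a module of size n drawn from a universe of N
genes, a term annotating K universe genes and k module genes has
upper-tail probability P(X >= k) with X ~ Hypergeometric(N, K, n).  The
same statistic serves as the set-overlap test between two landscapes.
Ontology hierarchy handling is deliberately out of scope — collections
must carry any desired propagation already.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    term_name: str
    genes: frozenset[str]


@dataclass
class GeneSetCollection:
    sets: dict[str, GeneSet]

    def __post_init__(self) -> None:
        for tid, gs in self.sets.items():
            if tid != gs.term_id:
                raise ValueError(f"key {tid!r} != term_id {gs.term_id!r}")
            if not gs.genes:
                raise ValueError(f"term {tid!r} has an empty gene set")

    @classmethod
    def from_dict(cls, d: dict[str, tuple[str, Iterable[str]]]):
        return cls(
            {
                tid: GeneSet(tid, name, frozenset(genes))
                for tid, (name, genes) in d.items()
            }
        )


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # module genes in term
    K: int  # universe genes in term
    n: int  # module size within universe
    N: int  # universe size
    p: float
    p_adj: float


def _log_comb(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), in log space.

    N: universe size, K: marked genes, n: draws, k: observed marked draws.
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if v < 0:
            raise ValueError(f"{name} negative: {v}")
    if K > N or n > N:
        raise ValueError(f"K={K} or n={n} exceeds N={N}")
    if k > min(K, n):
        raise ValueError(f"k={k} exceeds min(K, n)={min(K, n)}")
    if k <= max(0, n + K - N):
        return 1.0
    denom = _log_comb(N, n)
    log_terms = [
        _log_comb(K, j) + _log_comb(N - K, n - j) - denom
        for j in range(k, min(K, n) + 1)
    ]
    return float(min(1.0, math.exp(logsumexp(log_terms))))


def enrich(
    module_genes: set[str],
    universe: set[str],
    collection: GeneSetCollection,
    correction: str = "BH",
) -> list[EnrichmentResult]:
    """One upper-tail test per term overlapping the module.

    Terms are intersected with the universe before counting; correction
    (BH, bonferroni or none) is applied across all terms represented in
    the universe, and results with k >= 1 are returned sorted by p.
    """
    if correction not in ("BH", "bonferroni", "none"):
        raise ValueError(f"unknown correction: {correction!r}")
    outside = sorted(module_genes - universe)
    if outside:
        raise ValueError(f"module genes outside universe: {outside[:10]}")
    N = len(universe)
    n = len(module_genes)
    tested = []
    for gs in collection.sets.values():
        term_universe = gs.genes & universe
        K = len(term_universe)
        if K == 0:
            continue
        k = len(module_genes & term_universe)
        tested.append((gs, k, K, hypergeom_upper_tail(k, K, n, N)))
    if not tested:
        return []
    pvals = [t[3] for t in tested]
    if correction == "BH":
        p_adj = multipletests(pvals, method="fdr_bh")[1]
    elif correction == "bonferroni":
        p_adj = multipletests(pvals, method="bonferroni")[1]
    else:
        p_adj = pvals
    results = [
        EnrichmentResult(gs.term_id, gs.term_name, k, K, n, N, p, float(pa))
        for (gs, k, K, p), pa in zip(tested, p_adj)
        if k >= 1
    ]
    return sorted(results, key=lambda r: (r.p, r.term_id))


def overlap_test(
    set_a: set[str], set_b: set[str], universe: set[str]
) -> tuple[int, float, float]:
    """Hypergeometric overlap of two gene sets within a universe.

    Returns (observed overlap, expected overlap under independence,
    upper-tail p-value).  Symmetric in its first two arguments.
    """
    for name, s in (("set_a", set_a), ("set_b", set_b)):
        outside = sorted(s - universe)
        if outside:
            raise ValueError(f"{name} members outside universe: {outside[:10]}")
    N = len(universe)
    overlap = len(set_a & set_b)
    expected = len(set_a) * len(set_b) / N if N else 0.0
    p = hypergeom_upper_tail(overlap, len(set_a), len(set_b), N)
    return overlap, expected, p
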