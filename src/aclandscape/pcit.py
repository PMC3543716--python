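"""PCIT edge significance: partial correlations + information theory.

For every unordered gene trio (x, y, z) the three first-order partial
correlations are computed,

    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)),

and the trio-specific tolerance epsilon is the arithmetic mean of the three
partial/direct ratios (a ratio is skipped when its direct correlation is 0
within 1e-12; epsilon averages the rest).  The edge (x, y) is flagged
non-significant in the trio when both flanking correlations dominate it at
that tolerance:

    |r_xy| < |eps * r_xz|  and  |r_xy| < |eps * r_yz|.

An edge survives only if no trio flags it and its correlation is nonzero.
Trios containing a near-unit off-diagonal correlation (|r| >= 1 - 1e-12,
e.g. duplicated genes) are degenerate and skipped with a counter; such
edges are kept, they are only never conditioned on.

The production path is a numba-compiled O(n^3) trio loop
(:func:`pcit_mask`); :func:`pcit_mask_bruteforce` is a deliberately naive
pure-Python triple loop kept as an independent reference for validation.
The cubic loop is practical to roughly 5,000 genes on one core, comfortably
covering per-condition networks of a few thousand genes.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .types import (
    CorrelationMatrix,
    CorrelationNetwork,
    ExpressionMatrix,
    SampleGroup,
    SignificanceMask,
    ordered_pair,
)

UNIT_TOL = 1e-12  # |r| >= 1 - UNIT_TOL counts as a duplicate-gene correlation
ZERO_TOL = 1e-12  # |r| < ZERO_TOL counts as a zero direct correlation


class DegenerateTrioError(ValueError):
    """A conditioning correlation is at +-1: the partial is undefined."""


def correlation_matrix(
    expr: ExpressionMatrix, group: SampleGroup
) -> CorrelationMatrix:
    """Pearson correlations over the group's samples."""
    missing = [s for s in group.sample_ids if s not in set(expr.sample_ids)]
    if missing:
        raise KeyError(f"group {group.name}: samples not in matrix: {missing[:5]}")
    if len(group.sample_ids) < 3:
        raise ValueError(f"group {group.name}: need >= 3 samples for correlation")
    vals = expr.values[list(group.sample_ids)].to_numpy(float)
    sd = vals.std(axis=1)
    zero = [g for g, s in zip(expr.row_ids, sd) if s == 0.0]
    if zero:
        raise ValueError(
            f"zero-variance genes in group {group.name} "
            f"(variation filter bypassed?): {zero[:5]}"
        )
    r = np.corrcoef(vals)
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    return CorrelationMatrix(list(expr.row_ids), r)


def first_order_partial(rxy: float, rxz: float, ryz: float) -> float:
    """First-order partial correlation of x, y given z, clamped to [-1, 1]."""
    if abs(rxz) >= 1.0 - UNIT_TOL or abs(ryz) >= 1.0 - UNIT_TOL:
        raise DegenerateTrioError(
            f"conditioning correlation at unity: rxz={rxz}, ryz={ryz}"
        )
    p = (rxy - rxz * ryz) / math.sqrt((1.0 - rxz**2) * (1.0 - ryz**2))
    return max(-1.0, min(1.0, p))


@njit(cache=False)
def _pcit_flag_kernel(r, signed):  # pragma: no cover - exercised via pcit_mask
    n = r.shape[0]
    flagged = np.zeros((n, n), dtype=np.bool_)
    skipped = 0
    unit = 1.0 - 1e-12
    ztol = 1e-12
    for x in range(n - 2):
        for y in range(x + 1, n - 1):
            rxy = r[x, y]
            for z in range(y + 1, n):
                rxz = r[x, z]
                ryz = r[y, z]
                if abs(rxy) >= unit or abs(rxz) >= unit or abs(ryz) >= unit:
                    skipped += 1
                    continue
                pxy = (rxy - rxz * ryz) / math.sqrt(
                    (1.0 - rxz * rxz) * (1.0 - ryz * ryz)
                )
                pxz = (rxz - rxy * ryz) / math.sqrt(
                    (1.0 - rxy * rxy) * (1.0 - ryz * ryz)
                )
                pyz = (ryz - rxy * rxz) / math.sqrt(
                    (1.0 - rxy * rxy) * (1.0 - rxz * rxz)
                )
                pxy = max(-1.0, min(1.0, pxy))
                pxz = max(-1.0, min(1.0, pxz))
                pyz = max(-1.0, min(1.0, pyz))
                s = 0.0
                c = 0
                if abs(rxy) >= ztol:
                    ratio = pxy / rxy
                    if not signed:
                        ratio = abs(ratio)
                    s += ratio
                    c += 1
                if abs(rxz) >= ztol:
                    ratio = pxz / rxz
                    if not signed:
                        ratio = abs(ratio)
                    s += ratio
                    c += 1
                if abs(ryz) >= ztol:
                    ratio = pyz / ryz
                    if not signed:
                        ratio = abs(ratio)
                    s += ratio
                    c += 1
                if c == 0:
                    continue
                eps = s / c
                aexy = abs(eps * rxy)
                aexz = abs(eps * rxz)
                aeyz = abs(eps * ryz)
                if abs(rxy) < aexz and abs(rxy) < aeyz:
                    flagged[x, y] = True
                    flagged[y, x] = True
                if abs(rxz) < aexy and abs(rxz) < aeyz:
                    flagged[x, z] = True
                    flagged[z, x] = True
                if abs(ryz) < aexy and abs(ryz) < aexz:
                    flagged[y, z] = True
                    flagged[z, y] = True
    return flagged, skipped


def pcit_mask(corr: CorrelationMatrix, ratio_mode: str = "signed") -> SignificanceMask:
    """Locally significant edges under the trio tolerance rule.

    ratio_mode="signed" (default) averages the partial/direct ratios as-is;
    "absolute" averages their absolute values.  With fewer than 3 genes
    there are no trios and every nonzero correlation is kept.
    """
    if ratio_mode not in ("signed", "absolute"):
        raise ValueError(f"unknown ratio_mode: {ratio_mode!r}")
    n = len(corr.gene_ids)
    if n < 2:
        raise ValueError("need >= 2 genes")
    r = np.asarray(corr.r, dtype=np.float64)
    if n < 3:
        flagged = np.zeros((n, n), dtype=bool)
        skipped = 0
    else:
        flagged, skipped = _pcit_flag_kernel(r, ratio_mode == "signed")
        flagged = np.asarray(flagged)
    keep = (r != 0.0) & ~flagged
    np.fill_diagonal(keep, False)
    return SignificanceMask(list(corr.gene_ids), keep, skipped_trios=int(skipped))


def pcit_mask_bruteforce(
    corr: CorrelationMatrix, ratio_mode: str = "signed"
) -> SignificanceMask:
    """Naive reference implementation: explicit Python triple loop built on
    :func:`first_order_partial`.  Quadratic memory, cubic time; for
    validation only."""
    if ratio_mode not in ("signed", "absolute"):
        raise ValueError(f"unknown ratio_mode: {ratio_mode!r}")
    n = len(corr.gene_ids)
    if n < 2:
        raise ValueError("need >= 2 genes")
    r = corr.r
    flagged = np.zeros((n, n), dtype=bool)
    skipped = 0
    for x in range(n):
        for y in range(x + 1, n):
            for z in range(y + 1, n):
                trio = [(x, y, z), (x, z, y), (y, z, x)]
                try:
                    partials = {
                        (i, j): first_order_partial(r[i, j], r[i, k], r[j, k])
                        for i, j, k in trio
                    }
                except DegenerateTrioError:
                    skipped += 1
                    continue
                ratios = []
                for (i, j), p in partials.items():
                    if abs(r[i, j]) >= ZERO_TOL:
                        q = p / r[i, j]
                        ratios.append(q if ratio_mode == "signed" else abs(q))
                if not ratios:
                    continue
                eps = sum(ratios) / len(ratios)
                pairs = [(x, y), (x, z), (y, z)]
                for i, j in pairs:
                    others = [p for p in pairs if p != (i, j)]
                    if all(
                        abs(r[i, j]) < abs(eps * r[a, b]) for a, b in others
                    ):
                        flagged[i, j] = True
                        flagged[j, i] = True
    keep = (r != 0.0) & ~flagged
    np.fill_diagonal(keep, False)
    return SignificanceMask(list(corr.gene_ids), keep, skipped_trios=skipped)


def network_from_mask(
    corr: CorrelationMatrix, mask: SignificanceMask, group_name: str
) -> CorrelationNetwork:
    if corr.gene_ids != mask.gene_ids:
        raise ValueError("correlation matrix and mask gene IDs differ")
    genes = corr.gene_ids
    edges = {}
    ii, jj = np.nonzero(np.triu(mask.keep, k=1))
    for i, j in zip(ii, jj):
        edges[ordered_pair(genes[i], genes[j])] = float(corr.r[i, j])
    return CorrelationNetwork(group_name, set(genes), edges)


def build_network(
    expr: ExpressionMatrix, group: SampleGroup, ratio_mode: str = "signed"
) -> CorrelationNetwork:
    """Correlation + PCIT significance for one (already filtered) group.

    Nodes are all genes of the filtered matrix; edges are the PCIT-kept
    pairs weighted by their Pearson correlation.
    """
    corr = correlation_matrix(expr, group)
    mask = pcit_mask(corr, ratio_mode)
    return network_from_mask(corr, mask, group.name)
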