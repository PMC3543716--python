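"""Synthetic multi-condition expression data with known ground truth.

The generator emulates the structure of a multi-group microarray study of a
single tissue: disjoint condition groups of samples; modules of genes driven
by a latent factor that is active either in every group (always-correlated)
or only in a subset (condition-specific); mixed-sign factor loadings so that
negative correlations occur; flat low-variance genes that the one-SD
variation filter must remove; Present/Absent detection flags; transcription
factors tied to module factors; and a paired second "species" dataset with
a partial, strictly 1:1 gene-ID mapping.

Gene model, per group g and sample s:

* member i of a module active in g:   x_is = 8 + l_i * f_gs + e,  e ~ N(0, sd)
  where f_gs ~ N(0,1) is the module's factor value for that sample and l_i is
  the signed loading.  The expected Pearson correlation between members i, j
  is l_i l_j / sqrt((l_i^2 + sd^2)(l_j^2 + sd^2)).
* member of a module inactive in g, and background genes: 8 + N(0, sd).
* flat genes: 8 + N(0, sd/100) — provably below the variation filter.

Transcription-factor regulators are ordinary extra module members with
loading 0.9x the module loading, flagged in the ground truth so that
module-to-regulator recovery is testable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .types import ABSENT, PRESENT, ExpressionMatrix, IdMapping, Pair, ordered_pair

BASELINE = 8.0  # log2-like constant level for every gene
FLAT_NOISE_SHRINK = 100.0  # flat genes get noise_sd / 100
REGULATOR_LOADING_FACTOR = 0.9


class ConfigError(ValueError):
    """A SimulationConfig field violates its invariant."""


@dataclass(frozen=True)
class ModuleSpec:
    """One planted co-expression module.

    size : number of ordinary member genes (>= 2).
    loading : factor loading magnitude in (0, 1].
    negative_fraction : fraction of members given a negative loading.
    active_groups : group names in which the module's factor drives its
        members; None means active in every group (always-correlated).
    regulator_count : extra transcription-factor members with loading
        0.9 * loading, recorded in GroundTruth.regulator_map.
    """

    size: int
    loading: float = 1.0
    negative_fraction: float = 0.0
    active_groups: tuple[str, ...] | None = None
    regulator_count: int = 0

    @property
    def total_genes(self) -> int:
        return self.size + self.regulator_count


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 150
    groups: tuple[tuple[str, int], ...] = (
        ("Callipyge", 16),
        ("Normal", 19),
        ("Prenatal", 15),
        ("Postnatal", 20),
        ("HighLow", 40),
    )
    modules: tuple[ModuleSpec, ...] = (
        ModuleSpec(size=30, loading=1.0, negative_fraction=0.3, regulator_count=1),
        ModuleSpec(size=15, loading=1.0, regulator_count=1),
        ModuleSpec(
            size=20,
            loading=1.0,
            active_groups=("Callipyge", "Normal", "Prenatal"),
            regulator_count=1,
        ),
    )
    flat_gene_fraction: float = 0.2
    noise_sd: float = 0.5
    detection_missing_fraction: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        names = [g for g, _ in self.groups]
        if len(set(names)) != len(names):
            raise ConfigError("groups: names must be unique")
        if not self.groups:
            raise ConfigError("groups: at least one group required")
        for g, n in self.groups:
            if n < 1:
                raise ConfigError(f"groups: group {g} has n_samples={n} < 1")
        for frac_name in ("flat_gene_fraction", "detection_missing_fraction"):
            v = getattr(self, frac_name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{frac_name}: {v} outside [0, 1]")
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd: {self.noise_sd} must be non-negative")
        module_genes = sum(m.total_genes for m in self.modules)
        n_flat = self.n_flat_genes
        if module_genes + n_flat > self.n_genes:
            raise ConfigError(
                "n_genes: module genes + flat genes "
                f"({module_genes} + {n_flat}) exceed n_genes={self.n_genes}"
            )
        group_set = set(names)
        for i, m in enumerate(self.modules):
            if m.size < 2:
                raise ConfigError(f"modules[{i}].size: {m.size} < 2")
            if not 0.0 < m.loading <= 1.0:
                raise ConfigError(f"modules[{i}].loading: {m.loading} outside (0, 1]")
            if not 0.0 <= m.negative_fraction <= 1.0:
                raise ConfigError(
                    f"modules[{i}].negative_fraction: {m.negative_fraction}"
                )
            if m.regulator_count < 0:
                raise ConfigError(f"modules[{i}].regulator_count negative")
            if m.active_groups is not None:
                if not m.active_groups:
                    raise ConfigError(f"modules[{i}].active_groups: empty")
                unknown = set(m.active_groups) - group_set
                if unknown:
                    raise ConfigError(
                        f"modules[{i}].active_groups: unknown groups {sorted(unknown)}"
                    )

    @property
    def n_flat_genes(self) -> int:
        return int(round(self.flat_gene_fraction * self.n_genes))

    @property
    def group_names(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.groups)


@dataclass
class GroundTruth:
    """What the generator planted, for downstream recovery checks."""

    module_membership: dict[str, int]  # gene -> module index
    always_pairs: set[Pair]
    conditional_pairs: set[Pair]
    flat_genes: set[str]
    regulator_map: dict[str, int]  # TF gene -> module index
    loadings: dict[str, float] = field(default_factory=dict)
    module_active_groups: dict[int, tuple[str, ...]] = field(default_factory=dict)

    def module_genes(self, module_id: int) -> set[str]:
        return {g for g, m in self.module_membership.items() if m == module_id}


def _gene_names(n: int, prefix: str = "G") -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


def _assign_layout(config: SimulationConfig, prefix: str = "G"):
    """Deterministic gene layout: module members (regulators last within
    each module), then flat genes, then background genes."""
    genes = _gene_names(config.n_genes, prefix)
    cursor = 0
    membership: dict[str, int] = {}
    regulators: dict[str, int] = {}
    loadings: dict[str, float] = {}
    for mi, spec in enumerate(config.modules):
        n_neg = int(round(spec.negative_fraction * spec.size))
        for k in range(spec.size):
            g = genes[cursor]
            cursor += 1
            membership[g] = mi
            loadings[g] = -spec.loading if k < n_neg else spec.loading
        for _ in range(spec.regulator_count):
            g = genes[cursor]
            cursor += 1
            membership[g] = mi
            regulators[g] = mi
            loadings[g] = REGULATOR_LOADING_FACTOR * spec.loading
    flat = set(genes[cursor : cursor + config.n_flat_genes])
    cursor += config.n_flat_genes
    background = set(genes[cursor:])
    return genes, membership, regulators, loadings, flat, background


def generate_expression(
    config: SimulationConfig, gene_prefix: str = "G"
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw one multi-group expression dataset from the factor model.

    Deterministic for a fixed ``config.seed``.  Returns the expression
    matrix (with detection flags and sample->group labels) and the planted
    ground truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes, membership, regulators, loadings, flat, _ = _assign_layout(
        config, gene_prefix
    )
    n_genes = config.n_genes

    sample_ids: list[str] = []
    sample_group: dict[str, str] = {}
    blocks: list[np.ndarray] = []
    for gname, n_samples in config.groups:
        ids = [f"{gname}_s{i:02d}" for i in range(n_samples)]
        sample_ids.extend(ids)
        for s in ids:
            sample_group[s] = gname
        block = BASELINE + rng.normal(0.0, config.noise_sd, (n_genes, n_samples))
        # flat genes: shrink the noise, keep the constant level
        flat_idx = [i for i, g in enumerate(genes) if g in flat]
        if flat_idx:
            block[flat_idx, :] = BASELINE + rng.normal(
                0.0, config.noise_sd / FLAT_NOISE_SHRINK, (len(flat_idx), n_samples)
            )
        # overlay module factors active in this group
        for mi, spec in enumerate(config.modules):
            active = spec.active_groups is None or gname in spec.active_groups
            if not active:
                continue
            factor = rng.normal(0.0, 1.0, n_samples)
            for i, g in enumerate(genes):
                if membership.get(g) == mi:
                    block[i, :] += loadings[g] * factor
        blocks.append(block)

    values = pd.DataFrame(np.hstack(blocks), index=genes, columns=sample_ids)
    detect = np.full(values.shape, PRESENT, dtype=object)
    miss = rng.random(values.shape) < config.detection_missing_fraction
    detect[miss] = ABSENT
    detection = pd.DataFrame(detect, index=genes, columns=sample_ids)

    all_groups = set(config.group_names)
    always_pairs: set[Pair] = set()
    conditional_pairs: set[Pair] = set()
    module_active: dict[int, tuple[str, ...]] = {}
    for mi, spec in enumerate(config.modules):
        members = sorted(g for g, m in membership.items() if m == mi)
        active = (
            tuple(sorted(all_groups))
            if spec.active_groups is None
            else tuple(sorted(spec.active_groups))
        )
        module_active[mi] = active
        target = (
            always_pairs if set(active) == all_groups else conditional_pairs
        )
        for a, b in itertools.combinations(members, 2):
            target.add(ordered_pair(a, b))

    truth = GroundTruth(
        module_membership=membership,
        always_pairs=always_pairs,
        conditional_pairs=conditional_pairs,
        flat_genes=flat,
        regulator_map=regulators,
        loadings=loadings,
        module_active_groups=module_active,
    )
    return ExpressionMatrix(values, detection, sample_group), truth


def expected_pair_correlation(l_i: float, l_j: float, noise_sd: float) -> float:
    """Closed-form within-module correlation of the single-factor model."""
    return (l_i * l_j) / np.sqrt((l_i**2 + noise_sd**2) * (l_j**2 + noise_sd**2))


def _relabel_genes(expr: ExpressionMatrix, rename: dict[str, str]) -> ExpressionMatrix:
    values = expr.values.rename(index=rename).sort_index()
    detection = expr.detection.rename(index=rename).sort_index()
    return ExpressionMatrix(values, detection, dict(expr.sample_group))


def _relabel_truth(truth: GroundTruth, rename: dict[str, str]) -> GroundTruth:
    def rp(pairs: set[Pair]) -> set[Pair]:
        return {ordered_pair(rename[a], rename[b]) for a, b in pairs}

    return GroundTruth(
        module_membership={rename[g]: m for g, m in truth.module_membership.items()},
        always_pairs=rp(truth.always_pairs),
        conditional_pairs=rp(truth.conditional_pairs),
        flat_genes={rename[g] for g in truth.flat_genes},
        regulator_map={rename[g]: m for g, m in truth.regulator_map.items()},
        loadings={rename[g]: v for g, v in truth.loadings.items()},
        module_active_groups=dict(truth.module_active_groups),
    )


def generate_species_pair(
    config_a: SimulationConfig,
    config_b: SimulationConfig,
    shared_modules: int,
    mapping_fraction: float,
    seed: int,
) -> tuple[ExpressionMatrix, ExpressionMatrix, IdMapping, GroundTruth, GroundTruth]:
    """Two datasets ("species") whose first ``shared_modules`` modules hold
    the same member genes under a partial 1:1 ID mapping.

    Species A genes are named ``GA####``, species B ``GB####``; the mapping
    links equal indices for a random ``mapping_fraction`` of the genes
    present on both platforms.  Deterministic for fixed ``seed``.
    """
    if not 0.0 <= mapping_fraction <= 1.0:
        raise ConfigError(f"mapping_fraction: {mapping_fraction} outside [0, 1]")
    if shared_modules > min(len(config_a.modules), len(config_b.modules)):
        raise ConfigError(
            f"shared_modules={shared_modules} exceeds module counts "
            f"({len(config_a.modules)}, {len(config_b.modules)})"
        )
    for k in range(shared_modules):
        ma, mb = config_a.modules[k], config_b.modules[k]
        if ma.total_genes != mb.total_genes:
            raise ConfigError(
                f"shared module {k}: sizes differ ({ma.total_genes} vs {mb.total_genes})"
            )

    rng = np.random.default_rng(seed)
    seed_a, seed_b = (int(s) for s in rng.integers(0, 2**31 - 1, 2))
    expr_a, truth_a = generate_expression(replace(config_a, seed=seed_a), "GA")
    expr_b, truth_b = generate_expression(replace(config_b, seed=seed_b), "GB")

    # De-alias the non-shared tail of species B: reverse the gene labels
    # beyond the shared block so B's private modules land on A's background
    # region under the index mapping, never on A's own modules.
    shared_block = sum(m.total_genes for m in config_b.modules[:shared_modules])
    old_names = expr_b.row_ids
    n_b = len(old_names)
    perm = list(range(shared_block)) + list(range(n_b - 1, shared_block - 1, -1))
    rename = {old_names[i]: old_names[perm[i]] for i in range(n_b)}
    expr_b = _relabel_genes(expr_b, rename)
    truth_b = _relabel_truth(truth_b, rename)

    # identical layout => shared modules occupy the same gene indices
    n_common = min(config_a.n_genes, config_b.n_genes)
    n_mapped = int(round(mapping_fraction * n_common))
    chosen = rng.choice(n_common, size=n_mapped, replace=False)
    genes_a = expr_a.row_ids
    genes_b = expr_b.row_ids
    pairs = {genes_a[i]: genes_b[i] for i in sorted(chosen)}
    return expr_a, expr_b, IdMapping(pairs), truth_a, truth_b
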