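#!/usr/bin/env python
"""Generate the synthetic multi-condition expression study.

Five disjoint condition groups of muscle-like samples (16/19/15/20/40
arrays, mirroring a Callipyge/Normal/Prenatal/Postnatal/High-Low design)
with two always-active co-expression modules (31 and 16 genes including a
planted TF each), one module active in only three conditions (21 genes),
30 flat genes and background noise genes.  Writes the expression matrix,
detection flags, group table, TF catalog, module-derived gene sets and the
ground truth under results/study/.
"""

import sys
from pathlib import Path

from aclandscape import io
from aclandscape.enrichment import GeneSetCollection
from aclandscape.regulators import RegulatorCatalog
from aclandscape.synthetic import SimulationConfig, generate_expression

OUT = Path("results/study")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = SimulationConfig(seed=SEED)
    expr, truth = generate_expression(config)
    io.write_expression(expr, OUT / "expression.tsv", OUT / "flags.tsv",
                        OUT / "groups.tsv")
    io.write_ground_truth(truth, OUT / "ground_truth.json")
    # gene sets: one term per planted module, plus the flat genes as a decoy
    sets = {
        f"MOD{mid}": (f"planted module {mid}", truth.module_genes(mid))
        for mid in sorted(set(truth.module_membership.values()))
    }
    sets["FLAT"] = ("flat decoy genes", truth.flat_genes)
    io.write_gmt(GeneSetCollection.from_dict(sets), OUT / "gene_sets.gmt")
    decoys = sorted(g for g in expr.row_ids
                    if g not in truth.module_membership)[:30]
    io.write_tf_catalog(
        RegulatorCatalog(frozenset(truth.regulator_map) | frozenset(decoys)),
        OUT / "tf_catalog.tsv",
    )
    print(f"seed {SEED}: {len(expr.row_ids)} genes x {len(expr.sample_ids)} "
          f"samples in {len(set(expr.sample_group.values()))} groups")
    print(f"planted: {len(truth.always_pairs)} always-pairs, "
          f"{len(truth.conditional_pairs)} condition-specific pairs, "
          f"{len(truth.flat_genes)} flat genes, "
          f"{len(truth.regulator_map)} TFs")


if __name__ == "__main__":
    main()
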