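#!/usr/bin/env python
"""Sweep correlation cut-offs, detect MCODE modules, and annotate them.

Detection runs over the grid >0.95, >0.90, >0.85, >0.80, >0.70, none;
module lineages are tracked across cut-offs by Jaccard overlap and each
lineage keeps the cut-off reached before its connectivity into the rest
of the landscape jumps.  Chosen modules are tested for gene-set
over-representation (hypergeometric, BH-corrected) against the planted
module terms, using the landscape nodes as the universe.  Writes the
sweep table, module gene lists and enrichment table under results/study/.
"""

from pathlib import Path

import pandas as pd

from aclandscape import io
from aclandscape.enrichment import enrich
from aclandscape.mcode import MCODEParams, jaccard, sweep
from aclandscape.pipeline import DEFAULT_CUTOFFS

OUT = Path("results/study")


def main() -> None:
    land = io.read_edge_attributes(OUT / "landscape_edges.tsv", "Overall")
    truth = io.read_ground_truth(OUT / "ground_truth.json")
    result = sweep(land, DEFAULT_CUTOFFS, MCODEParams())
    pd.DataFrame(result.table()).to_csv(OUT / "sweep.tsv", sep="\t", index=False)
    chosen = {
        f"M{lin.lineage_id}": set(lin.chosen_module.genes)
        for lin in result.lineages
        if lin.chosen_module is not None
    }
    io.write_module_genes(chosen, OUT / "modules.tsv")
    print("chosen modules (size at chosen cut-off):")
    for lin in result.lineages:
        if lin.chosen_module is None:
            continue
        cut = "none" if lin.chosen_cutoff is None else f">{lin.chosen_cutoff}"
        planted = {
            mid: jaccard(set(lin.chosen_module.genes), truth.module_genes(mid))
            for mid in sorted(set(truth.module_membership.values()))
        }
        best = max(planted, key=planted.get)
        print(f"  M{lin.lineage_id}: {lin.chosen_module.size} genes at {cut}, "
              f"best planted match module {best} (J={planted[best]:.2f})")

    collection = io.read_gmt(OUT / "gene_sets.gmt")
    universe = set(land.nodes)
    rows = []
    for mid, genes in sorted(chosen.items()):
        for r in enrich(genes & universe, universe, collection):
            rows.append({"module": mid, "term_id": r.term_id, "term": r.term_name,
                         "k": r.k, "K": r.K, "n": r.n, "N": r.N,
                         "p": r.p, "p_adj": r.p_adj})
    table = pd.DataFrame(rows, columns=["module", "term_id", "term", "k", "K",
                                        "n", "N", "p", "p_adj"])
    table.to_csv(OUT / "enrichment.tsv", sep="\t", index=False)
    print("\ntop enrichment per module:")
    for mid in sorted(chosen):
        sub = table[table["module"] == mid]
        if len(sub):
            top = sub.iloc[0]
            print(f"  {mid}: {top['term']} (k={top['k']}/{top['K']}, "
                  f"p={top['p']:.2e}, BH p={top['p_adj']:.2e})")


if __name__ == "__main__":
    main()
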