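#!/usr/bin/env python
"""Module-to-Regulator analysis on the Overall correlation matrix.

Each catalog TF is scored per chosen module by its mean absolute Pearson
correlation to the module's genes (self-correlation excluded); the top 10
are cross-tabulated against module membership.  Planted TFs should rank
in the top 10 for their own module.  Writes the regulator table under
results/study/.
"""

from pathlib import Path

import pandas as pd

from aclandscape import io
from aclandscape.pcit import correlation_matrix
from aclandscape.regulators import module_to_regulator, regulator_table
from aclandscape.types import SampleGroup

OUT = Path("results/study")


def main() -> None:
    filt = io.read_expression(OUT / "expr_Overall_filtered.tsv",
                              OUT / "flags_Overall_filtered.tsv")
    corr = correlation_matrix(filt, SampleGroup("Overall", tuple(filt.sample_ids)))
    land = io.read_edge_attributes(OUT / "landscape_edges.tsv", "Overall")
    catalog = io.read_tf_catalog(OUT / "tf_catalog.tsv")
    modules = io.read_module_genes(OUT / "modules.tsv")
    truth = io.read_ground_truth(OUT / "ground_truth.json")

    per_module = {}
    for mid, genes in sorted(modules.items()):
        usable = genes & set(corr.gene_ids)
        if not usable:
            continue
        scores, skipped = module_to_regulator(
            corr, usable, catalog, module_id=mid, top_n=10, landscape=land
        )
        per_module[mid] = scores
    rows = regulator_table(per_module, modules, catalog)
    pd.DataFrame(
        [{"module": r.module_id,
          "in_module_and_top10": ",".join(r.in_module_and_top),
          "in_module_only": ",".join(r.in_module_only),
          "top10_only": ",".join(r.top_only)} for r in rows]
    ).to_csv(OUT / "regulators.tsv", sep="\t", index=False)

    planted = set(truth.regulator_map)
    print("module-to-regulator table:")
    for r in rows:
        hits = [t for t in r.in_module_and_top + r.top_only if t in planted]
        print(f"  {r.module_id}: in-module&top10={r.in_module_and_top} "
              f"top10-only={r.top_only[:5]}... planted TFs recovered: {hits}")


if __name__ == "__main__":
    main()
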