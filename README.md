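# aclandscape

Consensus ("Always Correlated") gene co-expression landscape analysis for
a single tissue measured under multiple conditions — for systems
biologists who want condition-robust co-expression structure from modest
sample numbers.

One network is inferred per condition group with **PCIT** (partial
correlation + information theory): for every gene trio (x, y, z) the
first-order partials

    r_xy·z = (r_xy − r_xz r_yz) / √((1 − r_xz²)(1 − r_yz²))

define a tolerance ε (mean partial/direct ratio), and the edge (x, y) is
dropped when |r_xy| < |ε·r_xz| and |r_xy| < |ε·r_yz| for some z. The
**AC landscape** keeps the gene pairs significant in *every* condition
network; dense modules are extracted with a re-implemented MCODE swept
over correlation cut-offs (>0.95 … none), annotated by hypergeometric
gene-set enrichment (P(X ≥ k), X ~ Hypergeom(N, K, n)), ranked against a
transcription-factor catalog (mean |r| to module genes in the Overall
network), and compared across species under a confident 1:1 gene map.

A synthetic multi-condition generator with known ground truth (planted
always-correlated and condition-specific modules, negative loadings,
flat genes, planted TF regulators, paired second species) makes every
stage testable without external data. See `docs/methods.md` for the full
model description.

## Worked example

The numbered drivers under `analysis/` run the default simulated study
(150 genes; groups of 16/19/15/20/40 samples; two always-active planted
modules, one module active in 3 of 6 groups; loading 1.0, noise 0.5):

```bash
python analysis/01_simulate.py 1
python analysis/02_networks_and_landscape.py
python analysis/03_modules_and_enrichment.py
python analysis/04_regulators.py
python analysis/05_cross_species.py 1
```

`02_networks_and_landscape.py` prints:

```
 Callipyge:  16 samples, 112 genes pass filters, 1548 PCIT edges
    Normal:  19 samples, 114 genes pass filters, 1342 PCIT edges
  Prenatal:  15 samples, 108 genes pass filters, 1335 PCIT edges
 Postnatal:  20 samples, 116 genes pass filters, 1298 PCIT edges
   HighLow:  40 samples, 120 genes pass filters, 1115 PCIT edges
   Overall: 110 samples, 120 genes pass filters, 1385 PCIT edges

AC landscape: 52 nodes, 575 edges (34.4% negative), largest component 31
ground truth: sensitivity 0.978 for always-pairs, leakage 0.014 for condition-specific pairs
```

Each per-group network is dense (a thousand-plus edges on ~115 genes),
but only 575 pairs are significant in all six — and those recover 97.8%
of the truly always-co-expressed pairs while letting through 1.4% of the
pairs co-expressed in only three conditions. The 34.4% negative edges
trace back to the mixed-sign factor loadings. The module step then
reports, e.g.:

```
  M0: 31 genes at none, best planted match module 0 (J=1.00)
  M5: 15 genes at none, best planted match module 1 (J=0.94)
  M0: planted module 0 (k=31/31, p=5.21e-15, BH p=1.56e-14)
```

i.e. the two planted always-active modules are recovered essentially
exactly and their gene-set terms dominate the enrichment, and the
regulator step places each planted TF in the top-10 list of its own
module. The cross-species run shares 471 mapped edges between the two
simulated landscapes, all of them inside the two shared modules, with
node-overlap p ≈ 4×10⁻³².

The same stages are scriptable via the CLI (`aclandscape simulate |
preprocess | pcit | landscape | modules | enrich | regulators | xspecies
| run`); `aclandscape run --config cfg.yaml` executes the whole pipeline
from a YAML config and writes a JSON run report.

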