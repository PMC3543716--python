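# Methods

## Overview

`aclandscape` implements a consensus approach to co-expression network
inference for a single tissue measured under several conditions. One
weighted gene co-expression network is inferred per condition group with
PCIT (partial correlation and information theory); the **Always
Correlated (AC) landscape** is the set of gene pairs significant in
*every* group network. Dense modules are then extracted from the
landscape with a re-implemented MCODE swept over correlation cut-offs,
annotated by hypergeometric gene-set enrichment, linked to candidate
transcription-factor regulators, and compared across platforms/species
under a confident 1:1 gene-ID mapping.

Because the landscape intersects *significance* across networks rather
than correlation values, an AC edge carries the full vector of per-group
correlations; its assigned value and sign come from a designated
reference group (the Overall group pooling all samples, by default).
Which network labels an edge's sign is a reporting convention, not part
of the method; it is explicit and configurable here.

## Preprocessing

Four filters, in order, before any correlation is computed:

1. **Dubious probes** (no gene, or several genes, for one probe set) are
   dropped.
2. **Probe→gene collapse**: for genes with several probe sets, the probe
   with the highest mean expression over *all* samples is kept and
   relabelled with the gene ID; equal means break toward the smallest
   probe ID for determinism.
3. **Detection filter**: a gene is kept when called Present in at least
   one sample. A stricter reading — Present in all replicates of at
   least one time point — is available when a sample→time-point table is
   supplied; the default is the permissive reading because replicate
   structure is not required input.
4. **Variation filter** (per analysis group): a gene is kept when its
   largest absolute deviation from its group mean exceeds `k_sd` (default
   1.0) standard deviations. The SD is, by default, the standard
   deviation of the pooled value distribution of all genes over the
   group's samples (`global_sd`), reading "one standard deviation across
   the dataset" as a dataset-level scale; a per-gene SD mode (`gene_sd`)
   is provided because the phrase is genuinely ambiguous. Neither mode is
   asserted as the original authors' choice.

Values are assumed log2-scale; `log2_transform` applies log2(x+1) on
ingest for linear-scale matrices. Filters only remove rows/columns and
never alter retained values, so each is idempotent.

## PCIT

For every unordered gene trio (x, y, z) the three first-order partial
correlations are computed,

    r_xy.z = (r_xy − r_xz r_yz) / sqrt((1 − r_xz²)(1 − r_yz²)),

clamped to [−1, 1]. The trio tolerance ε is the arithmetic mean of the
three partial/direct ratios (signed by default; an `absolute` ratio mode
averages |ratio|). A ratio whose direct correlation is zero within 1e−12
is skipped and ε averages the remainder. Edge (x, y) is flagged locally
non-significant in the trio when

    |r_xy| < |ε·r_xz|  and  |r_xy| < |ε·r_yz|   (strict <).

An edge survives iff its correlation is nonzero and no trio flags it.
With two genes there are no trios and any nonzero correlation is kept.
Trios containing a near-unit correlation (|r| ≥ 1 − 1e−12, duplicate
genes) are degenerate: they are skipped and counted, and the unit edge is
kept — such genes are simply never conditioned on.

The production kernel is a numba-compiled O(n³) trio loop with O(n²)
memory (practical to roughly 5,000 genes on one core, well beyond the
few-thousand-gene per-condition networks this pipeline targets). A naive
pure-Python triple loop (`pcit_mask_bruteforce`) is retained as an
independent oracle; tests and the acceptance script verify exact mask
agreement on random positive-definite correlation matrices.

Two behaviours worth knowing:

* **Closed form under exchangeability**: if all off-diagonal
  correlations equal ρ, every partial is ρ/(1+ρ), ε = 1/(1+ρ), and the
  flag test ρ < ρ/(1+ρ) is false — all edges are kept.
* **Sample-size noise floor**: with ~40 samples, truly independent gene
  pairs reach |r| ≳ 0.3 a few percent of the time, and two latent module
  factors can correlate empirically at |r| ≈ 0.2–0.4 in unlucky draws.
  Such pairs are *genuinely* correlated in the sample and PCIT keeps
  them; single-network null-pair survival therefore sits near 8% at this
  sample size. The AC intersection is what drives false landscape edges
  toward zero, because independent noise does not replicate across
  groups. A trio can only prune an indirect edge (x–y given z) when the
  common correlation ρ satisfies ρ²(1+ρ²) < 4/9, i.e. ρ ≲ 0.72; above
  that the indirect correlation is too strong relative to the tolerance.

## AC landscape

The landscape's edge set is the intersection of the unordered pair sets
of all supplied networks ("all six networks" generalises to "all supplied
networks"; the six-group design is the shipped default). Nodes are
exactly the edge endpoints. Per-network correlations are not required to
agree in sign; disagreeing edges are kept but flagged
`sign_consistent=false`, and classification uses the reference network's
sign. The sign/component report gives component sizes (decreasing, ties
by smallest gene ID) and negative/positive percentages rounded half-up to
one decimal.

## Module detection (MCODE) and the cut-off sweep

Correlation cut-offs are strict: the graph at cut-off c keeps edges with
|assigned r| > c (`none` keeps all); isolated nodes are dropped.

MCODE is re-implemented from its published description:

* **Vertex weight** = k_max × density of the highest-k-core subgraph of
  the vertex's closed neighborhood, where k_max is that subgraph's core
  index (a vertex inside K_n weighs n−1; a star's center weighs 1/3;
  isolated vertices weigh 0).
* **Expansion**: unvisited vertices seed modules in decreasing weight
  order (ties: smallest gene ID); breadth-first growth admits a neighbor
  when its weight ≥ seed_weight × (1 − vwp), to depth ≤ max_depth, and —
  once the module has at least two members — when it is adjacent to at
  least two of them. This local-connectivity guard keeps a single bridge
  edge between two dense cores from chaining them into one module (two
  K6 cliques joined by a bridge give identical vertex weights to the
  bridge endpoints, so no weight threshold alone can separate them);
  dense-module recovery is unaffected because genuine members touch many
  members. Each vertex joins at most one module.
* **Haircut** (default on) iteratively removes vertices with fewer than
  two in-module neighbors (the module's 2-core); trimmed vertices never
  joined a module and stay available to later seeds, which makes clique
  recovery independent of label order. **Fluff** (default off) adds
  boundary neighbors whose closed-neighborhood density exceeds
  `fluff_density`; only fluff can make modules overlap.
* **Score** = density × size; modules of size < 2 are discarded; output
  is sorted by decreasing score.

The sweep runs detection at a decreasing cut-off grid (default 0.95,
0.90, 0.85, 0.80, 0.70, none), tracks module lineages across adjacent
cut-offs by best Jaccard overlap (≥ 0.3; greedy best-first matching), and
chooses, per lineage, the cut-off giving the largest module among those
reached before a **connectivity jump** — the boundary/internal edge ratio
growing by ≥ `jump_factor` (default 2.0, including any growth from a zero
ratio) between adjacent cut-offs. Ties on size resolve toward the most
relaxed cut-off. The jump factor mechanises a by-eye "relax until the
module's connectivity into the surrounding network steps up" procedure;
the value 2.0 is this package's choice, exposed as a flag.

## Enrichment

Flat hypergeometric over-representation: for a module of size n inside a
universe of N genes and a term annotating K universe genes with k in the
module, the upper tail P(X ≥ k), X ~ Hypergeometric(N, K, n), is computed
in log space (lgamma + logsumexp; verified exact to 1e−12 relative
against rational direct summation for N ≤ 200). Terms are intersected
with the universe before counting; BH (default) or Bonferroni correction
is applied across all terms represented in the universe. The default
universe is the AC landscape node set (the reference set of the original
annotation tool is unknown, so the universe is an explicit, configurable
input). Ontology-hierarchy propagation is out of scope — supply
pre-propagated collections if hierarchy matters. The same statistic
serves as the two-set overlap test (observed overlap, expected
|A||B|/N, upper-tail p).

## Module-to-Regulator

For each module, every catalog TF present in the Overall correlation
matrix is scored by the mean of |r| over the module's genes, excluding
the TF itself from its own average (a member TF never scores from its
unit self-correlation); TFs rank by score (ties: smallest gene ID) and
the top 10 are reported. Mean |r| over all pairs — not restricted to
PCIT-significant pairs — is this package's concretization of
"relationships computed from the Overall network's correlation values";
a signed-mean statistic and a PCIT-masked variant are switchable. The
cross-tabulation partitions (module TFs ∪ top-10 TFs) into: in module and
top-ranked; in module only; top-ranked only.

## Cross-species comparison

A confident mapping links genes 1:1 via symbols annotated confidently on
both platforms, excluding any symbol with multiple candidates on either
side (conflicts are dropped and logged). All comparison statistics are
computed inside that mapping universe, since genes not measurable on both
platforms cannot overlap by construction. Node overlap is scored with the
hypergeometric upper tail on the universe; an edge is shared when its
mapped unordered pair is an edge in both landscapes (sign agreement
reported, not required); paired modules split into a-only / both / b-only
counts. Swapping the two landscapes transposes counts and leaves
p-values unchanged.

## Synthetic data generator

The generator emulates the multi-group single-tissue microarray design:

* **Groups**: five disjoint sample groups of 16, 19, 15, 20 and 40
  samples (a Callipyge-like, Normal-like, Prenatal, Postnatal and
  High-Low muscling design); the sixth analysis group, Overall, pools all
  110 samples at analysis time.
* **Modules**: per group g and module m active in g, a factor f_gs ~
  N(0,1) is drawn per sample; member i reads 8 + l_i·f_gs + N(0, σ) with
  σ = 0.5 and |l_i| = 1.0 by default; a configurable fraction of members
  (0.3 in the first default module) carries a negative loading, so the
  landscape contains negative edges. Defaults plant two always-active
  modules (30 and 15 members) and one module active in three of the five
  base groups (20 members). The expected within-module correlation is
  l_i l_j / sqrt((l_i²+σ²)(l_j²+σ²)) — 0.8 for the default regime — and
  the empirical correlation converges to it as samples grow.
* **Factors are independent across groups and samples** (no time-course
  autocorrelation): the method uses only within-group correlation, never
  temporal order, so autocorrelation would add realism without touching
  any tested behaviour.
* **Flat genes** (20% of genes) sit at 8.0 with σ/100 noise, so the
  one-SD variation filter provably removes them. **Background genes**
  carry pure N(0, σ) noise and model measured-but-unstructured
  transcripts.
* **Regulators**: each module adds one TF member at 0.9× the module
  loading, recorded in the ground truth, making module-to-regulator
  recovery a checkable claim.
* **Detection flags** are Present except a 5% random Absent fraction.
* **Species pairs**: two datasets are drawn with independent seeds; the
  first k modules occupy the same gene indices ("orthologs" under an
  index-based 1:1 mapping covering a configurable fraction, default
  90%); gene labels beyond the shared block are reversed in the second
  species so its private modules fall on the first species' background
  region and cannot alias.

What the generator does *not* emulate: probe-level effects, batch
effects, array-specific noise, heavy-tailed intensity distributions, and
correlated (structured) missingness of detection calls. Passing tests
therefore demonstrate correctness of the algorithms and the recovery
behaviour under an idealised factor model, not performance on real
arrays.

## Problem sizes and numerical choices

The shipped study uses 150 genes × 110 samples and six analysis groups —
large enough that every stage (filters, 6 PCIT networks, intersection,
sweep, enrichment, regulators, species comparison) runs in seconds while
leaving planted-structure recovery non-trivial. The PCIT kernel itself
is cubic and handles thousands of genes when needed.

Determinism: all randomness flows from a single integer seed through
`numpy.random.default_rng`; ties break lexicographically everywhere
(probe collapse, seeds, rankings, component order); rerunning the
pipeline with the same config yields byte-identical artifacts.

Known limitations: the sweep's jump factor and the Jaccard lineage
threshold (0.3) are heuristics for an undocumented manual procedure; the
regulator statistic is a minimal concretization; single-network PCIT
specificity degrades below ~40 samples (see the noise-floor note above),
which is intrinsic to correlation estimation, not to this implementation.
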