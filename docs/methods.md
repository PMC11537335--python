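# Methods

## Model and search

The unit of inference is a *proposal*: one (gene, cell type) assignment per
GWAS locus, for all loci jointly.  Each assignment is scored by eleven
boolean objective functions (OFs); a proposal's per-OF score is the fraction
of loci scored positive and its fitness is the unweighted arithmetic mean of
the eleven fractions.  Equal weighting is deliberate: the OFs are
incommensurable lines of evidence and the fitness is an average of
averages, bounded in [0, 1].  Six OFs depend only on a single element
(membership sets, promoter overlap, peak overlap, marker status); five are
pairwise — they ask whether the genes proposed at two *different* loci
interact, which is what makes the loci non-separable and motivates a global
search.

The search is a generational genetic algorithm.  One generation:

1. score and rank the population (ties are broken by a seeded shuffle before
   a stable sort, so equal-fitness proposals are permuted reproducibly);
2. split into `n_groups` equal rank groups and draw `2 x n_pairs` distinct
   parents without replacement, choosing a group with probability
   proportional to its weight (default 5:4:3:2:1, highest group first,
   renormalized over groups with members remaining), then a uniform member
   of that group's remaining pool;
3. each of the `n_pairs` pairs produces `children_per_pair` children by
   uniform crossover: an independent uniformly random subset of
   `floor(L/2)` loci comes from the first parent, the complement from the
   second;
4. every child element mutates its gene and its cell type in two independent
   Bernoulli(`mutation_rate`) events; resampling is uniform over the locus's
   candidate set / the cell catalog and may redraw the current value, so an
   *event* is not always a *change*;
5. one uniformly chosen member of the child generation's lowest rank group
   is replaced by the parent generation's elite.  This guarantees a
   monotone non-decreasing elite fitness.

The convergence diagnostic is the five-generation moving average of the
absolute percent change in mean fitness staying at or below 1% for ten
consecutive generations.  It is evaluated and logged but does not stop the
run: the run always consumes the full generation budget, and the generation
at which the rule first fired is recorded in the trace.

### Design choices where the procedure was open

* **Group sampling weights.**  Selection is "probability proportional to
  fitness rank" at group granularity; linear weights over the five groups
  are the simplest monotone scheme and are configurable
  (`GAConfig.group_weights`).
* **Parent count.**  `2 x n_pairs` distinct parents form `n_pairs` pairs
  (200 parents, 100 pairs under defaults), which is the only arithmetic
  consistent with 100 pairs x 10 children = population 1,000.
* **Elitism timing.**  The parent generation's elite replaces a random
  member of the *child* generation's lowest group, guaranteeing elite
  survival.
* **Mutation granularity.**  Per element and per field (gene, cell)
  independently, rather than one event per proposal; the realized event
  rate per element-field draw is exactly the configured rate.
* **Odd locus counts.**  The crossover mask takes `floor(L/2)` loci from the
  first parent.
* **RNG discipline.**  One seed per run, split into an initialization stream
  and one sub-stream per generation (`numpy` `SeedSequence.spawn`), so
  within-generation refactoring cannot silently change other generations.

## Objective-function semantics

* Candidate ("nearby") gene sets: the window spans the minimum to maximum
  SNP position of the locus (lead plus proxies) expanded by
  `window_expand` (200 kb) per side; if fewer than `min_flank_genes` (5)
  genes lie strictly upstream (gene end ≤ lead) or downstream (gene start >
  lead) of the lead inside the window, the window is minimally extended on
  that side to capture that many, stopping at the chromosome end.
  Membership is by span overlap with the half-open window; the output is
  sorted by genomic start.  Coordinates are 0-based half-open throughout;
  GFF3 input is converted on read.
* Promoters are strand-aware: `promoter_upstream` (1 kb) 5' of the TSS and
  `promoter_downstream` (100 bp) 3' of it in transcript orientation,
  clamped at zero.
* SNP-overlap OFs (promoter, chromatin) test *every* SNP of the locus by
  default (`snp_scope="all"`); a lead-only variant is a config switch.
* "Common" peaks are identical intervals accessible in two or more cell
  types; `isCommonATAC` additionally requires the proposed cell type to be
  among the peak's cell types (the OF informs cell-type choice), with a
  cell-agnostic variant behind `common_atac_cell_specific=False`.
* Marker genes and marker peaks are thresholded once at load time
  (p ≤ 0.05 and log2FC ≥ 0.25 for expression markers; peak marker flags
  encode the upstream FDR ≤ 0.05 / log2FC ≥ 0.25 call), so the OFs are pure
  membership tests.
* Pairwise OFs pair only *different* loci (no self-pairs: two loci proposing
  the same gene contribute nothing through a self-edge).  Protein-edge OFs
  use edges with experimental evidence strictly > 0; ligand-receptor and
  lncRNA-protein pairs match in either orientation.  `isIntraPPI` requires
  both genes outside the ligand-receptor universe and equal cell types;
  `isInterPPI` requires a ligand-receptor pair and unequal cell types;
  `isMarkerPPI` requires the marker-gene OF to hold at *both* loci of the
  pair (single-sided variant behind `marker_ppi_both_cells=False`).

Two scoring paths exist: object-level functions with these definitions, and
a vectorized engine over integer-coded populations (per-element OFs as table
lookups, pairwise OFs as boolean pair grids chunked over the population).
The test suite holds both paths to each other and to a brute-force O(n²)
pair enumeration.

## Consensus, confidence, diversity

The consensus takes the modal gene and, independently, the modal cell type
per locus across the final population (joint-mode variant behind
`consensus_joint_mode`); ties are broken by higher per-element OF support,
then lexicographically, and logged.  The consensus proposal is scored like
any other — it can (but need not) beat the elite, because the population can
hold mutually exclusive partial solutions whose per-locus modes combine.

The high-confidence vote threshold is the largest count `t` such that at
least `confidence_sensitivity` (80%) of calibration loci have gene frequency
≥ `t`, where calibration loci are those whose external reference call
(score ≥ 0.7) names the same gene as the consensus.  One shared threshold is
applied to gene and cell frequencies.

Call diversity at a locus is the Gini-Simpson index `1 − Σ p_i²` of consensus
top-gene calls pooled across independent runs (one call per run; pooling all
proposals of all runs is available but not the default).  "Stable" loci
satisfy Gini-Simpson ≤ 0.5 *and* distinct gene count ≤ 2.

## Foreground-vs-control statistics

The procedure names no specific posterior machinery, so the package uses the
two standard conjugate/nonparametric choices and documents them: proportions
are compared with independent Beta(1 + k, 1 + n − k) posteriors (uniform
prior) differenced over Monte-Carlo draws (default 10,000); score sets with
the Bayesian bootstrap (Dirichlet(1,...,1) weighted means per draw).
Enrichment means zero is excluded from the central 95% interval of the
difference draws; the exceedance probability is one-sided P(diff ≤ 0).
Per-locus support contrasts use the two-sided Wilcoxon rank-sum test (exact
enumeration for untied samples below 8 per side, normal approximation with
tie correction otherwise; identical constant samples give p = 1 by
convention) with Benjamini–Hochberg adjustment across loci — the standard
choice where the correction method is unstated.  Distribution equality uses
the two-sample Kolmogorov–Smirnov test.  Per-OF enrichment treats runs as
replicates (each run contributing its final-generation OF score); a pooled
proportion mode is available through `compare_proportions`.

## Network analysis

The interaction graph induced on proposed/consensus genes keeps edges with
combined score ≥ 0.4 — deliberately a different, looser filter than the
experimental-evidence floor used by the OFs, matching the two distinct
filters of the procedure.  A *subgraph* is a connected component of size
≥ 2; singletons are reported separately.  Multiple loci proposing the same
gene collapse to one node; cell-type annotation on nodes is decorative.
Downsampled comparisons re-sample `n_sub` loci without replacement from each
foreground run, rebuild the induced graph, and compare largest-component
sizes against controls with the KS test and the Bayesian bootstrap.

## The synthetic-data generator

`generate_scenario` emulates the statistical structure of the real inputs,
not their biology.  Each locus occupies its own chromosome with a regular
tiling of genes (default 10 genes, 20 kb long, 60 kb apart; the last gene of
each block is a lncRNA), the lead SNP in the central intergenic gap, so the
candidate window rule yields known, uniform candidate sets.  For planted
loci one candidate is the true gene and one catalog label the true cell;
independently per evidence family, with probability `signal_rate` (default
0.9) the true element receives the corresponding annotation (membership,
promoter-overlapping proxy SNP, cell-specific peak over a proxy, shared peak
whose cell set contains the true cell plus one other, expression-marker
row).  True genes are wired into a single interaction ring with random
chords (`extra_edge_prob` 0.3); a fraction of adjacent pairs are designated
ligand-receptor (`lr_pair_rate` 0.15) and lncRNA true genes receive
lncRNA-protein pairs.  Every gene and locus also receives background
annotation at `noise_rate` (default 0.05), including sub-threshold marker
rows that exercise load-time filtering.  A reference-call table emulates an
external locus-to-gene score (informative at 60% of planted loci).  The
default scenario is 40 loci x 10 genes x 8 cell types at signal 0.9 / noise
0.05 — large enough that pairwise OFs matter, small enough that ten full
default-configuration runs finish in minutes.

`generate_matched_null` mirrors the control-set construction structurally:
each control set has the foreground's locus count on fresh chromosome blocks
with identical gene tiling (hence matched candidate-set sizes and gene
density), added to the *shared* annotation universe with background-rate
evidence only.  Candidate overlap with the foreground is zero by
construction, satisfying the low-similarity requirement; variant-level
matching criteria (allele frequency, LD proxy counts) are population-genetic
properties outside the generator's scope and orthogonal to the algorithmic
contract being tested.

Signal is planted at the (gene, cell) level because that is the search
space; SNP positions exist only to exercise the promoter/peak overlap code
paths.  Consequences for interpretation: passing recovery tests shows the
optimizer and scoring machinery work when evidence concentrates on a true
assignment at the stated rates — it does not certify performance on real
data, where evidence families are correlated, candidate windows overlap,
LD structure is real, and the truth is not a single planted assignment.
The `distinct_true_cells` option assigns each planted locus a different true
cell type; it is used by exhaustive benchmarks where the global optimum must
be provably unique (with shared cell types, same-cell-type interaction
gains can in principle tie a one-element deviation).

## Numerical choices and degenerate inputs

* Fitness comparisons in ranking are exact float comparisons; ties are
  resolved by the seeded permutation described above.
* Candidate padding in the vectorized scorer reuses the first candidate and
  is never drawn (mutation resamples via `floor(u * n_candidates)`).
* `select_pairs` renormalizes group weights over non-empty groups when a
  pool is exhausted; requesting more parents than proposals is an error.
* A locus with a single candidate gene is legal: initialization and mutation
  are forced draws.
* Zero-count inputs error in `gini_simpson`; empty score sets and zero-n
  proportions error in the comparison functions; an empty candidate set or
  an unresolved gene/cell label is a hard load-time error naming the
  offender.
* Config validation enforces `population_size == n_pairs x
  children_per_pair` and divisibility by `n_groups` before any run starts.

## Problem sizes used by the automated checks

The test suite and acceptance script run entirely on generated data: the
default 40-locus scenario for recovery and enrichment checks (ten and eight
full default-configuration runs respectively), an exhaustively enumerable
3-locus x 4-gene x 4-cell instance (~4,000 proposals) for optimality checks,
10^6 element draws for operator-rate recovery, and 1,000 replicates for null
calibration.  These sizes were chosen so each behavioural property is
measured with comfortable statistical margin while the whole suite stays
fast.

## Known limitations

* Proxy SNPs are grouped under their lead; evidence from any proxy supports
  the locus, which can mask which SNP is causal.
* Equal OF weighting means an uninformative objective dilutes fitness
  rather than being down-weighted.
* The Bayesian machinery is intentionally simple (uniform priors, Monte
  Carlo differencing); no hierarchical pooling across loci or runs.
* The generator does not simulate LD, allele frequencies, read-level
  single-cell data, or overlapping candidate windows.
* Runs-as-replicates enrichment treats each GA run as one observation;
  with few runs the credible intervals are wide.
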