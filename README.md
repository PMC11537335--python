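# locusga

Genetic-algorithm assignment of a **gene and a cell type to every GWAS locus
simultaneously**, scored against boolean objective functions built from gene
membership sets, promoter overlap, single-nucleus chromatin and expression
markers, and protein-interaction networks — plus the downstream consensus,
foreground-vs-control enrichment, and interaction-subgraph analyses.

## The problem

Most trait-associated variants are non-coding, and a single association locus
can harbor dozens of plausible target genes in many possible cell types.
Evidence that discriminates among those hypotheses is scattered across
heterogeneous resources: gene-level association sets, curated disease genes,
promoter annotation, cell-type-resolved open chromatin and expression
markers, and protein/ligand-receptor/lncRNA interaction databases.  Crucially,
some of that evidence is *pairwise* — two loci whose candidate genes encode
interacting proteins support each other — so loci cannot be interpreted one
at a time.  With `L` loci and ~10 candidate genes each, the joint hypothesis
space (at least `10^L` combinations) rules out exhaustive search.

## The model

A **proposal** assigns one `(gene, cell type)` pair to each of the `L` loci.
Eleven boolean **objective functions** (OFs) score each element:

| objective | evidence | informs |
|---|---|---|
| isMAGMAgene | gene in a GWAS gene-level association set | gene |
| isCancerGene | gene in a curated disease gene set | gene |
| isPPI | protein interaction (experimental evidence > 0) with a gene proposed at another locus | gene |
| isLPI | lncRNA-protein pair with another locus's gene | gene |
| isPromoter | a locus SNP in the proposed gene's promoter (1 kb up / 100 bp down of the TSS) | gene |
| isCommonATAC | a locus SNP in an accessible peak shared by ≥ 2 cell types incl. the proposed one | cell |
| isMarkerATAC | a locus SNP in a cell-type-specific peak of the proposed cell type | cell |
| isMarkerGene | the gene is an expression marker of the proposed cell type | both |
| isMarkerPPI | interaction where both elements are marker-valid | both |
| isIntraPPI | interaction between non-ligand/receptor genes, same cell type | both |
| isInterPPI | ligand-receptor pair across different cell types | both |

A proposal's per-OF score is the **fraction of positive loci** and its
**fitness** is the unweighted mean of the eleven fractions,

```
fitness(P) = (1/11) Σ_k  (1/L) Σ_i  OF_k(locus_i, gene_i, cell_i).
```

The genetic algorithm evolves a population of 1,000 proposals for 200
generations: rank into five equal fitness groups, draw 200 distinct parents
with group-weighted probability (5:4:3:2:1), form 100 pairs, produce 10
children per pair by uniform half/half locus crossover, mutate each child's
gene and cell type independently at 1% per element, and preserve the elite by
replacing a random member of the child generation's lowest group.  A
convergence diagnostic (five-generation smoothed |% change| of mean fitness
≤ 1% for 10 consecutive generations) is reported; the run always uses the
full generation budget.

Downstream, the **consensus** (per-locus modal gene and cell type across the
final population) is scored, a high-confidence vote threshold is calibrated
against an external locus-to-gene reference (retaining 80% of agreeing
high-score loci), cross-run call diversity is summarized by the Gini-Simpson
index, foreground-vs-control enrichment uses Monte-Carlo credible differences
(Beta posteriors for proportions, Bayesian bootstrap for score sets), and the
interaction graph induced on consensus genes (combined score ≥ 0.4) is
decomposed into subgraphs whose size distributions are compared between
foreground and matched controls.

A fully parameterized synthetic-data generator (`locusga.simulate`) produces
self-consistent input bundles with a planted `(gene, cell)` truth and matched
control locus sets, so the entire pipeline is testable without external data.

## Worked example

```python
from locusga import LocusAssignmentModel, GAConfig
from locusga.simulate import generate_scenario, ScenarioParams

scenario = generate_scenario(ScenarioParams(n_loci=20, genes_per_locus=8,
                                            n_cell_types=6), seed=7)
config = GAConfig(population_size=500, n_pairs=50, children_per_pair=10,
                  n_generations=80)
model = LocusAssignmentModel(scenario.bundle, config)
result = model.fit(seed=7)
print(result.summary())
```

```
Locus assignment by genetic algorithm
=====================================================
loci:     20    population: 500
generations: 80    seed: 7
termination rule first met: 50
-----------------------------------------------------
elite fitness:     0.7773
mean fitness:      0.7641
consensus fitness: 0.7773
-----------------------------------------------------
objective         population   consensus
isMAGMAgene            0.942       0.950
isCancerGene           0.893       0.900
isPPI                  0.990       1.000
isLPI                  0.393       0.400
isPromoter             0.892       0.900
isCommonATAC           0.886       0.900
isMarkerATAC           0.877       0.900
isMarkerGene           0.965       1.000
isMarkerPPI            0.964       1.000
isIntraPPI             0.294       0.300
isInterPPI             0.308       0.300
=====================================================
```

The trace converged by generation 50; the consensus proposal matches the
elite's fitness here and recovers the planted gene at all 20 loci.
Calibrating the confidence threshold against the bundled reference calls:

```python
calls = result.consensus_calls()
threshold = result.calibrate_confidence()   # -> 494 (votes out of 500)
```

means a locus is called high-confidence when at least 494 of the 500 final
proposals vote for its consensus gene.  Per-objective rows read as fractions
of loci scored positive — e.g. `isPPI = 1.000` for the consensus says every
locus's gene has an experimental protein interaction with a gene proposed at
another locus.

The same workflow is available from the shell:

```sh
locusga simulate --seed 5 --out data/ --n-control-sets 10
locusga run --data data/ --out runs/fg1 --seed 1
locusga consensus --runs runs/fg1 --data data/ \
    --reference data/reference_calls.tsv --out consensus.tsv
locusga compare --foreground runs/fg1 --background runs/bg1 --out enrichment.tsv
locusga network --consensus consensus.tsv --edges data/network.tsv --out graph/
```

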