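"""Synthetic input bundles with a planted (gene, cell type) truth.

The generator emulates the statistical structure of the real inputs — gene
membership sets, promoter and accessible-peak SNP overlap, cell-type marker
genes and an interaction network — without any external download.  Each
locus lives on its own chromosome with a regular tiling of genes; the lead
SNP sits mid-tiling so the candidate window captures a fixed, known gene
set.  For *planted* loci one candidate is designated the true gene and one
catalog label the true cell type; evidence is attached to that (gene, cell)
pair independently per evidence family at ``signal_rate``, while every gene
and locus also receives background annotation at ``noise_rate``.  True genes
are wired into a single interaction ring (plus random chords) so that the
pairwise objectives reward the planted solution.

Matched control sets mirror the foreground structurally: the same number of
loci, identical candidate-set sizes and gene density, the same annotation
universe extended with control genes carrying background-rate evidence only,
and zero candidate overlap with the foreground.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .candidates import nearby_gene_set
from .config import GAConfig
from .io import write_bundle, write_loci
from .types import CellTypeCatalog, DataBundle, GeneRecord, InteractionNetwork, Locus

__all__ = [
    "DEFAULT_CELL_TYPES",
    "ScenarioParams",
    "SyntheticTruth",
    "Scenario",
    "generate_scenario",
    "generate_matched_null",
    "write_truth",
    "read_truth",
]

#: default cell-type labels (a normal-breast-style catalog)
DEFAULT_CELL_TYPES = (
    "luminal_hr_pos",
    "luminal_hr_neg",
    "basal",
    "blood_endothelial",
    "lymphatic_endothelial",
    "vascular_accessory",
    "adipocyte",
    "fibroblast",
    "myeloid",
    "lymphoid",
)


@dataclass
class ScenarioParams:
    n_loci: int = 40
    genes_per_locus: int = 10
    n_cell_types: int = 8
    planted_fraction: float = 1.0
    #: per-evidence-family probability that the true (gene, cell) element is annotated
    signal_rate: float = 0.9
    #: background annotation rate for every gene / locus
    noise_rate: float = 0.05
    #: probability that a planted locus's true gene is its lncRNA (drives the
    #: lncRNA-protein pair objective)
    lnc_fraction: float = 0.1
    #: chord probability between non-adjacent true genes beyond the ring
    extra_edge_prob: float = 0.3
    #: probability that a ring-adjacent true-gene pair is ligand-receptor
    lr_pair_rate: float = 0.15
    #: fraction of loci receiving an informative external reference call
    reference_coverage: float = 0.6
    gene_length: int = 20_000
    gene_spacing: int = 60_000
    #: assign each planted locus a distinct true cell type (requires
    #: n_cell_types >= number of planted loci); useful for exhaustive
    #: benchmarking where the optimum must be unambiguous
    distinct_true_cells: bool = False

    def validate(self) -> None:
        if self.genes_per_locus < 2:
            raise ValueError("genes_per_locus must be >= 2")
        if self.n_cell_types < 1:
            raise ValueError("need at least one cell type")
        if not 0.0 <= self.planted_fraction <= 1.0:
            raise ValueError("planted_fraction must lie in [0, 1]")
        for name in ("signal_rate", "noise_rate", "lnc_fraction", "extra_edge_prob",
                     "lr_pair_rate", "reference_coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_loci < 1:
            raise ValueError("need at least one locus")


@dataclass
class SyntheticTruth:
    """Planted ground truth for one scenario."""

    true_gene: dict[str, str]  # locus_id -> gene_id (planted loci only)
    true_cell: dict[str, str]
    planted: dict[str, bool]  # locus_id -> planted flag (all loci)
    planted_edges: list[tuple[str, str]]
    params: ScenarioParams
    seed: int

    @property
    def planted_loci(self) -> list[str]:
        return [l for l, f in self.planted.items() if f]


@dataclass
class Scenario:
    bundle: DataBundle
    truth: SyntheticTruth
    params: ScenarioParams
    config: GAConfig
    #: marker-table rows as written to markers.tsv (includes sub-threshold rows)
    marker_rows: pd.DataFrame = field(repr=False, default=None)


def _tile_block(
    chrom: str, prefix: str, params: ScenarioParams, rng: np.random.Generator
) -> list[GeneRecord]:
    """One chromosome block: a regular tiling of genes, the last one a lncRNA."""
    genes = []
    for j in range(params.genes_per_locus):
        start = 100_000 + j * params.gene_spacing
        end = start + params.gene_length
        strand = "+" if rng.random() < 0.5 else "-"
        biotype = "lncRNA" if j == params.genes_per_locus - 1 else "protein_coding"
        gid = f"{prefix}_{j}"
        genes.append(GeneRecord(gid, gid, chrom, start, end, strand, biotype))
    return genes


def _lead_position(block: list[GeneRecord], params: ScenarioParams) -> int:
    """Mid-gap position between the two central genes of a block."""
    mid = params.genes_per_locus // 2
    gap_start = block[mid - 1].end if mid >= 1 else block[0].start - 20_000
    return max(0, (gap_start + block[mid].start) // 2)


def _promoter_snp(gene: GeneRecord, config: GAConfig) -> int:
    if gene.strand == "+":
        return max(0, gene.start - config.promoter_upstream // 2)
    return gene.end + config.promoter_upstream // 2


class _UniverseBuilder:
    """Accumulates genes, peaks, sets, markers and edges across blocks."""

    def __init__(self, params: ScenarioParams, config: GAConfig, catalog: CellTypeCatalog):
        self.params = params
        self.config = config
        self.catalog = catalog
        self.genes: list[GeneRecord] = []
        self.peak_rows: list[dict] = []
        self.marker_rows: list[dict] = []
        self.magma: set[str] = set()
        self.cancer: set[str] = set()
        self.edges: list[tuple[str, str, float, float]] = []
        self.lr_pairs: list[tuple[str, str]] = []
        self.lpi_pairs: list[tuple[str, str]] = []

    def add_background(self, gene_ids: Sequence[str], rng: np.random.Generator) -> None:
        """Background-rate annotation over a set of genes."""
        p, noise = self.params, self.params.noise_rate
        cells = self.catalog.labels
        for g in gene_ids:
            if rng.random() < noise:
                self.magma.add(g)
            if rng.random() < noise:
                self.cancer.add(g)
            if rng.random() < noise:
                self.marker_rows.append(
                    {
                        "gene_id": g,
                        "cell_type": cells[rng.integers(len(cells))],
                        "p": float(rng.uniform(0, self.config.marker_gene_p)),
                        "log2fc": float(rng.uniform(self.config.marker_gene_lfc, 2.0)),
                    }
                )
            if rng.random() < noise:  # sub-threshold row, dropped at load
                self.marker_rows.append(
                    {
                        "gene_id": g,
                        "cell_type": cells[rng.integers(len(cells))],
                        "p": float(rng.uniform(0.5, 1.0)),
                        "log2fc": float(rng.uniform(0.0, 0.1)),
                    }
                )
            if rng.random() < noise:
                partner = gene_ids[rng.integers(len(gene_ids))]
                if partner != g:
                    exp_s = 0.0 if rng.random() < 0.3 else float(rng.uniform(0.1, 0.9))
                    comb = float(rng.uniform(0.2, 0.95))
                    self.edges.append((g, partner, exp_s, comb))
            if rng.random() < noise / 2:
                partner = gene_ids[rng.integers(len(gene_ids))]
                if partner != g:
                    self.lr_pairs.append((g, partner))

    def add_background_peaks(self, loci: Sequence[Locus], rng: np.random.Generator) -> None:
        """Background accessible peaks dropped near random locus SNPs."""
        noise = self.params.noise_rate
        cells = self.catalog.labels
        for locus in loci:
            if rng.random() < noise:
                pos = locus.positions[rng.integers(len(locus.positions))]
                self.peak_rows.append(
                    {
                        "chrom": locus.chrom,
                        "start": max(0, pos - 250),
                        "end": pos + 250,
                        "cell_type": cells[rng.integers(len(cells))],
                        "is_marker": 1,
                    }
                )
            if rng.random() < noise:
                pos = locus.positions[rng.integers(len(locus.positions))]
                picked = rng.choice(len(cells), size=2, replace=False)
                for ci in picked:
                    self.peak_rows.append(
                        {
                            "chrom": locus.chrom,
                            "start": max(0, pos - 250),
                            "end": pos + 250,
                            "cell_type": cells[ci],
                            "is_marker": 0,
                        }
                    )
            # an open region away from every SNP, for realism
            self.peak_rows.append(
                {
                    "chrom": locus.chrom,
                    "start": 10_000,
                    "end": 10_500,
                    "cell_type": cells[rng.integers(len(cells))],
                    "is_marker": 1,
                }
            )


def generate_scenario(
    params: Optional[ScenarioParams] = None,
    seed: int = 0,
    config: Optional[GAConfig] = None,
) -> Scenario:
    """Generate a self-consistent foreground bundle with planted truth.

    Fully determined by ``seed``; writing the bundle twice from the same seed
    is byte-identical.
    """
    params = params or ScenarioParams()
    params.validate()
    config = config or GAConfig()
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    if params.n_cell_types <= len(DEFAULT_CELL_TYPES):
        labels = list(DEFAULT_CELL_TYPES[: params.n_cell_types])
    else:
        labels = [f"cell_{i}" for i in range(params.n_cell_types)]
    catalog = CellTypeCatalog(labels)

    ub = _UniverseBuilder(params, config, catalog)
    blocks: list[list[GeneRecord]] = []
    loci: list[Locus] = []
    for i in range(params.n_loci):
        block = _tile_block(f"chr{i + 1}", f"G{i + 1}", params, rng)
        blocks.append(block)
        ub.genes.extend(block)
        lead = _lead_position(block, params)
        locus = Locus(f"rs{i + 1:04d}", block[0].chrom, lead,
                      proxies=[(f"rs{i + 1:04d}_p0", lead + 1_000)])
        loci.append(locus)

    # candidate sets via the standard window rule
    for locus in loci:
        locus.candidate_genes = nearby_gene_set(locus, ub.genes, config)

    # choose planted loci and their truth
    n_planted = int(round(params.planted_fraction * params.n_loci))
    planted_idx = sorted(rng.choice(params.n_loci, size=n_planted, replace=False).tolist())
    planted_set = set(planted_idx)

    true_gene: dict[str, str] = {}
    true_cell: dict[str, str] = {}
    planted_flag: dict[str, bool] = {}

    if params.distinct_true_cells and n_planted > params.n_cell_types:
        raise ValueError("distinct_true_cells requires n_cell_types >= planted loci")
    distinct_cells = (
        rng.permutation(params.n_cell_types)[:n_planted] if params.distinct_true_cells else None
    )

    for rank, i in enumerate(planted_idx):
        locus = loci[i]
        cands = locus.candidate_genes
        lnc = [g for g in cands if g.endswith(f"_{params.genes_per_locus - 1}")]
        if lnc and rng.random() < params.lnc_fraction:
            tg = lnc[0]
        else:
            protein = [g for g in cands if g not in lnc]
            tg = protein[rng.integers(len(protein))]
        tc = (
            catalog[int(distinct_cells[rank])]
            if distinct_cells is not None
            else catalog[rng.integers(len(catalog))]
        )
        true_gene[locus.lead_snp_id] = tg
        true_cell[locus.lead_snp_id] = tc
    for locus in loci:
        planted_flag[locus.lead_snp_id] = locus.lead_snp_id in {
            loci[i].lead_snp_id for i in planted_set
        }

    gene_by_id = {g.gene_id: g for g in ub.genes}

    # plant per-element evidence at the signal rate
    for i in planted_idx:
        locus = loci[i]
        lid = locus.lead_snp_id
        tg, tc = true_gene[lid], true_cell[lid]
        gene = gene_by_id[tg]
        if rng.random() < params.signal_rate:
            ub.magma.add(tg)
        if rng.random() < params.signal_rate:
            ub.cancer.add(tg)
        if rng.random() < params.signal_rate:  # promoter-overlap proxy SNP
            locus.proxies.append((f"{lid}_prom", _promoter_snp(gene, config)))
        if rng.random() < params.signal_rate:  # cell-type-specific peak over a proxy
            pos = locus.lead_pos + 5_000
            locus.proxies.append((f"{lid}_atac", pos))
            ub.peak_rows.append(
                {"chrom": locus.chrom, "start": pos - 250, "end": pos + 250,
                 "cell_type": tc, "is_marker": 1}
            )
        if rng.random() < params.signal_rate:  # shared (common) peak over a proxy
            pos = max(0, locus.lead_pos - 5_000)
            locus.proxies.append((f"{lid}_common", pos))
            others = [c for c in catalog.labels if c != tc]
            partner = others[rng.integers(len(others))]
            for c in (tc, partner):
                ub.peak_rows.append(
                    {"chrom": locus.chrom, "start": pos - 250, "end": pos + 250,
                     "cell_type": c, "is_marker": 0}
                )
        if rng.random() < params.signal_rate:  # expression marker for the true pair
            ub.marker_rows.append(
                {"gene_id": tg, "cell_type": tc, "p": 1e-4, "log2fc": 1.5}
            )

    # wire true genes into one interaction component: a ring plus chords
    planted_ids = [loci[i].lead_snp_id for i in planted_idx]
    planted_edges: list[tuple[str, str]] = []
    tgs = [true_gene[l] for l in planted_ids]
    if len(tgs) >= 2:
        for a, b in zip(tgs, tgs[1:] + tgs[:1]):
            if a != b and len(tgs) > 2 or (a != b and len(tgs) == 2):
                planted_edges.append((a, b))
        if len(tgs) == 2:  # ring over two nodes collapses to one edge
            planted_edges = planted_edges[:1]
        for a, b in planted_edges:
            ub.edges.append((a, b, float(rng.uniform(0.5, 0.9)), float(rng.uniform(0.6, 0.95))))
        n_chord = 0
        for _ in range(len(tgs)):
            if rng.random() < params.extra_edge_prob:
                i, j = rng.choice(len(tgs), size=2, replace=False)
                if tgs[i] != tgs[j]:
                    ub.edges.append(
                        (tgs[i], tgs[j], float(rng.uniform(0.5, 0.9)), float(rng.uniform(0.6, 0.95)))
                    )
                    planted_edges.append((tgs[i], tgs[j]))
                    n_chord += 1
        # ligand-receptor designation on some ring-adjacent pairs
        for a, b in list(planted_edges):
            if rng.random() < params.lr_pair_rate:
                ub.lr_pairs.append((a, b))
        # lncRNA-protein pairs between planted lncRNA true genes and other true genes
        for idx, g in enumerate(tgs):
            if gene_by_id[g].biotype == "lncRNA" and len(tgs) >= 2:
                if rng.random() < params.signal_rate:
                    others = [t for t in tgs if t != g]
                    ub.lpi_pairs.append((g, others[rng.integers(len(others))]))

    # background annotation over the whole universe
    all_gene_ids = [g.gene_id for g in ub.genes]
    ub.add_background(all_gene_ids, rng)
    ub.add_background_peaks(loci, rng)

    # reference calls emulating an external locus-to-gene score table
    ref_rows = []
    for locus in loci:
        lid = locus.lead_snp_id
        if rng.random() < params.reference_coverage and planted_flag[lid]:
            if rng.random() < 0.85:
                ref_rows.append({"lead_snp_id": lid, "gene_id": true_gene[lid],
                                 "score": float(rng.uniform(0.7, 0.99))})
            else:
                g = locus.candidate_genes[rng.integers(len(locus.candidate_genes))]
                ref_rows.append({"lead_snp_id": lid, "gene_id": g,
                                 "score": float(rng.uniform(0.7, 0.99))})
        else:
            g = locus.candidate_genes[rng.integers(len(locus.candidate_genes))]
            ref_rows.append({"lead_snp_id": lid, "gene_id": g,
                             "score": float(rng.uniform(0.0, 0.69))})

    marker_rows = pd.DataFrame(
        ub.marker_rows, columns=["gene_id", "cell_type", "p", "log2fc"]
    ).sort_values(["gene_id", "cell_type", "p"], kind="stable").reset_index(drop=True)
    peaks = pd.DataFrame(
        ub.peak_rows, columns=["chrom", "start", "end", "cell_type", "is_marker"]
    ).sort_values(["chrom", "start", "end", "cell_type"], kind="stable").reset_index(drop=True)

    markers = {
        (r.gene_id, r.cell_type)
        for r in marker_rows.itertuples(index=False)
        if r.p <= config.marker_gene_p and r.log2fc >= config.marker_gene_lfc
    }
    bundle = DataBundle(
        loci=loci,
        genes=gene_by_id,
        catalog=catalog,
        peaks=peaks,
        markers=markers,
        gene_sets={"magma": ub.magma, "cancer": ub.cancer},
        network=InteractionNetwork(ub.edges, ub.lr_pairs, ub.lpi_pairs),
        reference_calls=pd.DataFrame(ref_rows, columns=["lead_snp_id", "gene_id", "score"]),
    )
    truth = SyntheticTruth(
        true_gene=true_gene,
        true_cell=true_cell,
        planted=planted_flag,
        planted_edges=planted_edges,
        params=params,
        seed=seed,
    )
    return Scenario(bundle=bundle, truth=truth, params=params, config=config,
                    marker_rows=marker_rows)


def generate_matched_null(
    scenario: Scenario, n_sets: int = 10, seed: int = 1
) -> list[DataBundle]:
    """Structurally matched control bundles without planted signal.

    Each control set has the foreground's locus count with identical
    candidate-set sizes and gene density, drawn on fresh chromosome blocks
    added to the shared annotation universe; all evidence over control genes
    is assigned at the background rate only, so candidate overlap with the
    foreground is zero.
    """
    params = scenario.params
    config = scenario.config
    fg = scenario.bundle
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])

    ub = _UniverseBuilder(params, config, fg.catalog)
    bundles: list[DataBundle] = []
    all_ctrl_loci: list[list[Locus]] = []
    for s in range(n_sets):
        ctrl_loci: list[Locus] = []
        for i in range(params.n_loci):
            chrom = f"ctrl{s + 1}_{i + 1}"
            block = _tile_block(chrom, f"C{s + 1}_{i + 1}", params, rng)
            ub.genes.extend(block)
            lead = _lead_position(block, params)
            lid = f"ctrl{s + 1}_rs{i + 1:04d}"
            jitter = int(rng.integers(-2_000, 2_000))
            ctrl_loci.append(
                Locus(lid, chrom, max(0, lead + jitter), proxies=[(f"{lid}_p0", lead + 1_000)])
            )
        all_ctrl_loci.append(ctrl_loci)

    ctrl_gene_ids = [g.gene_id for g in ub.genes]
    ub.add_background(ctrl_gene_ids, rng)
    for ctrl_loci in all_ctrl_loci:
        ub.add_background_peaks(ctrl_loci, rng)

    # shared universe: foreground annotation plus background-rate control annotation
    genes = dict(fg.genes)
    genes.update({g.gene_id: g for g in ub.genes})
    peaks = pd.concat(
        [fg.peaks, pd.DataFrame(ub.peak_rows, columns=["chrom", "start", "end", "cell_type", "is_marker"])],
        ignore_index=True,
    ).sort_values(["chrom", "start", "end", "cell_type"], kind="stable").reset_index(drop=True)
    markers = set(fg.markers) | {
        (r["gene_id"], r["cell_type"])
        for r in ub.marker_rows
        if r["p"] <= config.marker_gene_p and r["log2fc"] >= config.marker_gene_lfc
    }
    gene_sets = {
        "magma": fg.gene_sets["magma"] | ub.magma,
        "cancer": fg.gene_sets["cancer"] | ub.cancer,
    }
    network = InteractionNetwork(
        fg.network.edge_list() + ub.edges,
        [tuple(sorted(p)) for p in fg.network.lr_pairs] + ub.lr_pairs,
        [tuple(sorted(p)) for p in fg.network.lpi_pairs] + ub.lpi_pairs,
    )

    all_genes = list(genes.values())
    for ctrl_loci in all_ctrl_loci:
        for locus in ctrl_loci:
            locus.candidate_genes = nearby_gene_set(locus, all_genes, config)
        bundles.append(
            DataBundle(
                loci=ctrl_loci,
                genes=genes,
                catalog=fg.catalog,
                peaks=peaks,
                markers=markers,
                gene_sets=gene_sets,
                network=network,
                reference_calls=None,
            )
        )
    return bundles


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    rows = []
    for lid, is_planted in truth.planted.items():
        rows.append(
            {
                "locus": lid,
                "true_gene": truth.true_gene.get(lid, ""),
                "true_cell": truth.true_cell.get(lid, ""),
                "planted": int(is_planted),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"locus": str, "true_gene": str, "true_cell": str},
                       keep_default_na=False)
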