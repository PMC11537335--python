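"""The eleven boolean objective functions (OFs) and proposal scoring.

Each OF tests one line of evidence for a proposed (gene, cell type) element:

* gene membership: ``isMAGMAgene`` (GWAS gene-level association set),
  ``isCancerGene`` (curated cancer gene set);
* pairwise interaction between loci: ``isPPI`` (experimental protein-protein
  edge with the gene proposed at another locus), ``isLPI`` (lncRNA-protein
  pair), ``isInterPPI`` (ligand-receptor pair across *different* proposed
  cell types), ``isIntraPPI`` (protein-protein edge between non-ligand/
  receptor genes with the *same* proposed cell type), ``isMarkerPPI``
  (protein-protein edge where both elements' genes are expression markers of
  their proposed cell types);
* position: ``isPromoter`` (a locus SNP falls in the proposed gene's
  promoter);
* chromatin: ``isCommonATAC`` (a locus SNP in an accessible region shared by
  several cell types including the proposed one), ``isMarkerATAC`` (a locus
  SNP in a cell-type-specific accessible region of the proposed cell type);
* expression: ``isMarkerGene`` (the proposed gene is a marker of the
  proposed cell type).

A proposal's per-OF score is the fraction of loci scored positive and its
fitness is the unweighted mean of the eleven fractions.

Two scoring paths are provided: element/proposal-level functions operating
on the domain objects (the reference semantics) and
:class:`ProposalScorer`, a vectorized engine over integer-coded populations
used by the genetic algorithm.  They are equivalent; the test suite holds
them to each other and to a brute-force pair enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .candidates import promoter_interval
from .config import GAConfig
from .types import CellTypeCatalog, DataBundle, GeneRecord, InteractionNetwork, Locus, Proposal, ProposalElement

__all__ = [
    "OF_NAMES",
    "ObjectiveMatrix",
    "SnpPeakIndex",
    "score_membership",
    "score_promoter",
    "score_atac",
    "score_marker_gene",
    "score_pairwise",
    "score_proposal",
    "ProposalScorer",
]

#: fixed OF column order
OF_NAMES = (
    "isMAGMAgene",
    "isCancerGene",
    "isPPI",
    "isLPI",
    "isPromoter",
    "isCommonATAC",
    "isMarkerATAC",
    "isMarkerGene",
    "isMarkerPPI",
    "isIntraPPI",
    "isInterPPI",
)

N_OF = len(OF_NAMES)


@dataclass
class ObjectiveMatrix:
    """Loci x 11 boolean OF grid for one proposal with derived summaries."""

    values: np.ndarray  # (n_loci, 11) bool
    of_names: tuple[str, ...] = OF_NAMES

    @property
    def of_fractions(self) -> np.ndarray:
        return self.values.mean(axis=0)

    @property
    def fitness(self) -> float:
        return float(self.of_fractions.mean())

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.of_names.index(name)]

    def support_counts(self) -> np.ndarray:
        """Number of positive OFs per locus (0..11)."""
        return self.values.sum(axis=1)


class SnpPeakIndex:
    """Per-locus cell-type sets from SNP / accessible-peak overlap.

    Marker peaks are rows flagged ``is_marker == 1`` (cell-type-specific
    accessibility, thresholded upstream).  *Common* peaks are identical
    intervals present for two or more cell types; a SNP inside one is
    annotated with that peak's full cell set.
    """

    def __init__(self, loci: Sequence[Locus], peaks: pd.DataFrame, catalog: CellTypeCatalog,
                 snp_scope: str = "all"):
        marker_trees: dict[str, IntervalTree] = {}
        common_trees: dict[str, IntervalTree] = {}

        mk = peaks[peaks["is_marker"] == 1]
        for chrom, grp in mk.groupby("chrom"):
            marker_trees[chrom] = IntervalTree.from_tuples(
                (int(s), int(e), c) for s, e, c in zip(grp["start"], grp["end"], grp["cell_type"])
            )
        nm = peaks[peaks["is_marker"] == 0]
        grouped = nm.groupby(["chrom", "start", "end"])["cell_type"].agg(lambda s: frozenset(s))
        for (chrom, start, end), cells in grouped.items():
            if len(cells) >= 2:  # shared across cell types -> "common"
                common_trees.setdefault(chrom, IntervalTree()).addi(int(start), int(end), cells)

        self.snp_marker_cells: dict[tuple[str, int], frozenset] = {}
        self.snp_common_cells: dict[tuple[str, int], frozenset] = {}
        self.locus_marker_cells: dict[str, frozenset] = {}
        self.locus_common_cells: dict[str, frozenset] = {}

        for locus in loci:
            positions = [locus.lead_pos] if snp_scope == "lead" else locus.positions
            marker_cells: set[str] = set()
            common_cells: set[str] = set()
            for pos in positions:
                mcells = frozenset(
                    iv.data for iv in marker_trees.get(locus.chrom, IntervalTree())[pos]
                )
                ccells = frozenset(
                    c for iv in common_trees.get(locus.chrom, IntervalTree())[pos] for c in iv.data
                )
                self.snp_marker_cells[(locus.chrom, pos)] = mcells
                self.snp_common_cells[(locus.chrom, pos)] = ccells
                marker_cells |= mcells
                common_cells |= ccells
            self.locus_marker_cells[locus.lead_snp_id] = frozenset(marker_cells)
            self.locus_common_cells[locus.lead_snp_id] = frozenset(common_cells)


# ---------------------------------------------------------------------------
# element-level objective functions (reference semantics)

def score_membership(element: ProposalElement, member_set: set[str]) -> bool:
    """True iff the proposed gene belongs to the membership set."""
    return element.gene_id in member_set


def score_promoter(
    element: ProposalElement,
    locus: Locus,
    genes: dict[str, GeneRecord],
    config: GAConfig,
) -> bool:
    """True iff any SNP of the locus falls inside the proposed gene's promoter."""
    gene = genes[element.gene_id]
    if gene.chrom != locus.chrom:
        return False
    lo, hi = promoter_interval(gene, config)
    positions = [locus.lead_pos] if config.snp_scope == "lead" else locus.positions
    return any(lo <= pos < hi for pos in positions)


def score_atac(element: ProposalElement, locus: Locus, index: SnpPeakIndex) -> tuple[bool, bool]:
    """(isCommonATAC, isMarkerATAC) for the proposed cell type."""
    is_marker = element.cell_type in index.locus_marker_cells.get(locus.lead_snp_id, frozenset())
    is_common = element.cell_type in index.locus_common_cells.get(locus.lead_snp_id, frozenset())
    return is_common, is_marker


def score_atac_cell_agnostic(locus: Locus, index: SnpPeakIndex) -> bool:
    """Cell-agnostic common-peak overlap (config switch variant)."""
    return bool(index.locus_common_cells.get(locus.lead_snp_id, frozenset()))


def score_marker_gene(element: ProposalElement, markers: set[tuple[str, str]]) -> bool:
    """True iff (gene, cell type) is a thresholded expression-marker pair."""
    return (element.gene_id, element.cell_type) in markers


def score_pairwise(
    proposal: Proposal,
    network: InteractionNetwork,
    markers: set[tuple[str, str]],
    config: GAConfig,
) -> dict[str, np.ndarray]:
    """Per-locus booleans for the five pairwise OFs.

    For locus i with proposed gene g_i and cell c_i (partners always at a
    *different* locus j):

    * isPPI: an experimental-evidence edge (g_i, g_j) exists;
    * isLPI: (g_i, g_j) is a lncRNA-protein pair (either orientation);
    * isInterPPI: (g_i, g_j) is a ligand-receptor pair and c_i != c_j;
    * isIntraPPI: an experimental edge (g_i, g_j) with neither gene in the
      ligand-receptor universe and c_i == c_j;
    * isMarkerPPI: an experimental edge (g_i, g_j) where both elements are
      marker-valid (gene is an expression marker of its proposed cell type).
    """
    ids = [el.locus_id for el in proposal]
    if len(set(ids)) != len(ids):
        raise ValueError("proposal contains duplicate locus ids")

    n = len(proposal)
    adj = network.experimental_adjacency(config.ppi_experimental_min)
    lr_genes = network.lr_genes
    out = {k: np.zeros(n, dtype=bool) for k in ("isPPI", "isLPI", "isInterPPI", "isIntraPPI", "isMarkerPPI")}

    marker_ok = [score_marker_gene(el, markers) for el in proposal]
    for i, el_i in enumerate(proposal):
        gi, ci = el_i.gene_id, el_i.cell_type
        neighbors = adj.get(gi, set())
        for j, el_j in enumerate(proposal):
            if j == i:
                continue
            gj, cj = el_j.gene_id, el_j.cell_type
            if gj in neighbors:
                out["isPPI"][i] = True
                if marker_ok[i] and (marker_ok[j] or not config.marker_ppi_both_cells):
                    out["isMarkerPPI"][i] = True
                if gi not in lr_genes and gj not in lr_genes and ci == cj:
                    out["isIntraPPI"][i] = True
            if frozenset((gi, gj)) in network.lpi_pairs:
                out["isLPI"][i] = True
            if frozenset((gi, gj)) in network.lr_pairs and ci != cj:
                out["isInterPPI"][i] = True
    return out


def score_proposal(
    proposal: Proposal,
    bundle: DataBundle,
    config: GAConfig,
    index: Optional[SnpPeakIndex] = None,
) -> ObjectiveMatrix:
    """Score one proposal against all eleven OFs (object-level reference path)."""
    if index is None:
        index = SnpPeakIndex(bundle.loci, bundle.peaks, bundle.catalog, config.snp_scope)
    n = len(proposal)
    values = np.zeros((n, N_OF), dtype=bool)
    col = {name: k for k, name in enumerate(OF_NAMES)}

    locus_by_id = {l.lead_snp_id: l for l in bundle.loci}
    for i, el in enumerate(proposal):
        locus = locus_by_id[el.locus_id]
        values[i, col["isMAGMAgene"]] = score_membership(el, bundle.gene_sets["magma"])
        values[i, col["isCancerGene"]] = score_membership(el, bundle.gene_sets["cancer"])
        values[i, col["isPromoter"]] = score_promoter(el, locus, bundle.genes, config)
        common, marker = score_atac(el, locus, index)
        if not config.common_atac_cell_specific:
            common = score_atac_cell_agnostic(locus, index)
        values[i, col["isCommonATAC"]] = common
        values[i, col["isMarkerATAC"]] = marker
        values[i, col["isMarkerGene"]] = score_marker_gene(el, bundle.markers)

    pairwise = score_pairwise(proposal, bundle.network, bundle.markers, config)
    for name, arr in pairwise.items():
        values[:, col[name]] = arr
    return ObjectiveMatrix(values)


# ---------------------------------------------------------------------------
# vectorized scorer

class ProposalScorer:
    """Vectorized scoring of integer-coded populations.

    Proposals are coded as two (P, L) integer arrays: the per-locus candidate
    index K (0..n_candidates(l)-1) and the cell index C (0..n_cells-1).  All
    per-element OFs reduce to table lookups built once from the bundle; the
    five pairwise OFs are evaluated with (P, L, L) boolean pair grids,
    chunked over P to bound memory.
    """

    def __init__(self, bundle: DataBundle, config: GAConfig):
        self.bundle = bundle
        self.config = config
        loci = bundle.loci
        catalog = bundle.catalog
        self.n_loci = len(loci)
        self.n_cells = len(catalog)
        self.candidates = [list(l.candidate_genes) for l in loci]
        self.n_cand = np.array([len(c) for c in self.candidates], dtype=np.int64)
        max_c = int(self.n_cand.max())

        # global gene index over genes appearing in any candidate set
        gene_ids = sorted({g for cands in self.candidates for g in cands})
        self.gene_ids = gene_ids
        gidx = {g: i for i, g in enumerate(gene_ids)}
        self.gene_index = gidx
        nG = len(gene_ids)

        self.cand_gene = np.zeros((self.n_loci, max_c), dtype=np.int64)
        for l, cands in enumerate(self.candidates):
            self.cand_gene[l, : len(cands)] = [gidx[g] for g in cands]
            if len(cands) < max_c:  # pad with the first candidate; never drawn
                self.cand_gene[l, len(cands):] = gidx[cands[0]]

        # gene-level membership flags
        self.magma_g = np.array([g in bundle.gene_sets["magma"] for g in gene_ids])
        self.cancer_g = np.array([g in bundle.gene_sets["cancer"] for g in gene_ids])

        # promoter overlap per (locus, candidate)
        index = SnpPeakIndex(loci, bundle.peaks, catalog, config.snp_scope)
        self.index = index
        self.prom_lk = np.zeros((self.n_loci, max_c), dtype=bool)
        for l, locus in enumerate(loci):
            positions = [locus.lead_pos] if config.snp_scope == "lead" else locus.positions
            for k, gid in enumerate(self.candidates[l]):
                gene = bundle.genes[gid]
                if gene.chrom != locus.chrom:
                    continue
                lo, hi = promoter_interval(gene, config)
                self.prom_lk[l, k] = any(lo <= p < hi for p in positions)

        # marker-gene flag per (gene, cell)
        self.mg_gc = np.zeros((nG, self.n_cells), dtype=bool)
        for g, c in bundle.markers:
            if g in gidx and c in catalog:
                self.mg_gc[gidx[g], catalog.index(c)] = True

        # ATAC flags per (locus, cell)
        self.common_lc = np.zeros((self.n_loci, self.n_cells), dtype=bool)
        self.matac_lc = np.zeros((self.n_loci, self.n_cells), dtype=bool)
        for l, locus in enumerate(loci):
            for c in index.locus_common_cells.get(locus.lead_snp_id, frozenset()):
                self.common_lc[l, catalog.index(c)] = True
            for c in index.locus_marker_cells.get(locus.lead_snp_id, frozenset()):
                self.matac_lc[l, catalog.index(c)] = True
        if not config.common_atac_cell_specific:
            any_common = self.common_lc.any(axis=1, keepdims=True)
            self.common_lc = np.broadcast_to(any_common, self.common_lc.shape).copy()

        # pairwise adjacency matrices over the gene universe
        self.A = np.zeros((nG, nG), dtype=bool)
        for key in network_edge_keys(bundle.network, config.ppi_experimental_min):
            a, b = tuple(key)
            if a in gidx and b in gidx:
                self.A[gidx[a], gidx[b]] = True
                self.A[gidx[b], gidx[a]] = True
        self.LPI = _pair_matrix(bundle.network.lpi_pairs, gidx, nG)
        self.LR = _pair_matrix(bundle.network.lr_pairs, gidx, nG)
        self.in_lr = np.array([g in bundle.network.lr_genes for g in gene_ids])

        self._col = {name: k for k, name in enumerate(OF_NAMES)}
        self._locus_arange = np.arange(self.n_loci)

    # -- coding helpers -----------------------------------------------------

    def encode(self, proposal: Proposal) -> tuple[np.ndarray, np.ndarray]:
        K = np.array(
            [self.candidates[l].index(el.gene_id) for l, el in enumerate(proposal)],
            dtype=np.int64,
        )
        C = np.array([self.bundle.catalog.index(el.cell_type) for el in proposal], dtype=np.int64)
        return K[None, :], C[None, :]

    def decode(self, K: np.ndarray, C: np.ndarray) -> Proposal:
        els = tuple(
            ProposalElement(
                self.bundle.loci[l].lead_snp_id,
                self.candidates[l][int(K[l])],
                self.bundle.catalog[int(C[l])],
            )
            for l in range(self.n_loci)
        )
        return Proposal(els)

    # -- scoring ------------------------------------------------------------

    def score_grids(self, K: np.ndarray, C: np.ndarray, chunk: int = 256) -> np.ndarray:
        """Full boolean OF grids: (P, L, 11)."""
        P, L = K.shape
        out = np.zeros((P, L, N_OF), dtype=bool)
        col = self._col
        G = self.cand_gene[self._locus_arange[None, :], K]  # (P, L) global gene index

        out[:, :, col["isMAGMAgene"]] = self.magma_g[G]
        out[:, :, col["isCancerGene"]] = self.cancer_g[G]
        out[:, :, col["isPromoter"]] = self.prom_lk[self._locus_arange[None, :], K]
        mg = self.mg_gc[G, C]
        out[:, :, col["isMarkerGene"]] = mg
        out[:, :, col["isCommonATAC"]] = self.common_lc[self._locus_arange[None, :], C]
        out[:, :, col["isMarkerATAC"]] = self.matac_lc[self._locus_arange[None, :], C]

        eye = np.eye(L, dtype=bool)[None, :, :]
        for s in range(0, P, chunk):
            e = min(s + chunk, P)
            g = G[s:e]
            c = C[s:e]
            m = mg[s:e]
            pair_edge = self.A[g[:, :, None], g[:, None, :]] & ~eye  # (p, L, L)
            out[s:e, :, col["isPPI"]] = pair_edge.any(axis=2)
            lpi = self.LPI[g[:, :, None], g[:, None, :]] & ~eye
            out[s:e, :, col["isLPI"]] = lpi.any(axis=2)
            same_cell = c[:, :, None] == c[:, None, :]
            lr = self.LR[g[:, :, None], g[:, None, :]] & ~eye
            out[s:e, :, col["isInterPPI"]] = (lr & ~same_cell).any(axis=2)
            not_lr = ~self.in_lr[g]
            intra = pair_edge & same_cell & not_lr[:, :, None] & not_lr[:, None, :]
            out[s:e, :, col["isIntraPPI"]] = intra.any(axis=2)
            if self.config.marker_ppi_both_cells:
                mppi = pair_edge & m[:, :, None] & m[:, None, :]
            else:
                mppi = pair_edge & m[:, :, None]
            out[s:e, :, col["isMarkerPPI"]] = mppi.any(axis=2)
        return out

    def score_population(self, K: np.ndarray, C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(fractions (P, 11), fitness (P,)) for an integer-coded population."""
        grids = self.score_grids(K, C)
        fractions = grids.mean(axis=1)
        return fractions, fractions.mean(axis=1)

    def objective_matrix(self, K_row: np.ndarray, C_row: np.ndarray) -> ObjectiveMatrix:
        grids = self.score_grids(K_row[None, :], C_row[None, :])
        return ObjectiveMatrix(grids[0])


def network_edge_keys(network: InteractionNetwork, floor: float):
    return [k for k, (exp_s, _) in network.edges.items() if exp_s > floor]


def _pair_matrix(pairs: set[frozenset], gidx: dict[str, int], nG: int) -> np.ndarray:
    M = np.zeros((nG, nG), dtype=bool)
    for p in pairs:
        a, b = tuple(p)
        if a in gidx and b in gidx:
            M[gidx[a], gidx[b]] = True
            M[gidx[b], gidx[a]] = True
    return M
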