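"""Consensus calling over a final population, confidence-threshold
calibration against reference gene calls, and call-diversity statistics.

The consensus proposal takes, per locus, the modal gene and (independently)
the modal cell type across the population.  A frequency threshold for
"high-confidence" calls is calibrated so that a chosen sensitivity (default
80%) of the loci whose consensus gene agrees with a high-scoring external
reference call are retained.  Call diversity across independent runs is
summarized by the Gini-Simpson index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import GAConfig
from .ga import Population
from .objectives import OF_NAMES, ObjectiveMatrix
from .types import Proposal, ProposalElement

logger = logging.getLogger(__name__)

__all__ = [
    "ConsensusCall",
    "DiversityRecord",
    "consensus",
    "confidence_threshold",
    "apply_confidence",
    "gini_simpson",
    "call_diversity",
    "stable_loci",
    "consensus_table",
]


@dataclass
class ConsensusCall:
    locus_id: str
    top_gene: str
    gene_frequency: int
    top_cell: str
    cell_frequency: int
    high_conf_gene: bool = False
    high_conf_cell: bool = False
    supporting_ofs: tuple[str, ...] = ()


@dataclass
class DiversityRecord:
    locus_id: str
    gini_simpson: float
    distinct_gene_count: int


def _modal(counts: np.ndarray, support: Optional[np.ndarray], labels: Sequence[str]) -> int:
    """Index of the modal category; ties broken by higher support, then by
    lexicographic label."""
    best = counts.max()
    tied = np.flatnonzero(counts == best)
    if len(tied) == 1:
        return int(tied[0])
    if support is not None:
        s = support[tied]
        tied = tied[s == s.max()]
        if len(tied) == 1:
            logger.info("consensus tie broken by OF support")
            return int(tied[0])
    winner = min(tied, key=lambda i: labels[i])
    logger.info("consensus tie broken lexicographically: %s", labels[winner])
    return int(winner)


def consensus(
    population: Population, config: Optional[GAConfig] = None
) -> tuple[Proposal, ObjectiveMatrix, list[ConsensusCall]]:
    """Modal gene and cell type per locus across a scored population.

    Gene and cell modes are taken independently (the default); with
    ``config.consensus_joint_mode`` the modal joint (gene, cell) pair is used.
    Ties are broken by higher per-element OF support for the tied candidate
    (evaluated with the locus's modal cell), then lexicographically, and
    logged.  Returns the consensus proposal, its objective matrix, and the
    per-locus calls.
    """
    scorer = population.scorer
    if population.fitness is None:
        population.score()
    P, L = population.K.shape
    joint = bool(config is not None and config.consensus_joint_mode)

    K_cons = np.empty(L, dtype=np.int64)
    C_cons = np.empty(L, dtype=np.int64)
    gene_freq = np.empty(L, dtype=np.int64)
    cell_freq = np.empty(L, dtype=np.int64)

    for l in range(L):
        cands = scorer.candidates[l]
        cell_counts = np.bincount(population.C[:, l], minlength=scorer.n_cells)
        if joint:
            pair_counts = np.zeros((len(cands), scorer.n_cells), dtype=np.int64)
            np.add.at(pair_counts, (population.K[:, l], population.C[:, l]), 1)
            flat = int(pair_counts.argmax())
            k, c = divmod(flat, scorer.n_cells)
            K_cons[l], C_cons[l] = k, c
            gene_freq[l] = pair_counts[k].sum()
            cell_freq[l] = pair_counts[:, c].sum()
            continue
        gene_counts = np.bincount(population.K[:, l], minlength=len(cands))
        c = _modal(cell_counts, None, scorer.bundle.catalog.labels)
        # per-element OF support for tie-breaking among genes, at the modal cell
        g_global = scorer.cand_gene[l, : len(cands)]
        support = (
            scorer.magma_g[g_global].astype(int)
            + scorer.cancer_g[g_global].astype(int)
            + scorer.prom_lk[l, : len(cands)].astype(int)
            + scorer.mg_gc[g_global, c].astype(int)
        )
        k = _modal(gene_counts, support, cands)
        K_cons[l], C_cons[l] = k, c
        gene_freq[l] = gene_counts[k]
        cell_freq[l] = cell_counts[c]

    matrix = scorer.objective_matrix(K_cons, C_cons)
    proposal = scorer.decode(K_cons, C_cons)
    proposal.fitness = matrix.fitness

    calls = []
    for l, el in enumerate(proposal):
        positive = tuple(name for j, name in enumerate(OF_NAMES) if matrix.values[l, j])
        calls.append(
            ConsensusCall(
                locus_id=el.locus_id,
                top_gene=el.gene_id,
                gene_frequency=int(gene_freq[l]),
                top_cell=el.cell_type,
                cell_frequency=int(cell_freq[l]),
                supporting_ofs=positive,
            )
        )
    return proposal, matrix, calls


def confidence_threshold(
    calls: Sequence[ConsensusCall],
    reference: pd.DataFrame,
    config: GAConfig,
) -> int:
    """Largest vote-count threshold retaining at least
    ``confidence_sensitivity`` of the reference-agreeing loci.

    The calibration set is the loci whose reference call scores at least
    ``reference_score_min`` *and* names the same gene as the consensus.  The
    returned threshold t is the largest count such that the fraction of
    calibration loci with gene_frequency >= t is at least the sensitivity.
    """
    ref = reference[reference["score"] >= config.reference_score_min]
    ref_gene = dict(zip(ref["lead_snp_id"], ref["gene_id"]))
    agreeing = [c for c in calls if ref_gene.get(c.locus_id) == c.top_gene]
    if not agreeing:
        raise ValueError(
            "no high-score reference locus agrees with the consensus; "
            "calibrate the threshold on synthetic truth or relax reference_score_min"
        )
    freqs = np.sort([c.gene_frequency for c in agreeing])[::-1]
    n = len(freqs)
    need = int(np.ceil(config.confidence_sensitivity * n))
    need = max(need, 1)
    return int(freqs[need - 1])


def apply_confidence(calls: Sequence[ConsensusCall], threshold: int) -> None:
    """Flag calls whose vote counts reach the calibrated threshold (the same
    threshold is applied to gene and cell frequencies)."""
    for c in calls:
        c.high_conf_gene = c.gene_frequency >= threshold
        c.high_conf_cell = c.cell_frequency >= threshold


def gini_simpson(category_counts: Mapping[object, int] | Sequence[int]) -> float:
    """Gini-Simpson diversity 1 - sum(p_i^2) of categorical call counts."""
    counts = np.asarray(
        list(category_counts.values()) if isinstance(category_counts, Mapping) else category_counts,
        dtype=float,
    )
    total = counts.sum()
    if total <= 0:
        raise ValueError("total count must be positive")
    p = counts / total
    return float(1.0 - np.sum(p**2))


def call_diversity(per_run_calls: Sequence[Sequence[ConsensusCall]]) -> list[DiversityRecord]:
    """Diversity of consensus top-gene calls pooled across independent runs.

    One count per run per locus (the run's consensus call), following the
    pooled-consensus reading of diversity across multiple independent runs.
    """
    if not per_run_calls:
        return []
    by_locus: dict[str, list[str]] = {}
    for calls in per_run_calls:
        for c in calls:
            by_locus.setdefault(c.locus_id, []).append(c.top_gene)
    records = []
    for locus_id, genes in by_locus.items():
        counts: dict[str, int] = {}
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
        records.append(DiversityRecord(locus_id, gini_simpson(counts), len(counts)))
    return records


def stable_loci(diversity: Sequence[DiversityRecord], config: GAConfig) -> set[str]:
    """Loci with low call diversity: Gini-Simpson <= gini_max and distinct
    gene count <= gini_gene_count_max (conjunctive)."""
    return {
        d.locus_id
        for d in diversity
        if d.gini_simpson <= config.gini_max and d.distinct_gene_count <= config.gini_gene_count_max
    }


def consensus_table(
    calls: Sequence[ConsensusCall],
    diversity: Optional[Sequence[DiversityRecord]] = None,
) -> pd.DataFrame:
    div = {d.locus_id: d for d in diversity} if diversity else {}
    rows = []
    for c in calls:
        d = div.get(c.locus_id)
        rows.append(
            {
                "locus": c.locus_id,
                "gene": c.top_gene,
                "gene_freq": c.gene_frequency,
                "cell": c.top_cell,
                "cell_freq": c.cell_frequency,
                "high_conf_gene": c.high_conf_gene,
                "high_conf_cell": c.high_conf_cell,
                "gini_simpson": d.gini_simpson if d else np.nan,
                "n_genes": d.distinct_gene_count if d else np.nan,
                "supporting_ofs": ",".join(c.supporting_ofs),
            }
        )
    return pd.DataFrame(rows)
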