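"""Candidate ("nearby") gene-set construction and promoter geometry.

The candidate window spans the minimum to maximum SNP position of a locus
(lead plus proxies) expanded by a fixed margin on each side; if fewer than a
minimum number of genes lie on either side of the lead SNP the window is
extended on that side until the minimum is met or the chromosome ends.
Membership is by span overlap with the half-open window.
"""

from __future__ import annotations

from typing import Sequence

from .config import GAConfig
from .types import GeneRecord, Locus

__all__ = ["nearby_gene_set", "promoter_interval", "candidate_window"]


def candidate_window(locus: Locus, genes: Sequence[GeneRecord], config: GAConfig) -> tuple[int, int]:
    """Half-open genomic window used for candidate-gene membership.

    Starts from [min(SNP) - window_expand, max(SNP) + window_expand] and
    extends per side until at least ``min_flank_genes`` genes lie strictly
    upstream (gene end <= lead) and downstream (gene start > lead) of the
    lead SNP inside the window.
    """
    chrom_genes = sorted(
        (g for g in genes if g.chrom == locus.chrom), key=lambda g: (g.start, g.end, g.gene_id)
    )
    if not chrom_genes:
        raise ValueError(f"no annotated genes on chromosome {locus.chrom!r} for {locus.lead_snp_id}")

    positions = locus.positions
    win_start = max(0, min(positions) - config.window_expand)
    win_end = max(positions) + config.window_expand + 1  # half-open; SNP positions are points

    lead = locus.lead_pos
    upstream = [g for g in chrom_genes if g.end <= lead]  # entirely 5' of the lead on the + axis
    downstream = [g for g in chrom_genes if g.start > lead]

    k = config.min_flank_genes
    # upstream side: count genes overlapping the window
    n_up = sum(1 for g in upstream if g.end > win_start)
    if n_up < k and upstream:
        # nearest-first by proximity of the gene end to the lead; minimal
        # extension: just past the k-th gene's end so its span intersects
        ordered = sorted(upstream, key=lambda g: -g.end)
        take = ordered[: min(k, len(ordered))]
        win_start = min(win_start, max(0, take[-1].end - 1))
    n_down = sum(1 for g in downstream if g.start < win_end)
    if n_down < k and downstream:
        ordered = sorted(downstream, key=lambda g: g.start)
        take = ordered[: min(k, len(ordered))]
        win_end = max(win_end, take[-1].start + 1)
    return win_start, win_end


def nearby_gene_set(locus: Locus, genes: Sequence[GeneRecord], config: GAConfig) -> list[str]:
    """Ordered candidate gene ids whose spans intersect the locus window.

    Deterministic: output is sorted by genomic start (then end, then id) and
    does not depend on proxy input order.
    """
    win_start, win_end = candidate_window(locus, genes, config)
    hits = [
        g
        for g in genes
        if g.chrom == locus.chrom and g.start < win_end and g.end > win_start
    ]
    hits.sort(key=lambda g: (g.start, g.end, g.gene_id))
    return [g.gene_id for g in hits]


def promoter_interval(gene: GeneRecord, config: GAConfig) -> tuple[int, int]:
    """Half-open promoter interval: promoter_upstream bp 5' of the TSS and
    promoter_downstream bp 3' of it, in transcript orientation, clamped at 0.
    """
    if gene.strand == "+":
        lo = gene.start - config.promoter_upstream
        hi = gene.start + config.promoter_downstream
    else:
        # TSS at the right edge; upstream extends to larger coordinates
        lo = gene.end - config.promoter_downstream
        hi = gene.end + config.promoter_upstream
    return max(0, lo), max(0, hi)
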