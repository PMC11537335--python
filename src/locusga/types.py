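"""Domain types shared by all stages.

Coordinates are 0-based half-open throughout (BED convention); GFF3 input is
converted on read.  A *locus* is a lead GWAS SNP together with its proxy SNPs
and an ordered candidate ("nearby") gene set.  A *proposal* assigns one
(gene, cell type) pair to every locus simultaneously and is the genetic
algorithm's unit of search.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence

__all__ = [
    "BIOTYPES",
    "GeneRecord",
    "Locus",
    "CellTypeCatalog",
    "ProposalElement",
    "Proposal",
    "InteractionNetwork",
    "DataBundle",
]

#: the two gene classes retained from the annotation
BIOTYPES = ("protein_coding", "lncRNA")


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    symbol: str
    chrom: str
    start: int  # 0-based, half-open
    end: int
    strand: str  # '+' or '-'
    biotype: str  # 'protein_coding' or 'lncRNA'

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: start must be < end ({self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"{self.gene_id}: biotype must be one of {BIOTYPES}")

    @property
    def tss(self) -> int:
        """Transcription start site: leftmost base for '+', rightmost for '-'."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class Locus:
    lead_snp_id: str
    chrom: str
    lead_pos: int
    proxies: list[tuple[str, int]] = field(default_factory=list)
    candidate_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.candidate_genes)) != len(self.candidate_genes):
            raise ValueError(f"{self.lead_snp_id}: duplicate candidate genes")

    @property
    def positions(self) -> list[int]:
        """Lead plus proxy positions."""
        return [self.lead_pos] + [pos for _, pos in self.proxies]

    def validate(self) -> None:
        if not self.candidate_genes:
            raise ValueError(f"{self.lead_snp_id}: empty candidate gene set")


class CellTypeCatalog:
    """Ordered, unique cell-type labels available to proposals."""

    def __init__(self, labels: Sequence[str]):
        labels = list(labels)
        if not labels:
            raise ValueError("catalog must contain at least one cell type")
        if len(set(labels)) != len(labels):
            raise ValueError("catalog labels must be unique")
        self.labels: list[str] = labels
        self._index = {c: i for i, c in enumerate(labels)}

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self) -> Iterator[str]:
        return iter(self.labels)

    def __contains__(self, label: object) -> bool:
        return label in self._index

    def __getitem__(self, i: int) -> str:
        return self.labels[i]

    def index(self, label: str) -> int:
        return self._index[label]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CellTypeCatalog) and self.labels == other.labels

    def __repr__(self) -> str:
        return f"CellTypeCatalog({self.labels!r})"


@dataclass(frozen=True)
class ProposalElement:
    locus_id: str
    gene_id: str
    cell_type: str


@dataclass
class Proposal:
    """One (gene, cell type) assignment per locus, in fixed locus order."""

    elements: tuple[ProposalElement, ...]
    fitness: Optional[float] = None

    def __len__(self) -> int:
        return len(self.elements)

    def __iter__(self) -> Iterator[ProposalElement]:
        return iter(self.elements)

    def validate(self, loci: Sequence[Locus], catalog: CellTypeCatalog) -> None:
        if len(self.elements) != len(loci):
            raise ValueError("proposal length must equal the number of loci")
        for el, locus in zip(self.elements, loci):
            if el.locus_id != locus.lead_snp_id:
                raise ValueError(f"locus order mismatch: {el.locus_id} vs {locus.lead_snp_id}")
            if el.gene_id not in locus.candidate_genes:
                raise ValueError(f"{el.gene_id} not a candidate at {el.locus_id}")
            if el.cell_type not in catalog:
                raise ValueError(f"unknown cell type {el.cell_type!r} at {el.locus_id}")


class InteractionNetwork:
    """Undirected scored gene-gene edges plus ligand-receptor and
    lncRNA-protein pair sets.

    ``edges`` carries one row per undirected pair with an experimental
    evidence score and a combined score; the two thresholds used by the
    method (experimental evidence for objective scoring, combined score for
    subgraph analysis) are applied by the consumers, not here.  Self edges
    are dropped on construction.
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str, float, float]],
        lr_pairs: Iterable[tuple[str, str]] = (),
        lpi_pairs: Iterable[tuple[str, str]] = (),
    ):
        seen: dict[frozenset, tuple[float, float]] = {}
        for a, b, exp_s, comb_s in edges:
            if a == b:
                continue
            key = frozenset((a, b))
            prev = seen.get(key)
            if prev is None or (exp_s, comb_s) > prev:
                seen[key] = (float(exp_s), float(comb_s))
        self.edges: dict[frozenset, tuple[float, float]] = seen
        self.lr_pairs: set[frozenset] = {frozenset(p) for p in lr_pairs if p[0] != p[1]}
        self.lpi_pairs: set[frozenset] = {frozenset(p) for p in lpi_pairs if p[0] != p[1]}
        #: the ligand-receptor gene universe: genes appearing in any LR pair
        self.lr_genes: set[str] = {g for p in self.lr_pairs for g in p}

    def edge_list(self) -> list[tuple[str, str, float, float]]:
        out = []
        for key, (exp_s, comb_s) in self.edges.items():
            a, b = sorted(key)
            out.append((a, b, exp_s, comb_s))
        return sorted(out)

    def experimental_adjacency(self, floor: float = 0.0) -> dict[str, set[str]]:
        """Adjacency over edges with experimental evidence strictly > floor."""
        adj: dict[str, set[str]] = {}
        for key, (exp_s, _) in self.edges.items():
            if exp_s > floor:
                a, b = tuple(key)
                adj.setdefault(a, set()).add(b)
                adj.setdefault(b, set()).add(a)
        return adj

    def combined_edges(self, min_score: float) -> list[tuple[str, str]]:
        """Undirected pairs with combined score >= min_score."""
        return [tuple(sorted(k)) for k, (_, c) in self.edges.items() if c >= min_score]


@dataclass
class DataBundle:
    """Everything one analysis needs, cross-referenced and filtered."""

    loci: list[Locus]
    genes: dict[str, GeneRecord]
    catalog: CellTypeCatalog
    peaks: "object"  # pandas.DataFrame: chrom, start, end, cell_type, is_marker
    markers: set[tuple[str, str]]  # (gene_id, cell_type) pairs passing thresholds
    gene_sets: dict[str, set[str]]  # e.g. {'magma': {...}, 'cancer': {...}}
    network: InteractionNetwork
    reference_calls: Optional["object"] = None  # pandas.DataFrame: lead_snp_id, gene_id, score

    @property
    def locus_ids(self) -> list[str]:
        return [l.lead_snp_id for l in self.loci]
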