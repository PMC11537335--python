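"""Readers and writers for the tabular input formats, plus `load_inputs`.

All genomic intervals are 0-based half-open internally.  BED-like peak files
are native; GFF3 gene annotation (1-based closed) is converted on read.
Marker tables are thresholded here, once, so downstream objective functions
are pure membership tests.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .candidates import nearby_gene_set
from .config import GAConfig
from .types import BIOTYPES, CellTypeCatalog, DataBundle, GeneRecord, InteractionNetwork, Locus

logger = logging.getLogger(__name__)

__all__ = [
    "read_loci",
    "write_loci",
    "read_genes",
    "write_genes",
    "read_peaks",
    "write_peaks",
    "read_markers",
    "write_markers",
    "read_gene_set",
    "write_gene_set",
    "read_network",
    "write_network",
    "read_pairs",
    "write_pairs",
    "read_reference_calls",
    "write_reference_calls",
    "read_catalog",
    "write_catalog",
    "load_inputs",
    "write_bundle",
]


# ---------------------------------------------------------------------------
# loci

def read_loci(path: str | Path) -> list[Locus]:
    df = pd.read_csv(path, sep="\t", dtype={"lead_snp_id": str, "chrom": str})
    loci = []
    for row in df.itertuples(index=False):
        proxies: list[tuple[str, int]] = []
        ids = getattr(row, "proxy_ids", "")
        pos = getattr(row, "proxy_pos", "")
        if isinstance(ids, str) and ids.strip():
            id_list = ids.split(",")
            pos_list = [int(p) for p in str(pos).split(",")]
            if len(id_list) != len(pos_list):
                raise ValueError(f"{row.lead_snp_id}: proxy_ids and proxy_pos lengths differ")
            proxies = list(zip(id_list, pos_list))
        loci.append(Locus(str(row.lead_snp_id), str(row.chrom), int(row.pos), proxies))
    return loci


def write_loci(loci: Sequence[Locus], path: str | Path) -> None:
    rows = []
    for l in loci:
        rows.append(
            {
                "lead_snp_id": l.lead_snp_id,
                "chrom": l.chrom,
                "pos": l.lead_pos,
                "proxy_ids": ",".join(pid for pid, _ in l.proxies),
                "proxy_pos": ",".join(str(p) for _, p in l.proxies),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genes

def read_genes(path: str | Path) -> list[GeneRecord]:
    """Read gene annotation from TSV (0-based half-open) or GFF3 (converted).

    Records outside the retained biotypes (protein_coding, lncRNA) are
    dropped with a warning.
    """
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return _read_genes_gff3(path)
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "symbol": str, "chrom": str})
    return _records_from_rows(
        (r.gene_id, r.symbol, r.chrom, int(r.start), int(r.end), r.strand, r.biotype)
        for r in df.itertuples(index=False)
    )


def _read_genes_gff3(path: Path) -> list[GeneRecord]:
    cols = ["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"]
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=cols, dtype={"seqid": str})
    df = df[df["type"] == "gene"]
    rows = []
    for r in df.itertuples(index=False):
        attrs = dict(
            item.split("=", 1) for item in str(r.attributes).rstrip(";").split(";") if "=" in item
        )
        gene_id = attrs.get("ID") or attrs.get("gene_id")
        if gene_id is None:
            raise ValueError(f"GFF3 gene without ID attribute: {r.attributes!r}")
        symbol = attrs.get("Name", gene_id)
        biotype = attrs.get("biotype") or attrs.get("gene_biotype") or ""
        # GFF3 is 1-based closed; convert to 0-based half-open
        rows.append((gene_id, symbol, r.seqid, int(r.start) - 1, int(r.end), r.strand, biotype))
    return _records_from_rows(rows)


def _records_from_rows(rows) -> list[GeneRecord]:
    records = []
    for gene_id, symbol, chrom, start, end, strand, biotype in rows:
        if biotype not in BIOTYPES:
            warnings.warn(
                f"dropping gene {gene_id} with biotype {biotype!r} "
                f"(retained biotypes: {BIOTYPES})",
                stacklevel=3,
            )
            continue
        records.append(GeneRecord(str(gene_id), str(symbol), str(chrom), start, end, strand, biotype))
    return records


def write_genes(genes: Sequence[GeneRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "symbol": g.symbol,
                "chrom": g.chrom,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "biotype": g.biotype,
            }
            for g in genes
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# peaks / markers / sets / network

PEAK_COLUMNS = ["chrom", "start", "end", "cell_type", "is_marker"]


def read_peaks(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=PEAK_COLUMNS,
                     dtype={"chrom": str, "cell_type": str})
    df["is_marker"] = df["is_marker"].astype(int)
    return df


def write_peaks(peaks: pd.DataFrame, path: str | Path) -> None:
    peaks[PEAK_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


def read_markers(path: str | Path, config: GAConfig) -> set[tuple[str, str]]:
    """Marker-gene (gene_id, cell_type) pairs passing p and log2FC thresholds."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "cell_type": str},
                     float_precision="round_trip")
    keep = (df["p"] <= config.marker_gene_p) & (df["log2fc"] >= config.marker_gene_lfc)
    return {(r.gene_id, r.cell_type) for r in df[keep].itertuples(index=False)}


def write_markers(rows: pd.DataFrame, path: str | Path) -> None:
    rows[["gene_id", "cell_type", "p", "log2fc"]].to_csv(path, sep="\t", index=False)


def read_gene_set(path: str | Path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_gene_set(genes: set[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")


def read_network(
    path: str | Path,
    lr_path: Optional[str | Path] = None,
    lpi_path: Optional[str | Path] = None,
) -> InteractionNetwork:
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str},
                     float_precision="round_trip")
    edges = [
        (r.gene_a, r.gene_b, float(r.experimental_score), float(r.combined_score))
        for r in df.itertuples(index=False)
    ]
    lr = read_pairs(lr_path) if lr_path else []
    lpi = read_pairs(lpi_path) if lpi_path else []
    return InteractionNetwork(edges, lr, lpi)


def write_network(network: InteractionNetwork, path: str | Path) -> None:
    pd.DataFrame(
        network.edge_list(), columns=["gene_a", "gene_b", "experimental_score", "combined_score"]
    ).to_csv(path, sep="\t", index=False)


def read_pairs(path: str | Path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t")
    a, b = df.columns[:2]
    return [(str(r[0]), str(r[1])) for r in df[[a, b]].itertuples(index=False)]


def write_pairs(pairs, path: str | Path, columns: tuple[str, str]) -> None:
    pd.DataFrame(sorted(tuple(sorted(p)) for p in pairs), columns=list(columns)).to_csv(
        path, sep="\t", index=False
    )


def read_reference_calls(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"lead_snp_id": str, "gene_id": str},
                       float_precision="round_trip")


def write_reference_calls(df: pd.DataFrame, path: str | Path) -> None:
    df[["lead_snp_id", "gene_id", "score"]].to_csv(path, sep="\t", index=False)


def read_catalog(path: str | Path) -> CellTypeCatalog:
    with open(path) as fh:
        return CellTypeCatalog([line.strip() for line in fh if line.strip()])


def write_catalog(catalog: CellTypeCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        for label in catalog:
            fh.write(label + "\n")


# ---------------------------------------------------------------------------
# bundle

BUNDLE_FILES = {
    "loci": "loci.tsv",
    "genes": "genes.tsv",
    "catalog": "cell_types.txt",
    "peaks": "peaks.bed",
    "markers": "markers.tsv",
    "magma": "magma_genes.txt",
    "cancer": "cancer_genes.txt",
    "network": "network.tsv",
    "lr_pairs": "lr_pairs.tsv",
    "lpi_pairs": "lpi_pairs.tsv",
    "reference_calls": "reference_calls.tsv",
}


def load_inputs(
    paths: Mapping[str, str | Path] | str | Path, config: GAConfig
) -> DataBundle:
    """Load and cross-validate a complete input bundle.

    ``paths`` is either a directory holding the standard file names or a
    mapping with the keys of :data:`BUNDLE_FILES`.  Candidate gene sets are
    built here (window expansion + flank minimum) unless already present.
    Unresolvable cell labels or empty candidate sets are hard errors.
    """
    if isinstance(paths, (str, Path)):
        base = Path(paths)
        paths = {k: base / v for k, v in BUNDLE_FILES.items()}

    genes = read_genes(paths["genes"])
    gene_map = {g.gene_id: g for g in genes}
    catalog = read_catalog(paths["catalog"])
    loci = read_loci(paths["loci"])
    peaks = read_peaks(paths["peaks"])
    markers = read_markers(paths["markers"], config)
    gene_sets = {
        "magma": read_gene_set(paths["magma"]),
        "cancer": read_gene_set(paths["cancer"]),
    }
    network = read_network(paths["network"], paths.get("lr_pairs"), paths.get("lpi_pairs"))
    reference_calls = None
    ref_path = paths.get("reference_calls")
    if ref_path is not None and Path(ref_path).exists():
        reference_calls = read_reference_calls(ref_path)

    bad_cells = set(peaks["cell_type"]) - set(catalog.labels)
    if bad_cells:
        rows = peaks.index[peaks["cell_type"].isin(bad_cells)].tolist()
        raise ValueError(
            f"peak file references cell labels absent from catalog: {sorted(bad_cells)} "
            f"(first offending row {rows[0]})"
        )
    bad_marker_cells = {c for _, c in markers} - set(catalog.labels)
    if bad_marker_cells:
        raise ValueError(
            f"marker table references cell labels absent from catalog: {sorted(bad_marker_cells)}"
        )

    for locus in loci:
        if not locus.candidate_genes:
            locus.candidate_genes = nearby_gene_set(locus, genes, config)
        locus.validate()
        missing = [g for g in locus.candidate_genes if g not in gene_map]
        if missing:
            raise ValueError(
                f"locus {locus.lead_snp_id}: candidate gene(s) without annotation: {missing}"
            )

    logger.info(
        "loaded %d loci, %d genes, %d cell types, %d peaks, %d marker pairs, %d edges",
        len(loci), len(genes), len(catalog), len(peaks), len(markers), len(network.edges),
    )
    return DataBundle(
        loci=loci,
        genes=gene_map,
        catalog=catalog,
        peaks=peaks,
        markers=markers,
        gene_sets=gene_sets,
        network=network,
        reference_calls=reference_calls,
    )


def write_bundle(bundle: DataBundle, out_dir: str | Path, marker_rows: Optional[pd.DataFrame] = None) -> None:
    """Write a bundle to the standard file layout (inverse of load_inputs).

    ``markers`` in memory holds only the passing pairs; unless the full table
    is supplied via ``marker_rows``, passing pairs are written with
    placeholder statistics that survive thresholding on re-read.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_loci(bundle.loci, out / BUNDLE_FILES["loci"])
    write_genes(list(bundle.genes.values()), out / BUNDLE_FILES["genes"])
    write_catalog(bundle.catalog, out / BUNDLE_FILES["catalog"])
    write_peaks(bundle.peaks, out / BUNDLE_FILES["peaks"])
    if marker_rows is None:
        marker_rows = pd.DataFrame(
            [
                {"gene_id": g, "cell_type": c, "p": 0.001, "log2fc": 1.0}
                for g, c in sorted(bundle.markers)
            ],
            columns=["gene_id", "cell_type", "p", "log2fc"],
        )
    write_markers(marker_rows, out / BUNDLE_FILES["markers"])
    write_gene_set(bundle.gene_sets["magma"], out / BUNDLE_FILES["magma"])
    write_gene_set(bundle.gene_sets["cancer"], out / BUNDLE_FILES["cancer"])
    write_network(bundle.network, out / BUNDLE_FILES["network"])
    write_pairs(bundle.network.lr_pairs, out / BUNDLE_FILES["lr_pairs"], ("ligand_gene", "receptor_gene"))
    write_pairs(bundle.network.lpi_pairs, out / BUNDLE_FILES["lpi_pairs"], ("lncrna_gene", "protein_gene"))
    if bundle.reference_calls is not None:
        write_reference_calls(bundle.reference_calls, out / BUNDLE_FILES["reference_calls"])
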