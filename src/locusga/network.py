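"""Interaction-subgraph analysis of proposed / consensus genes.

The induced protein-interaction graph over a gene list keeps edges whose
combined interaction score reaches ``network_combined_min`` (default 0.4,
a deliberately looser filter than the experimental-evidence floor used by
the objective functions).  A *subgraph* is a connected component with at
least two genes; singletons are reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .config import GAConfig
from .stats import ComparisonResult, compare_score_sets, ks_compare
from .types import InteractionNetwork

__all__ = ["GeneGraph", "build_graph", "subgraph_stats", "downsampled_comparison", "components_table"]


@dataclass
class GeneGraph:
    graph: "nx.Graph"
    components: list[set[str]]  # size >= 2, descending size
    isolated: set[str]
    annotations: dict[str, dict]  # gene -> {"locus": ..., "cell_type": ...}

    @property
    def largest_size(self) -> int:
        return len(self.components[0]) if self.components else 0


def build_graph(
    genes: Sequence[str],
    network: InteractionNetwork,
    config: GAConfig,
    annotations: Optional[dict[str, dict]] = None,
) -> GeneGraph:
    """Induced interaction graph on ``genes`` at the combined-score threshold.

    Multiple loci proposing the same gene collapse to a single node; locus
    and cell-type annotations are decorative metadata.
    """
    if not len(genes):
        raise ValueError("gene list must be non-empty")
    node_set = set(genes)
    g = nx.Graph()
    g.add_nodes_from(node_set)
    for a, b in network.combined_edges(config.network_combined_min):
        if a in node_set and b in node_set:
            g.add_edge(a, b)
    comps = [set(c) for c in nx.connected_components(g)]
    big = sorted((c for c in comps if len(c) >= 2), key=len, reverse=True)
    isolated = {n for c in comps if len(c) == 1 for n in c}
    ann = annotations or {}
    for n in g.nodes:
        g.nodes[n].update(ann.get(n, {}))
    return GeneGraph(graph=g, components=big, isolated=isolated, annotations=ann)


def subgraph_stats(graph: GeneGraph) -> tuple[int, list[int], int]:
    """(number of subgraphs, size list descending, largest size), over
    components of size >= 2."""
    sizes = [len(c) for c in graph.components]
    return len(sizes), sizes, (sizes[0] if sizes else 0)


def downsampled_comparison(
    fg_runs: Sequence[dict[str, str]],
    bg_runs: Sequence[dict[str, str]],
    network: InteractionNetwork,
    config: GAConfig,
    n_sub: int,
    reps: int = 20,
    seed: Optional[int] = None,
) -> dict:
    """Largest-subgraph-size comparison with foreground downsampling.

    ``fg_runs`` / ``bg_runs`` are per-run locus -> consensus-gene mappings.
    For each repetition, ``n_sub`` loci are sampled without replacement from
    every foreground run, the induced graph rebuilt and its largest component
    size recorded; background runs are used at full size.  Returns the KS
    test and the Bayesian-bootstrap credible difference over the two size
    samples, plus the raw size lists.
    """
    rng = np.random.default_rng(seed)
    fg_sizes: list[int] = []
    for _ in range(reps):
        for calls in fg_runs:
            loci = list(calls)
            if n_sub > len(loci):
                raise ValueError(f"n_sub ({n_sub}) exceeds locus count ({len(loci)})")
            pick = rng.choice(len(loci), size=n_sub, replace=False)
            genes = [calls[loci[i]] for i in pick]
            fg_sizes.append(build_graph(genes, network, config).largest_size)
    bg_sizes = [
        build_graph(list(calls.values()), network, config).largest_size for calls in bg_runs
    ]
    ks_stat, ks_p = ks_compare(fg_sizes, bg_sizes)
    credible = compare_score_sets(fg_sizes, bg_sizes, seed=None if seed is None else seed + 1)
    return {
        "fg_sizes": fg_sizes,
        "bg_sizes": bg_sizes,
        "ks_statistic": ks_stat,
        "ks_p": ks_p,
        "credible": credible,
    }


def components_table(graph: GeneGraph) -> pd.DataFrame:
    """Long-form component membership: gene, component_id (1-based by
    descending size; 0 for isolated), size, cell_type annotation."""
    rows = []
    for cid, comp in enumerate(graph.components, start=1):
        for gene in sorted(comp):
            rows.append(
                {
                    "gene": gene,
                    "component_id": cid,
                    "size": len(comp),
                    "cell_type": graph.annotations.get(gene, {}).get("cell_type", ""),
                }
            )
    for gene in sorted(graph.isolated):
        rows.append(
            {
                "gene": gene,
                "component_id": 0,
                "size": 1,
                "cell_type": graph.annotations.get(gene, {}).get("cell_type", ""),
            }
        )
    return pd.DataFrame(rows, columns=["gene", "component_id", "size", "cell_type"])
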