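"""Shared fixtures: small synthetic scenarios and brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from locusga.config import GAConfig
from locusga.estimator import LocusAssignmentModel
from locusga.simulate import ScenarioParams, generate_scenario
from locusga.types import CellTypeCatalog, GeneRecord, Locus


def small_config(**overrides) -> GAConfig:
    """A fast GA config for tests: population 100 = 10 pairs x 10 children."""
    base = dict(population_size=100, n_pairs=10, children_per_pair=10, n_generations=30)
    base.update(overrides)
    return GAConfig(**base)


@pytest.fixture(scope="session")
def default_config() -> GAConfig:
    return GAConfig()


@pytest.fixture(scope="session")
def tiny_scenario():
    """4 planted loci x 3 candidates x 4 cells, full signal, zero noise."""
    params = ScenarioParams(
        n_loci=4,
        genes_per_locus=3,
        n_cell_types=4,
        signal_rate=1.0,
        noise_rate=0.0,
        lnc_fraction=0.0,
        lr_pair_rate=0.0,
        extra_edge_prob=0.0,
        distinct_true_cells=True,
    )
    return generate_scenario(params, seed=11)


@pytest.fixture(scope="session")
def small_scenario():
    """12 loci x 6 candidates x 5 cells with realistic signal/noise."""
    params = ScenarioParams(n_loci=12, genes_per_locus=6, n_cell_types=5)
    return generate_scenario(params, seed=5)


@pytest.fixture(scope="session")
def small_model(small_scenario):
    return LocusAssignmentModel(small_scenario.bundle, small_config())


# ---------------------------------------------------------------------------
# brute-force oracles (kept independent of the library's scoring path)

def brute_force_pairwise(proposal, network, markers, config):
    """O(n^2) pair enumeration straight from the objective definitions.

    Works from the raw edge list, not from adjacency structures.
    """
    exp_edges = set()
    comb = {}
    for a, b, exp_s, comb_s in network.edge_list():
        if exp_s > config.ppi_experimental_min:
            exp_edges.add(frozenset((a, b)))
    lr = set(network.lr_pairs)
    lpi = set(network.lpi_pairs)
    lr_universe = set()
    for p in lr:
        lr_universe |= set(p)

    els = list(proposal)
    n = len(els)
    out = {k: np.zeros(n, dtype=bool) for k in ("isPPI", "isLPI", "isInterPPI", "isIntraPPI", "isMarkerPPI")}
    for i in range(n):
        gi, ci = els[i].gene_id, els[i].cell_type
        for j in range(n):
            if i == j:
                continue
            gj, cj = els[j].gene_id, els[j].cell_type
            pair = frozenset((gi, gj))
            if pair in exp_edges:
                out["isPPI"][i] = True
                if (gi, ci) in markers and (gj, cj) in markers:
                    out["isMarkerPPI"][i] = True
                if gi not in lr_universe and gj not in lr_universe and ci == cj:
                    out["isIntraPPI"][i] = True
            if pair in lpi:
                out["isLPI"][i] = True
            if pair in lr and ci != cj:
                out["isInterPPI"][i] = True
    return out


def brute_force_window(locus, genes, config):
    """Candidate set by direct scan: window from SNP min/max, then widened
    per side to the nearest positions capturing min_flank_genes genes."""
    chrom_genes = sorted((g for g in genes if g.chrom == locus.chrom), key=lambda g: g.start)
    lo = max(0, min(locus.positions) - config.window_expand)
    hi = max(locus.positions) + config.window_expand + 1

    def members(a, b):
        return [g for g in chrom_genes if g.start < b and g.end > a]

    lead = locus.lead_pos
    k = config.min_flank_genes
    while sum(1 for g in members(lo, hi) if g.end <= lead) < k and lo > 0:
        lo -= 1
    while (
        sum(1 for g in members(lo, hi) if g.start > lead) < k
        and hi <= max(g.end for g in chrom_genes)
    ):
        hi += 1
    return [g.gene_id for g in sorted(members(lo, hi), key=lambda g: (g.start, g.end, g.gene_id))]


def random_pairwise_instance(rng, n_loci, n_genes=20, n_cells=3):
    """A random proposal + network + marker set for oracle equivalence tests."""
    from locusga.types import InteractionNetwork, Proposal, ProposalElement

    genes = [f"g{k}" for k in range(n_genes)]
    cells = [f"c{k}" for k in range(n_cells)]
    edges = []
    for _ in range(rng.integers(5, 25)):
        a, b = rng.choice(n_genes, size=2, replace=False)
        edges.append((genes[a], genes[b], float(rng.uniform(0, 0.5)), float(rng.uniform(0, 1))))
    lr = []
    for _ in range(rng.integers(0, 5)):
        a, b = rng.choice(n_genes, size=2, replace=False)
        lr.append((genes[a], genes[b]))
    lpi = []
    for _ in range(rng.integers(0, 5)):
        a, b = rng.choice(n_genes, size=2, replace=False)
        lpi.append((genes[a], genes[b]))
    network = InteractionNetwork(edges, lr, lpi)
    markers = {
        (genes[rng.integers(n_genes)], cells[rng.integers(n_cells)]) for _ in range(rng.integers(0, 15))
    }
    els = tuple(
        ProposalElement(f"L{i}", genes[rng.integers(n_genes)], cells[rng.integers(n_cells)])
        for i in range(n_loci)
    )
    return Proposal(els), network, markers
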