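"""Objective-function semantics, the implication lattice, and equivalence of
the object-level and vectorized scoring paths."""

import numpy as np
import pandas as pd
import pytest

from locusga.config import GAConfig
from locusga.objectives import (
    OF_NAMES,
    ObjectiveMatrix,
    ProposalScorer,
    SnpPeakIndex,
    score_atac,
    score_marker_gene,
    score_membership,
    score_pairwise,
    score_promoter,
    score_proposal,
)
from locusga.types import (
    CellTypeCatalog,
    GeneRecord,
    InteractionNetwork,
    Locus,
    Proposal,
    ProposalElement,
)

from conftest import brute_force_pairwise, random_pairwise_instance


def el(locus="L1", gene="g1", cell="c1"):
    return ProposalElement(locus, gene, cell)


class TestMembership:
    def test_in_set(self):
        assert score_membership(el(gene="g1"), {"g1", "g2"})

    def test_not_in_set(self):
        assert not score_membership(el(gene="g3"), {"g1", "g2"})

    def test_empty_set_always_false(self):
        assert not score_membership(el(), set())


class TestPromoter:
    config = GAConfig()
    genes = {"g1": GeneRecord("g1", "g1", "chr1", 10_000, 30_000, "+", "protein_coding")}

    def test_lead_inside(self):
        locus = Locus("L1", "chr1", 9_500, candidate_genes=["g1"])
        assert score_promoter(el(), locus, self.genes, self.config)

    def test_boundary_excluded(self):
        locus = Locus("L1", "chr1", 8_999, candidate_genes=["g1"])
        assert not score_promoter(el(), locus, self.genes, self.config)

    def test_any_proxy_counts(self):
        locus = Locus("L1", "chr1", 500_000, proxies=[("p1", 9_100)], candidate_genes=["g1"])
        assert score_promoter(el(), locus, self.genes, self.config)

    def test_lead_scope_ignores_proxies(self):
        locus = Locus("L1", "chr1", 500_000, proxies=[("p1", 9_100)], candidate_genes=["g1"])
        cfg = GAConfig(snp_scope="lead")
        assert not score_promoter(el(), locus, self.genes, cfg)


def peak_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "cell_type", "is_marker"])


class TestAtac:
    catalog = CellTypeCatalog(["fibroblast", "basal", "adipocyte"])

    def build(self, rows, locus):
        return SnpPeakIndex([locus], peak_frame(rows), self.catalog)

    def test_marker_peak_of_proposed_cell(self):
        locus = Locus("L1", "chr1", 150, candidate_genes=["g1"])
        idx = self.build([("chr1", 100, 200, "fibroblast", 1)], locus)
        assert score_atac(el(cell="fibroblast"), locus, idx) == (False, True)

    def test_common_peak_includes_proposed_cell(self):
        locus = Locus("L1", "chr1", 150, candidate_genes=["g1"])
        rows = [("chr1", 100, 200, c, 0) for c in ("fibroblast", "basal", "adipocyte")]
        idx = self.build(rows, locus)
        assert score_atac(el(cell="basal"), locus, idx) == (True, False)

    def test_cell_type_mismatch(self):
        locus = Locus("L1", "chr1", 150, candidate_genes=["g1"])
        idx = self.build([("chr1", 100, 200, "basal", 1)], locus)
        assert score_atac(el(cell="adipocyte"), locus, idx) == (False, False)

    def test_single_cell_nonmarker_peak_is_not_common(self):
        locus = Locus("L1", "chr1", 150, candidate_genes=["g1"])
        idx = self.build([("chr1", 100, 200, "basal", 0)], locus)
        assert score_atac(el(cell="basal"), locus, idx) == (False, False)


class TestMarkerGene:
    markers = {("g1", "fibroblast"), ("g1", "basal")}

    def test_pair_present(self):
        assert score_marker_gene(el(gene="g1", cell="fibroblast"), self.markers)

    def test_pair_absent(self):
        assert not score_marker_gene(el(gene="g1", cell="adipocyte"), self.markers)

    def test_two_cell_marker(self):
        assert score_marker_gene(el(gene="g1", cell="basal"), self.markers)
        assert not score_marker_gene(el(gene="g2", cell="basal"), self.markers)


class TestPairwise:
    config = GAConfig()

    def test_edge_lights_both_loci(self):
        net = InteractionNetwork([("A", "B", 0.5, 0.9)])
        prop = Proposal((el("L1", "A", "c1"), el("L2", "B", "c2"), el("L3", "C", "c1")))
        out = score_pairwise(prop, net, set(), self.config)
        assert out["isPPI"].tolist() == [True, True, False]

    def test_intra_excludes_lr_universe_and_requires_same_cell(self):
        net = InteractionNetwork([("A", "B", 0.5, 0.9)], lr_pairs=[("X", "Y")])
        same = Proposal((el("L1", "A", "c1"), el("L2", "B", "c1")))
        out = score_pairwise(same, net, set(), self.config)
        assert out["isIntraPPI"].tolist() == [True, True]
        assert out["isInterPPI"].tolist() == [False, False]
        # gene inside the ligand-receptor universe can never be intra-positive
        net2 = InteractionNetwork([("A", "B", 0.5, 0.9)], lr_pairs=[("A", "Z")])
        out2 = score_pairwise(same, net2, set(), self.config)
        assert out2["isIntraPPI"].tolist() == [False, False]

    def test_inter_requires_heterogeneous_cells(self):
        net = InteractionNetwork([], lr_pairs=[("A", "B")])
        hetero = Proposal((el("L1", "A", "c1"), el("L2", "B", "c2")))
        homo = Proposal((el("L1", "A", "c1"), el("L2", "B", "c1")))
        assert score_pairwise(hetero, net, set(), self.config)["isInterPPI"].all()
        assert not score_pairwise(homo, net, set(), self.config)["isInterPPI"].any()

    def test_experimental_floor_is_strict(self):
        net = InteractionNetwork([("A", "B", 0.0, 0.9)])
        prop = Proposal((el("L1", "A", "c1"), el("L2", "B", "c2")))
        assert not score_pairwise(prop, net, set(), self.config)["isPPI"].any()

    def test_duplicate_locus_ids_rejected(self):
        net = InteractionNetwork([])
        prop = Proposal((el("L1", "A", "c1"), el("L1", "B", "c2")))
        with pytest.raises(ValueError, match="duplicate"):
            score_pairwise(prop, net, set(), self.config)

    def test_same_gene_at_two_loci_does_not_self_pair(self):
        net = InteractionNetwork([("A", "A", 0.5, 0.9), ("A", "B", 0.5, 0.9)])
        prop = Proposal((el("L1", "A", "c1"), el("L2", "A", "c2")))
        assert not score_pairwise(prop, net, set(), self.config)["isPPI"].any()

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(1000 + seed)
        n_loci = int(rng.integers(2, 13))
        prop, net, markers = random_pairwise_instance(rng, n_loci)
        got = score_pairwise(prop, net, markers, self.config)
        want = brute_force_pairwise(prop, net, markers, self.config)
        for key in want:
            assert got[key].tolist() == want[key].tolist(), key


class TestScoreProposal:
    def test_fitness_bounds_and_single_column(self, tiny_scenario):
        bundle, config = tiny_scenario.bundle, tiny_scenario.config
        n = len(bundle.loci)
        # a constructed matrix: fractions [1,0,...,0] -> fitness 1/11
        values = np.zeros((2, 11), dtype=bool)
        values[:, 0] = True
        m = ObjectiveMatrix(values)
        assert m.fitness == pytest.approx(1 / 11)
        assert ObjectiveMatrix(np.ones((3, 11), dtype=bool)).fitness == 1.0
        assert ObjectiveMatrix(np.zeros((3, 11), dtype=bool)).fitness == 0.0

    def test_fitness_invariant_to_locus_permutation(self, small_scenario):
        bundle, config = small_scenario.bundle, small_scenario.config
        rng = np.random.default_rng(0)
        els = tuple(
            ProposalElement(
                l.lead_snp_id,
                l.candidate_genes[rng.integers(len(l.candidate_genes))],
                bundle.catalog[rng.integers(len(bundle.catalog))],
            )
            for l in bundle.loci
        )
        base = score_proposal(Proposal(els), bundle, config).fitness
        perm = rng.permutation(len(els))
        loci_perm = [bundle.loci[i] for i in perm]
        bundle_perm = type(bundle)(
            loci=loci_perm,
            genes=bundle.genes,
            catalog=bundle.catalog,
            peaks=bundle.peaks,
            markers=bundle.markers,
            gene_sets=bundle.gene_sets,
            network=bundle.network,
        )
        permuted = score_proposal(Proposal(tuple(els[i] for i in perm)), bundle_perm, config).fitness
        assert permuted == pytest.approx(base)

    @pytest.mark.parametrize("seed", range(5))
    def test_vectorized_scorer_equals_object_path(self, small_scenario, seed):
        bundle, config = small_scenario.bundle, small_scenario.config
        scorer = ProposalScorer(bundle, config)
        rng = np.random.default_rng(seed)
        P = 8
        K = np.stack([rng.integers(0, scorer.n_cand) for _ in range(P)])
        C = rng.integers(0, scorer.n_cells, size=(P, scorer.n_loci))
        grids = scorer.score_grids(K, C)
        for i in range(P):
            prop = scorer.decode(K[i], C[i])
            ref = score_proposal(prop, bundle, config)
            assert np.array_equal(grids[i], ref.values)

    def test_implication_lattice(self, small_scenario):
        bundle, config = small_scenario.bundle, small_scenario.config
        scorer = ProposalScorer(bundle, config)
        rng = np.random.default_rng(3)
        K = np.array([rng.integers(0, scorer.n_cand) for _ in range(50)])
        C = rng.integers(0, scorer.n_cells, size=(50, scorer.n_loci))
        g = scorer.score_grids(K, C)
        names = list(OF_NAMES)
        mppi = g[:, :, names.index("isMarkerPPI")]
        ppi = g[:, :, names.index("isPPI")]
        mg = g[:, :, names.index("isMarkerGene")]
        intra = g[:, :, names.index("isIntraPPI")]
        assert not (mppi & ~ppi).any()
        assert not (mppi & ~mg).any()
        assert not (intra & ~ppi).any()
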