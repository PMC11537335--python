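"""Model / Results objects over the genetic-algorithm optimizer.

:class:`LocusAssignmentModel` wraps a data bundle and configuration the way a
statistical model wraps its design matrix; ``fit(seed)`` executes the
generational loop and returns a :class:`GAResults` carrying the final
population, the elite, the trace and the consensus machinery, with a
``summary()`` table of per-objective scores.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .consensus import (
    ConsensusCall,
    apply_confidence,
    confidence_threshold,
    consensus as consensus_call,
)
from .config import GAConfig
from .ga import Population, RunTrace, run, termination_generation
from .io import load_inputs
from .objectives import OF_NAMES, ObjectiveMatrix, ProposalScorer
from .types import DataBundle, Proposal

__all__ = ["LocusAssignmentModel", "GAResults"]


class LocusAssignmentModel:
    """Genetic-algorithm assignment of a (gene, cell type) pair per GWAS locus.

    Parameters
    ----------
    bundle
        Cross-referenced inputs: loci with candidate gene sets, gene
        annotation, cell-type catalog, accessible peaks, marker genes,
        membership sets and the interaction network.
    config
        All numeric constants of the method; defaults reproduce the
        published settings (population 1,000, 200 generations, five rank
        groups, 1% mutation).

    Examples
    --------
    >>> from locusga.simulate import generate_scenario
    >>> scenario = generate_scenario(seed=7)
    >>> model = LocusAssignmentModel(scenario.bundle, scenario.config)
    >>> result = model.fit(seed=7)          # doctest: +SKIP
    >>> result.consensus_calls()            # doctest: +SKIP
    """

    def __init__(self, bundle: DataBundle, config: Optional[GAConfig] = None):
        self.bundle = bundle
        self.config = config or GAConfig()
        self.scorer = ProposalScorer(bundle, self.config)

    @classmethod
    def from_directory(cls, path: str | Path, config: Optional[GAConfig] = None) -> "LocusAssignmentModel":
        config = config or GAConfig()
        return cls(load_inputs(path, config), config)

    @property
    def n_loci(self) -> int:
        return len(self.bundle.loci)

    def fit(self, seed: Optional[int] = None) -> "GAResults":
        population, trace, elite_history = run(self.bundle, self.config, seed=seed, scorer=self.scorer)
        return GAResults(self, population, trace, elite_history,
                         seed=self.config.rng_seed if seed is None else seed)

    def fit_replicates(self, seeds: Sequence[int]) -> list["GAResults"]:
        """Independent runs differing only in their initial population seed."""
        return [self.fit(seed=s) for s in seeds]


class GAResults:
    """Fitted genetic-algorithm run: final population, elite, trace, consensus."""

    def __init__(
        self,
        model: LocusAssignmentModel,
        population: Population,
        trace: RunTrace,
        elite_history: list[tuple[int, float]],
        seed: int,
    ):
        self.model = model
        self.population = population
        self.trace = trace
        self.elite_history = elite_history
        self.seed = seed
        self._consensus: Optional[tuple[Proposal, ObjectiveMatrix, list[ConsensusCall]]] = None

    # -- basic accessors ----------------------------------------------------

    @property
    def elite(self) -> Proposal:
        return self.population.proposal(self.population.elite_index())

    @property
    def elite_fitness(self) -> float:
        return float(self.population.fitness.max())

    @property
    def mean_fitness(self) -> float:
        return float(self.population.fitness.mean())

    @property
    def termination_generation(self) -> Optional[int]:
        return self.trace.termination_generation

    def of_fractions(self) -> pd.Series:
        """Population-mean per-objective positive fractions at the final generation."""
        return pd.Series(self.population.fractions.mean(axis=0), index=list(OF_NAMES))

    # -- consensus ----------------------------------------------------------

    def consensus(self) -> tuple[Proposal, ObjectiveMatrix, list[ConsensusCall]]:
        if self._consensus is None:
            self._consensus = consensus_call(self.population, self.model.config)
        return self._consensus

    def consensus_calls(self) -> list[ConsensusCall]:
        return self.consensus()[2]

    def consensus_fitness(self) -> float:
        return self.consensus()[1].fitness

    def support_counts(self) -> pd.Series:
        """Positive-OF count (0..11) per locus for the consensus element."""
        _, matrix, calls = self.consensus()
        return pd.Series(matrix.support_counts(), index=[c.locus_id for c in calls])

    def calibrate_confidence(self, reference: Optional[pd.DataFrame] = None) -> int:
        """Calibrate and apply the high-confidence vote threshold."""
        reference = reference if reference is not None else self.model.bundle.reference_calls
        if reference is None:
            raise ValueError("no reference call table available")
        calls = self.consensus_calls()
        t = confidence_threshold(calls, reference, self.model.config)
        apply_confidence(calls, t)
        return t

    # -- presentation -------------------------------------------------------

    def trace_frame(self) -> pd.DataFrame:
        return self.trace.to_frame()

    def summary(self) -> str:
        cfg = self.model.config
        _, matrix, _ = self.consensus()
        lines = [
            "Locus assignment by genetic algorithm",
            "=" * 53,
            f"loci: {self.model.n_loci:>6d}    population: {cfg.population_size}",
            f"generations: {cfg.n_generations}    seed: {self.seed}",
            f"termination rule first met: "
            + (str(self.termination_generation) if self.termination_generation is not None else "not reached"),
            "-" * 53,
            f"elite fitness:     {self.elite_fitness:.4f}",
            f"mean fitness:      {self.mean_fitness:.4f}",
            f"consensus fitness: {matrix.fitness:.4f}",
            "-" * 53,
            f"{'objective':<16s}{'population':>12s}{'consensus':>12s}",
        ]
        pop_fracs = self.of_fractions()
        for k, name in enumerate(OF_NAMES):
            lines.append(f"{name:<16s}{pop_fracs[name]:>12.3f}{matrix.of_fractions[k]:>12.3f}")
        lines.append("=" * 53)
        return "\n".join(lines)

    def plot_trace(self, ax=None):
        """Fitness trace (mean and max per generation)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.trace_frame()
        ax.plot(df["generation"], df["mean_fitness"], label="mean fitness")
        ax.plot(df["generation"], df["max_fitness"], label="max fitness")
        if self.termination_generation is not None:
            ax.axvline(self.termination_generation, ls="--", color="red", alpha=0.6,
                       label="convergence rule met")
        ax.set_xlabel("generation")
        ax.set_ylabel("fitness")
        ax.legend()
        return ax

    def save(self, out_dir: str | Path) -> None:
        """Persist trace.tsv, final_population.tsv and elite.tsv."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.trace_frame().to_csv(out / "trace.tsv", sep="\t", index=False)
        rows = []
        for i in range(len(self.population)):
            for l, locus in enumerate(self.model.bundle.loci):
                rows.append(
                    {
                        "proposal_id": i,
                        "locus": locus.lead_snp_id,
                        "gene": self.model.scorer.candidates[l][int(self.population.K[i, l])],
                        "cell": self.model.bundle.catalog[int(self.population.C[i, l])],
                    }
                )
        pd.DataFrame(rows).to_csv(out / "final_population.tsv", sep="\t", index=False)
        elite = self.elite
        pd.DataFrame(
            [
                {"locus": el.locus_id, "gene": el.gene_id, "cell": el.cell_type}
                for el in elite
            ]
        ).to_csv(out / "elite.tsv", sep="\t", index=False)
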