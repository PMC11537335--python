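"""The generational loop: initialization, rank-group selection, crossover,
mutation, elitism and the convergence diagnostic.

One generation: score the population, rank proposals by fitness into
``n_groups`` equal groups (group 1 highest), draw ``2 * n_pairs`` distinct
parents without replacement with group-weighted probability, produce
``children_per_pair`` children per pair by uniform half/half locus crossover,
mutate every child element's gene and cell type independently with
probability ``mutation_rate``, then replace one random member of the child
generation's lowest-ranked group with the parent generation's elite.

The convergence rule (moving average of the absolute percent change in mean
fitness staying at or below ``termination_pct`` for ``termination_window``
consecutive generations) is evaluated and reported, but the run always uses
the full generation budget; the generation at which the rule first fired is
recorded in the trace metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import GAConfig
from .objectives import OF_NAMES, ProposalScorer
from .types import CellTypeCatalog, DataBundle, Locus, Proposal

logger = logging.getLogger(__name__)

__all__ = [
    "Population",
    "RunTrace",
    "init_population",
    "rank_and_group",
    "select_pairs",
    "crossover",
    "mutate",
    "apply_elitism",
    "check_termination",
    "termination_generation",
    "run",
]


@dataclass
class Population:
    """Integer-coded population: per-locus candidate index and cell index."""

    K: np.ndarray  # (P, L) candidate index within each locus's candidate set
    C: np.ndarray  # (P, L) cell index within the catalog
    scorer: ProposalScorer
    generation: int = 0
    fitness: Optional[np.ndarray] = None  # (P,)
    fractions: Optional[np.ndarray] = None  # (P, 11)

    def __post_init__(self) -> None:
        if self.K.shape != self.C.shape:
            raise ValueError("K and C must have identical shapes")
        n_cand = self.scorer.n_cand
        if (self.K < 0).any() or (self.K >= n_cand[None, :]).any():
            raise ValueError("candidate index out of range for its locus")
        if (self.C < 0).any() or (self.C >= self.scorer.n_cells).any():
            raise ValueError("cell index out of range")

    def __len__(self) -> int:
        return self.K.shape[0]

    @property
    def n_loci(self) -> int:
        return self.K.shape[1]

    def score(self) -> None:
        self.fractions, self.fitness = self.scorer.score_population(self.K, self.C)

    def proposal(self, i: int) -> Proposal:
        p = self.scorer.decode(self.K[i], self.C[i])
        if self.fitness is not None:
            p.fitness = float(self.fitness[i])
        return p

    @property
    def proposals(self) -> list[Proposal]:
        return [self.proposal(i) for i in range(len(self))]

    def elite_index(self) -> int:
        if self.fitness is None:
            self.score()
        return int(np.argmax(self.fitness))


@dataclass
class RunTrace:
    """Per-generation summaries: mean/max fitness and mean OF fractions."""

    rows: list[dict] = field(default_factory=list)
    termination_generation: Optional[int] = None

    def append(self, generation: int, fitness: np.ndarray, fractions: np.ndarray) -> None:
        row = {
            "generation": generation,
            "mean_fitness": float(fitness.mean()),
            "max_fitness": float(fitness.max()),
        }
        mean_fracs = fractions.mean(axis=0)
        for name, v in zip(OF_NAMES, mean_fracs):
            row[name] = float(v)
        self.rows.append(row)

    @property
    def mean_fitness(self) -> np.ndarray:
        return np.array([r["mean_fitness"] for r in self.rows])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rows)
        df.attrs["termination_generation"] = self.termination_generation
        return df

    def __len__(self) -> int:
        return len(self.rows)


def init_population(
    loci: Sequence[Locus],
    catalog: CellTypeCatalog,
    config: GAConfig,
    rng: np.random.Generator,
    scorer: ProposalScorer,
) -> Population:
    """Uniform random population: gene uniform over each locus's candidates,
    cell uniform over the catalog."""
    if not len(loci):
        raise ValueError("cannot initialize a population with zero loci")
    P, L = config.population_size, len(loci)
    u = rng.random((P, L))
    K = np.floor(u * scorer.n_cand[None, :]).astype(np.int64)
    C = rng.integers(0, len(catalog), size=(P, L))
    return Population(K=K, C=C, scorer=scorer)


def rank_and_group(population: Population, rng: np.random.Generator, config: GAConfig) -> tuple[Population, list[np.ndarray]]:
    """Sort by fitness descending into ``n_groups`` equal groups.

    Ties are broken by a seeded shuffle applied before a stable sort, so
    equal-fitness proposals are permuted reproducibly.  Returns the sorted
    population and index arrays (into the sorted order) per group.
    """
    if population.fitness is None:
        population.score()
    P = len(population)
    if P % config.n_groups != 0:
        raise ValueError("population size must be divisible by n_groups")
    perm = rng.permutation(P)
    order = perm[np.argsort(-population.fitness[perm], kind="stable")]
    ranked = Population(
        K=population.K[order],
        C=population.C[order],
        scorer=population.scorer,
        generation=population.generation,
        fitness=population.fitness[order],
        fractions=population.fractions[order],
    )
    size = P // config.n_groups
    groups = [np.arange(g * size, (g + 1) * size) for g in range(config.n_groups)]
    return ranked, groups


def select_pairs(
    groups: list[np.ndarray],
    config: GAConfig,
    rng: np.random.Generator,
) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Draw ``2 * n_pairs`` distinct parents without replacement.

    Each draw picks a group with probability proportional to its weight
    (renormalized over groups with members remaining), then a uniform member
    of that group's remaining pool.  Draws are paired sequentially.  Returns
    the pairs (indices into the ranked population) and the group index of
    every draw, in draw order.
    """
    pools = [list(g) for g in groups]
    weights = np.asarray(config.group_weights, dtype=float)
    n_draw = 2 * config.n_pairs
    if n_draw > sum(len(p) for p in pools):
        raise ValueError("not enough proposals to draw the requested parents")
    drawn: list[int] = []
    drawn_groups = np.empty(n_draw, dtype=np.int64)
    for t in range(n_draw):
        avail = np.array([len(p) > 0 for p in pools])
        w = np.where(avail, weights, 0.0)
        w = w / w.sum()
        g = int(rng.choice(len(pools), p=w))
        pool = pools[g]
        j = int(rng.integers(len(pool)))
        drawn.append(pool.pop(j))
        drawn_groups[t] = g
    pairs = [(drawn[2 * i], drawn[2 * i + 1]) for i in range(config.n_pairs)]
    return pairs, drawn_groups


def _crossover_masks(n_children: int, n_loci: int, rng: np.random.Generator) -> np.ndarray:
    """(n_children, L) boolean masks, each with exactly floor(L/2) True
    positions chosen uniformly (loci taken from parent A)."""
    half = n_loci // 2
    u = rng.random((n_children, n_loci))
    rank = np.argsort(np.argsort(u, axis=1), axis=1)
    return rank < half


def crossover(
    parent_a: Proposal | tuple[np.ndarray, np.ndarray],
    parent_b: Proposal | tuple[np.ndarray, np.ndarray],
    n_children: int,
    rng: np.random.Generator,
    scorer: Optional[ProposalScorer] = None,
) -> list[Proposal] | tuple[np.ndarray, np.ndarray]:
    """Uniform half/half crossover.

    Each child takes an independent uniformly random subset of floor(L/2)
    loci from parent A and the complement from parent B.  Accepts either
    domain Proposals (requires ``scorer``; returns Proposals) or integer-coded
    (K_row, C_row) tuples (returns stacked child arrays).
    """
    as_objects = isinstance(parent_a, Proposal)
    if as_objects:
        if scorer is None:
            raise ValueError("scorer required for object-level crossover")
        Ka, Ca = scorer.encode(parent_a)
        Kb, Cb = scorer.encode(parent_b)
        Ka, Ca, Kb, Cb = Ka[0], Ca[0], Kb[0], Cb[0]
    else:
        Ka, Ca = parent_a
        Kb, Cb = parent_b
    L = Ka.shape[0]
    mask = _crossover_masks(n_children, L, rng)
    K = np.where(mask, Ka[None, :], Kb[None, :])
    C = np.where(mask, Ca[None, :], Cb[None, :])
    if as_objects:
        return [scorer.decode(K[i], C[i]) for i in range(n_children)]
    return K, C


def _mutation_masks(shape: tuple[int, ...], rate: float, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Independent Bernoulli(rate) event masks for the gene and cell fields."""
    return rng.random(shape) < rate, rng.random(shape) < rate


def mutate_population(
    K: np.ndarray,
    C: np.ndarray,
    scorer: ProposalScorer,
    config: GAConfig,
    rng: np.random.Generator,
    return_events: bool = False,
):
    """Vectorized mutation of a child block.

    For every element independently, with probability ``mutation_rate`` the
    gene is resampled uniformly from the locus's candidate set and, in an
    independent event, the cell type is resampled uniformly from the catalog.
    Resampling may redraw the current value, so an *event* is not always a
    *change*.
    """
    gene_mask, cell_mask = _mutation_masks(K.shape, config.mutation_rate, rng)
    new_K = np.floor(rng.random(K.shape) * scorer.n_cand[None, :]).astype(np.int64)
    new_C = rng.integers(0, scorer.n_cells, size=C.shape)
    K = np.where(gene_mask, new_K, K)
    C = np.where(cell_mask, new_C, C)
    if return_events:
        return K, C, gene_mask, cell_mask
    return K, C


def mutate(
    child: Proposal,
    loci: Sequence[Locus],
    catalog: CellTypeCatalog,
    config: GAConfig,
    rng: np.random.Generator,
    scorer: ProposalScorer,
) -> Proposal:
    """Object-level mutation of a single child proposal."""
    K, C = scorer.encode(child)
    K, C = mutate_population(K, C, scorer, config, rng)
    return scorer.decode(K[0], C[0])


def apply_elitism(
    children: Population,
    elite: tuple[np.ndarray, np.ndarray],
    rng: np.random.Generator,
    config: GAConfig,
) -> Population:
    """Replace one uniformly chosen member of the child generation's
    lowest-ranked group with the parent generation's elite.

    ``children`` must already be scored; the returned population is ranked
    (sorted by fitness) with the replacement applied and rescored fitness for
    the substituted slot.
    """
    ranked, groups = rank_and_group(children, rng, config)
    low = groups[-1]
    slot = int(low[rng.integers(len(low))])
    eK, eC = elite
    ranked.K[slot] = eK
    ranked.C[slot] = eC
    fr, fit = ranked.scorer.score_population(eK[None, :], eC[None, :])
    ranked.fractions[slot] = fr[0]
    ranked.fitness[slot] = fit[0]
    return ranked


def smoothed_pct_change(mean_fitness: np.ndarray, smoothing_window: int) -> np.ndarray:
    """Moving average (window ``smoothing_window``) of the absolute percent
    change in mean fitness; entry t corresponds to generation t (valid from
    t = smoothing_window)."""
    m = np.asarray(mean_fitness, dtype=float)
    pct = np.full(m.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct[1:] = np.abs(np.diff(m) / m[:-1]) * 100.0
    out = np.full(m.shape, np.nan)
    w = smoothing_window
    for t in range(w, len(m)):
        out[t] = np.nanmean(pct[t - w + 1 : t + 1])
    return out


def termination_generation(trace: RunTrace | np.ndarray, config: GAConfig) -> Optional[int]:
    """First generation at which the smoothed percent change has stayed at or
    below ``termination_pct`` for ``termination_window`` consecutive
    generations, or None."""
    m = trace.mean_fitness if isinstance(trace, RunTrace) else np.asarray(trace, dtype=float)
    sm = smoothed_pct_change(m, config.smoothing_window)
    ok = sm <= config.termination_pct  # NaN compares False
    run_len = 0
    for t in range(len(m)):
        run_len = run_len + 1 if ok[t] else 0
        if run_len >= config.termination_window:
            return t
    return None


def check_termination(trace: RunTrace | np.ndarray, config: GAConfig) -> bool:
    """True iff the convergence rule holds at the end of the trace."""
    m = trace.mean_fitness if isinstance(trace, RunTrace) else np.asarray(trace, dtype=float)
    if len(m) < config.smoothing_window + config.termination_window:
        return False
    sm = smoothed_pct_change(m, config.smoothing_window)
    tail = sm[-config.termination_window:]
    return bool(np.all(~np.isnan(tail) & (tail <= config.termination_pct)))


def run(
    bundle: DataBundle,
    config: GAConfig,
    seed: Optional[int] = None,
    scorer: Optional[ProposalScorer] = None,
) -> tuple[Population, RunTrace, list[tuple[int, float]]]:
    """Execute the full generational loop.

    Returns the final (ranked) population, the per-generation trace, and the
    elite history as (generation, elite fitness) tuples.  The run is fully
    determined by ``seed``; per-generation RNG sub-streams keep results
    stable under refactoring of within-generation draw order.
    """
    if seed is None:
        seed = config.rng_seed
    if scorer is None:
        scorer = ProposalScorer(bundle, config)
    ss = np.random.SeedSequence(seed)
    init_ss, *gen_ss = ss.spawn(config.n_generations + 1)
    rng0 = np.random.default_rng(init_ss)

    population = init_population(bundle.loci, bundle.catalog, config, rng0, scorer)
    population.score()
    trace = RunTrace()
    trace.append(0, population.fitness, population.fractions)
    elite_history: list[tuple[int, float]] = []

    for gen in range(1, config.n_generations + 1):
        rng = np.random.default_rng(gen_ss[gen - 1])
        ranked, groups = rank_and_group(population, rng, config)
        elite_idx = 0  # ranked order: index 0 is the elite
        elite = (ranked.K[elite_idx].copy(), ranked.C[elite_idx].copy())
        elite_history.append((gen - 1, float(ranked.fitness[elite_idx])))

        pairs, _ = select_pairs(groups, config, rng)
        n_children = config.n_pairs * config.children_per_pair
        L = ranked.n_loci
        childK = np.empty((n_children, L), dtype=np.int64)
        childC = np.empty((n_children, L), dtype=np.int64)
        for p, (ia, ib) in enumerate(pairs):
            s = p * config.children_per_pair
            e = s + config.children_per_pair
            cK, cC = crossover(
                (ranked.K[ia], ranked.C[ia]),
                (ranked.K[ib], ranked.C[ib]),
                config.children_per_pair,
                rng,
            )
            childK[s:e] = cK
            childC[s:e] = cC
        childK, childC = mutate_population(childK, childC, scorer, config, rng)
        children = Population(K=childK, C=childC, scorer=scorer, generation=gen)
        children.score()
        population = apply_elitism(children, elite, rng, config)
        trace.append(gen, population.fitness, population.fractions)

    elite_history.append((config.n_generations, float(population.fitness.max())))
    trace.termination_generation = termination_generation(trace, config)
    if trace.termination_generation is not None:
        logger.info("convergence rule first satisfied at generation %d", trace.termination_generation)
    return population, trace, elite_history
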