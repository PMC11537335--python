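"""Run configuration: every numeric constant of the method in one place.

The defaults reproduce the published analysis settings: a population of
1,000 proposals evolved for 200 generations, rank-group selection over five
groups, 100 parent pairs each producing 10 children, and a 1% per-field
mutation rate.  Data-conversion thresholds (candidate window, promoter
geometry, marker significance cut-offs, interaction-score floors) live here
too so that the objective functions themselves are pure membership tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["GAConfig", "load_config", "save_config"]


@dataclass
class GAConfig:
    # genetic-algorithm loop
    population_size: int = 1000
    n_generations: int = 200
    n_groups: int = 5
    n_pairs: int = 100
    children_per_pair: int = 10
    mutation_rate: float = 0.01
    #: rank-group sampling weights, highest-fitness group first.  Linear
    #: rank weights are the simplest scheme consistent with selection
    #: probability proportional to fitness rank.
    group_weights: tuple[float, ...] = (5.0, 4.0, 3.0, 2.0, 1.0)

    # candidate ("nearby") gene set construction
    window_expand: int = 200_000
    min_flank_genes: int = 5

    # promoter geometry (relative to the TSS, strand-aware)
    promoter_upstream: int = 1000
    promoter_downstream: int = 100

    # interaction-network filters
    ppi_experimental_min: float = 0.0  # edges kept when experimental score strictly exceeds this
    network_combined_min: float = 0.4  # combined-score threshold for subgraph analysis

    # marker thresholds applied once at load time
    marker_atac_fdr: float = 0.05
    marker_atac_lfc: float = 0.25
    marker_gene_p: float = 0.05
    marker_gene_lfc: float = 0.25

    # consensus confidence calibration
    confidence_sensitivity: float = 0.8
    reference_score_min: float = 0.7

    # call-diversity filter
    gini_max: float = 0.5
    gini_gene_count_max: int = 2

    # termination rule (reported, not enforced: the run uses the full budget)
    termination_pct: float = 1.0
    termination_window: int = 10
    smoothing_window: int = 5

    rng_seed: int = 0

    # behavioural switches for points the method leaves open
    #: common-peak overlap must include the proposed cell type (cell-aware);
    #: set False for the cell-agnostic variant.
    common_atac_cell_specific: bool = True
    #: SNP-overlap objectives test every SNP of the locus ("all") or only the
    #: lead SNP ("lead").
    snp_scope: str = "all"
    #: marker-PPI requires marker-valid cell types at both loci of the pair.
    marker_ppi_both_cells: bool = True
    #: consensus gene and cell are modal independently; True takes the modal
    #: joint (gene, cell) pair instead.
    consensus_joint_mode: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.population_size != self.n_pairs * self.children_per_pair:
            raise ValueError(
                f"population_size ({self.population_size}) must equal "
                f"n_pairs x children_per_pair ({self.n_pairs} x {self.children_per_pair})"
            )
        if self.population_size % self.n_groups != 0:
            raise ValueError(
                f"population_size ({self.population_size}) must be divisible by "
                f"n_groups ({self.n_groups})"
            )
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be a probability in [0, 1]")
        if not 0.0 <= self.confidence_sensitivity <= 1.0:
            raise ValueError("confidence_sensitivity must be a probability in [0, 1]")
        if len(self.group_weights) != self.n_groups:
            raise ValueError("group_weights must have one weight per group")
        if any(w < 0 for w in self.group_weights) or sum(self.group_weights) <= 0:
            raise ValueError("group_weights must be non-negative with positive sum")
        if self.snp_scope not in ("all", "lead"):
            raise ValueError("snp_scope must be 'all' or 'lead'")
        for name in ("window_expand", "min_flank_genes", "promoter_upstream",
                     "promoter_downstream", "n_generations"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["group_weights"] = list(self.group_weights)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GAConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "group_weights" in d:
            d = dict(d)
            d["group_weights"] = tuple(d["group_weights"])
        return cls(**d)


def load_config(path: str | Path) -> GAConfig:
    """Read a YAML config whose keys match :class:`GAConfig` fields."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return GAConfig.from_dict(data)


def save_config(config: GAConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
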