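"""Foreground-vs-control statistics.

Enrichment of a boolean objective function (or of fitness) in a foreground
set relative to matched controls is summarized by the Monte-Carlo posterior
distribution of the foreground-minus-background difference:

* proportions: independent Beta(1 + k, 1 + n - k) posteriors (uniform
  prior) on each side, differenced over Monte-Carlo draws;
* score sets: the Bayesian bootstrap — each draw reweights the observations
  with Dirichlet(1, ..., 1) weights and takes the weighted mean.

A contrast is *enriched* when zero is excluded from the central 95% interval
of the difference draws.  The exceedance probability is the one-sided
P(difference <= 0).  Per-locus support contrasts use the two-sided Wilcoxon
rank-sum test with Benjamini-Hochberg correction across loci.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "compare_proportions",
    "compare_score_sets",
    "ks_compare",
    "locus_support_tests",
    "benjamini_hochberg",
]


@dataclass
class ComparisonResult:
    effect_size: float  # median of the difference draws
    ci95: tuple[float, float]
    exceed_prob: float  # P(difference <= 0)
    enriched: bool  # zero excluded from ci95

    @classmethod
    def from_draws(cls, diff: np.ndarray) -> "ComparisonResult":
        lo, hi = np.percentile(diff, [2.5, 97.5])
        return cls(
            effect_size=float(np.median(diff)),
            ci95=(float(lo), float(hi)),
            exceed_prob=float(np.mean(diff <= 0.0)),
            enriched=not (lo <= 0.0 <= hi),
        )


def compare_proportions(
    fg: tuple[int, int],
    bg: tuple[int, int],
    draws: int = 10_000,
    seed: Optional[int] = None,
) -> ComparisonResult:
    """Credible difference of two proportions under Beta(1,1) priors.

    ``fg`` and ``bg`` are (positives, n) pairs.
    """
    rng = np.random.default_rng(seed)
    (k1, n1), (k0, n0) = fg, bg
    if n1 <= 0 or n0 <= 0:
        raise ValueError("both sides need n > 0")
    p1 = rng.beta(1 + k1, 1 + n1 - k1, size=draws)
    p0 = rng.beta(1 + k0, 1 + n0 - k0, size=draws)
    return ComparisonResult.from_draws(p1 - p0)


def compare_score_sets(
    fg: Sequence[float],
    bg: Sequence[float],
    draws: int = 10_000,
    seed: Optional[int] = None,
) -> ComparisonResult:
    """Credible difference of two score-set means via the Bayesian bootstrap."""
    fg = np.asarray(fg, dtype=float)
    bg = np.asarray(bg, dtype=float)
    if fg.size == 0 or bg.size == 0:
        raise ValueError("both score sets must be non-empty")
    rng = np.random.default_rng(seed)
    w1 = rng.dirichlet(np.ones(fg.size), size=draws)
    w0 = rng.dirichlet(np.ones(bg.size), size=draws)
    return ComparisonResult.from_draws(w1 @ fg - w0 @ bg)


def ks_compare(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic (max ECDF distance) and p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.ks_2samp(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def benjamini_hochberg(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, order-preserving)."""
    return sps.false_discovery_control(np.asarray(p, dtype=float), method="bh")


def _ranksum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p: exact enumeration for
    small untied samples, normal approximation with tie correction otherwise.
    Identical constant samples give p = 1 by convention."""
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        return 0.5 * len(x) * len(y), 1.0
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) < 8 and len(y) < 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def locus_support_tests(
    fg_support: pd.DataFrame,
    bg_support: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-locus comparison of objective-function support counts across runs.

    Inputs are loci x runs tables of per-locus positive-OF counts (0..11) for
    the foreground and background run sets (loci on the index).  Returns one
    row per shared locus with the rank-sum statistic, raw and BH-adjusted
    p-values, the effect direction (sign of the median difference), and the
    significance call at ``alpha``.
    """
    shared = fg_support.index.intersection(bg_support.index)
    if shared.empty:
        raise ValueError("no shared loci between foreground and background tables")
    rows = []
    for locus in shared:
        x = np.asarray(fg_support.loc[locus], dtype=float)
        y = np.asarray(bg_support.loc[locus], dtype=float)
        if x.size < 2 or y.size < 2:
            raise ValueError(f"{locus}: need at least 2 runs per side")
        stat, p = _ranksum(x, y)
        rows.append(
            {
                "locus": locus,
                "W": stat,
                "p": p,
                "direction": int(np.sign(np.median(x) - np.median(y))),
            }
        )
    out = pd.DataFrame(rows).set_index("locus")
    out["p_adj"] = benjamini_hochberg(out["p"].to_numpy())
    out["significant"] = out["p_adj"] <= alpha
    return out
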