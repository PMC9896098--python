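"""Nonparametric FWER control by the permutation distribution of the maximum.

Subjects are repeatedly relabeled into two balanced groups; for each split
the image-wide maximum statistic (peak |t|, or largest suprathreshold cluster
extent) is recorded.  With M splits sorted ascending, the critical value is
the c'th largest with c = floor(alpha * M) + 1, and the null is rejected for
observed values strictly greater.  Empirical p-values are quantized in steps
of 1/M.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .connectivity import group_tmaps_for_splits, label_excursions

__all__ = [
    "SplitPlan",
    "MaxNullDistribution",
    "enumerate_splits",
    "sample_splits",
    "max_stat_distribution",
    "critical_value",
    "empirical_pvalue",
]


@dataclass
class SplitPlan:
    """Balanced two-group subject splits (group-A index subsets)."""

    n_subjects: int
    group_size: int
    mode: str                      # {"enumerated", "sampled"}
    M: int
    rng_seed: int | None = None
    assignments: list | None = None  # materialized subsets, or None when lazy

    def iter_assignments(self):
        if self.assignments is not None:
            yield from self.assignments
        else:
            from itertools import combinations

            yield from combinations(range(self.n_subjects), self.group_size)


@dataclass
class MaxNullDistribution:
    """Sorted permutation maxima with critical-value bookkeeping."""

    kind: str                  # {"pixel_abs_t", "cluster_size"}
    values: np.ndarray         # sorted ascending, length M
    alpha: float
    c: int = field(init=False)
    critical_value: float = field(init=False)

    def __post_init__(self):
        self.values = np.sort(np.asarray(self.values, dtype=float))
        M = self.values.size
        self.c = int(math.floor(self.alpha * M)) + 1
        self.critical_value = float(self.values[M - self.c])

    @property
    def M(self) -> int:
        return int(self.values.size)


# ---------------------------------------------------------------------------
# Split plans
# ---------------------------------------------------------------------------

def enumerate_splits(n: int, k: int, cap: int | None = None) -> SplitPlan:
    """All C(n, k) group-A subsets in lexicographic order (lazily iterated)."""
    M = math.comb(n, k)
    if cap is not None and M > cap:
        raise ValueError(
            f"C({n},{k}) = {M} exceeds cap {cap}; use sample_splits instead"
        )
    return SplitPlan(n_subjects=n, group_size=k, mode="enumerated", M=M)


def _unrank_combination(rank: int, n: int, k: int) -> tuple:
    """The ``rank``'th k-subset of range(n) in lexicographic order."""
    out = []
    r = rank
    x = 0
    for i in range(k, 0, -1):
        while math.comb(n - x - 1, i - 1) <= r:
            r -= math.comb(n - x - 1, i - 1)
            x += 1
        out.append(x)
        x += 1
    return tuple(out)


def sample_splits(n: int, k: int, M: int, rng_seed: int) -> SplitPlan:
    """M distinct subsets drawn uniformly among all C(n, k), seeded."""
    total = math.comb(n, k)
    if M > total:
        raise ValueError(f"cannot draw {M} distinct subsets from C({n},{k}) = {total}")
    rng = np.random.default_rng(rng_seed)
    if total <= max(10 * M, 1_000_000):
        ranks = rng.choice(total, size=M, replace=False)
    else:
        seen: set[int] = set()
        while len(seen) < M:
            need = M - len(seen)
            seen.update(int(r) for r in rng.integers(0, total, size=2 * need))
        ranks = rng.permutation(np.fromiter(seen, dtype=np.int64))[:M]
    assignments = [_unrank_combination(int(r), n, k) for r in ranks]
    return SplitPlan(n_subjects=n, group_size=k, mode="sampled", M=M,
                     rng_seed=rng_seed, assignments=assignments)


# ---------------------------------------------------------------------------
# Maximum-statistic distribution
# ---------------------------------------------------------------------------

def max_stat_distribution(
    maps: np.ndarray,
    plan: SplitPlan,
    statistic: str = "pixel_abs_t",
    analysis_mask: np.ndarray | None = None,
    cluster_threshold: float | None = None,
    alpha: float = 0.05,
) -> MaxNullDistribution:
    """One image-wide maximum per split, over the analysis mask.

    ``maps`` is ``(n_subjects, rows, cols)`` with complete data inside the
    mask.  For ``statistic="pixel_abs_t"`` the maximum of |t| is recorded;
    for ``"cluster_size"`` the largest two-sided cluster extent at
    ``cluster_threshold`` (0 when no pixel is suprathreshold), so the
    distribution always has M entries.
    """
    maps = np.asarray(maps, dtype=float)
    if analysis_mask is None:
        analysis_mask = np.ones(maps.shape[1:], dtype=bool)
    if statistic == "cluster_size" and cluster_threshold is None:
        raise ValueError("cluster_size statistic requires cluster_threshold")

    tmaps = group_tmaps_for_splits(maps, plan.iter_assignments())
    maxima = np.empty(tmaps.shape[0])
    if statistic == "pixel_abs_t":
        maxima[:] = np.max(np.abs(tmaps[:, analysis_mask]), axis=1)
    elif statistic == "cluster_size":
        for i, t in enumerate(tmaps):
            clusters = label_excursions(t, analysis_mask, cluster_threshold,
                                        sidedness=2)
            maxima[i] = max((c[0] for c in clusters), default=0)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    return MaxNullDistribution(kind=statistic, values=maxima, alpha=alpha)


def critical_value(dist: MaxNullDistribution, alpha: float | None = None) -> float:
    """The c'th largest maximum, c = floor(alpha*M) + 1; reject strictly above."""
    if alpha is None or alpha == dist.alpha:
        return dist.critical_value
    c = int(math.floor(alpha * dist.M)) + 1
    return float(dist.values[dist.M - c])


def empirical_pvalue(observed: float, dist: MaxNullDistribution) -> float:
    """p = #{maxima >= observed} / M (quantized in steps of 1/M)."""
    return float(np.count_nonzero(dist.values >= observed)) / dist.M
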