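"""Distribution tail test: enrichment of the smallest values.

The test asks whether the low end of a value distribution (shortest
distances, fewest chromosomes) is more populated in the real genome than in
permuted genomes.  Real values are partitioned into k equal-occupancy bins
by their own quantile thresholds (or natural integer bins for counts); the
same thresholds then bin each replicate's values.  For each prefix length j
the cumulative count F_j = f_1 + ... + f_j is compared against the
replicates with an empirical p-value p_j, and the minimal j whose
Bonferroni-corrected value j*p_j clears alpha is reported.

Replicate values beyond the last threshold fall into an overflow bin and
are excluded from every F_j, which can only make the replicate prefix
counts smaller -- the conservative direction.  An optional lexicographic
order on the whole prefix vector refines tie-heavy comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .engine import PermutationEngine
from .genome import GenomeLayout
from .groups import GroupCollection
from .spatial import ContactMap
from .stats import StatisticUndefinedError

__all__ = [
    "BinThresholds",
    "TailTestResult",
    "quantile_thresholds",
    "integer_thresholds",
    "bin_counts",
    "bin_count_prefixes",
    "distribution_tail_test",
    "lexicographic_extreme",
    "permutation_tail_test",
]


@dataclass(frozen=True)
class BinThresholds:
    """Strictly increasing thresholds t_0 < ... < t_k.

    Bin i (1-based) is the half-open interval (t_{i-1}, t_i], except bin 1
    which is closed on the left: [t_0, t_1].
    """

    thresholds: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds)
        if t.size < 2:
            raise ValueError("need at least one bin (two thresholds)")
        if not np.all(np.diff(t) > 0):
            raise ValueError("thresholds must be strictly increasing")

    @property
    def k(self) -> int:
        return len(self.thresholds) - 1


def quantile_thresholds(
    real_values: Sequence[float] | np.ndarray,
    k: int,
    lower_bound: float = 0.0,
) -> BinThresholds:
    """Equal-occupancy thresholds: t_i is the i/k empirical quantile.

    Linear interpolation between order statistics (type-7).  t_0 is the
    fixed lower bound of the value domain (0 for distances).  Raises if
    there are fewer than k values or if ties collapse quantiles.
    """
    values = np.asarray(real_values, dtype=float)
    if values.size < k:
        raise ValueError(f"need at least k={k} values, got {values.size}")
    if values.min() < lower_bound:
        raise ValueError("values below the lower bound")
    t = np.quantile(values, np.arange(1, k + 1) / k, method="linear")
    t = np.concatenate([[lower_bound], t])
    flat = np.flatnonzero(np.diff(t) <= 0)
    if flat.size:
        levels = ", ".join(f"{(i + 1) / k:.0%}" for i in flat)
        raise ValueError(f"ties collapse the quantile thresholds at {levels}")
    return BinThresholds(tuple(t))


def integer_thresholds(max_value: int, lower_bound: float = 0.0) -> BinThresholds:
    """Natural bins for positive integer values: bin i = {i}, i = 1..max."""
    return BinThresholds((lower_bound, *range(1, max_value + 1)))


def bin_counts(
    values: Sequence[float] | np.ndarray, thresholds: BinThresholds
) -> np.ndarray:
    """Per-bin frequencies f_1..f_k; values above t_k overflow and are dropped."""
    v = np.asarray(values, dtype=float)
    t = np.asarray(thresholds.thresholds)
    if v.size == 0:
        return np.zeros(thresholds.k, dtype=int)
    idx = np.searchsorted(t[1:], v, side="left")  # (t_{i-1}, t_i] bins
    return np.bincount(idx[idx < thresholds.k], minlength=thresholds.k)


def bin_count_prefixes(
    values: Sequence[float] | np.ndarray, thresholds: BinThresholds
) -> np.ndarray:
    """Cumulative frequencies F_j = f_1 + ... + f_j for j = 1..k."""
    return np.cumsum(bin_counts(values, thresholds))


def lexicographic_extreme(
    real_prefixes: np.ndarray, replicate_prefixes: np.ndarray
) -> np.ndarray:
    """Which replicate prefix vectors are >= the real one lexicographically.

    The first coordinate where a replicate differs from the real vector
    decides; exactly equal vectors count as extreme (tie rule).
    """
    real = np.asarray(real_prefixes)
    reps = np.atleast_2d(np.asarray(replicate_prefixes))
    if reps.shape[1] != real.size:
        raise ValueError("prefix vectors must have equal length")
    result = np.zeros(reps.shape[0], dtype=bool)
    undecided = np.ones(reps.shape[0], dtype=bool)
    for j in range(real.size):
        gt = undecided & (reps[:, j] > real[j])
        lt = undecided & (reps[:, j] < real[j])
        result[gt] = True
        undecided &= ~(gt | lt)
    result[undecided] = True
    return result


@dataclass
class TailTestResult:
    """Prefix-enrichment test outcome.

    ``p_values[j-1]`` is the raw empirical p for prefix 1..j; ``j_star`` is
    the minimal j with j*p_j <= alpha (None if no prefix qualifies) and
    ``p_corrected`` its Bonferroni-by-j corrected value, capped at 1.
    """

    thresholds: BinThresholds
    f_real: np.ndarray
    prefixes_real: np.ndarray
    prefixes_replicates: np.ndarray
    p_values: np.ndarray
    j_star: int | None
    p_corrected: float | None
    n: int
    alpha: float
    p_lexicographic: float | None = None
    seed: int | None = None

    @property
    def significant(self) -> bool:
        return self.j_star is not None


def distribution_tail_test(
    real_values: Sequence[float] | np.ndarray,
    replicate_value_sets: Sequence[Sequence[float] | np.ndarray],
    k: int = 20,
    alpha: float = 0.05,
    thresholds: BinThresholds | None = None,
    refinement: str | None = None,
    seed: int | None = None,
) -> TailTestResult:
    """Tail test from explicit real and replicate value sets.

    Thresholds default to the k equal-occupancy quantiles of the REAL
    values; replicates are binned by those same thresholds.  With
    ``refinement="lexicographic"`` an additional overall p-value based on
    the lexicographic order of full prefix vectors is reported.
    """
    real = np.asarray(real_values, dtype=float)
    if thresholds is None:
        thresholds = quantile_thresholds(real, k)
    F_real = bin_count_prefixes(real, thresholds)
    F_reps = np.array(
        [bin_count_prefixes(vs, thresholds) for vs in replicate_value_sets]
    )
    return _tail_from_prefixes(
        thresholds, F_real, F_reps, alpha, refinement=refinement, seed=seed
    )


def _tail_from_prefixes(
    thresholds: BinThresholds,
    F_real: np.ndarray,
    F_reps: np.ndarray,
    alpha: float,
    refinement: str | None = None,
    seed: int | None = None,
) -> TailTestResult:
    if F_reps.ndim != 2 or F_reps.shape[1] != thresholds.k:
        raise ValueError("replicate prefix matrix has wrong shape")
    n = F_reps.shape[0]
    k = thresholds.k
    # p_j with ge extremeness, ties inclusive
    p = (np.sum(F_reps >= F_real[None, :], axis=0) + 1) / (n + 1)
    corrected = np.arange(1, k + 1) * p
    qualifying = np.flatnonzero(corrected <= alpha + 1e-12)
    j_star = int(qualifying[0]) + 1 if qualifying.size else None
    p_corr = min(1.0, float(corrected[j_star - 1])) if j_star is not None else None
    p_lex = None
    if refinement == "lexicographic":
        extreme = lexicographic_extreme(F_real, F_reps)
        p_lex = (int(extreme.sum()) + 1) / (n + 1)
    elif refinement is not None:
        raise ValueError(f"unknown refinement {refinement!r}")
    f_real = np.diff(np.concatenate([[0], F_real]))
    return TailTestResult(
        thresholds=thresholds,
        f_real=f_real,
        prefixes_real=F_real,
        prefixes_replicates=F_reps,
        p_values=p,
        j_star=j_star,
        p_corrected=p_corr,
        n=n,
        alpha=alpha,
        p_lexicographic=p_lex,
        seed=seed,
    )


#: Engine quantities usable as tail-test value sets.
TAIL_VALUE_KINDS = {
    "chrom_counts": "chrom_counts",
    "linear_group_means": "linear_group_means",
    "spatial_all_group_means": "spatial_all_group_means",
    "spatial_inter_group_means": "spatial_inter_group_means",
    "spatial_inter_pair_dists": "spatial_inter_pair_dists",
}


def permutation_tail_test(
    layout: GenomeLayout,
    collection: GroupCollection,
    values: str,
    scheme: str,
    n: int = 999,
    k: int = 20,
    alpha: float = 0.05,
    thresholds: BinThresholds | None = None,
    seed: int = 0,
    contact_map: ContactMap | None = None,
    refinement: str | None = None,
) -> TailTestResult:
    """Tail test on a per-group or per-pair quantity under a permutation null.

    ``values`` names an engine quantity (e.g. ``linear_group_means`` for the
    20-bin test on per-group mean intra-chromosomal distances,
    ``spatial_inter_pair_dists`` for individual inter-chromosomal 3D
    distances, ``chrom_counts`` for the chromosome-dispersal histogram,
    which defaults to natural integer bins).
    """
    if values not in TAIL_VALUE_KINDS:
        raise KeyError(f"unknown tail value kind {values!r}")
    quantity = TAIL_VALUE_KINDS[values]
    eng = PermutationEngine(layout, collection, contact_map)
    obs = eng.observed([quantity])[quantity].astype(float)
    real = obs[~np.isnan(obs)]
    if real.size == 0:
        raise StatisticUndefinedError(f"no defined real values for {values!r}")
    if thresholds is None:
        if values == "chrom_counts":
            thresholds = integer_thresholds(eng.n_chrom)
        else:
            thresholds = quantile_thresholds(real, k)
    F_real = bin_count_prefixes(real, thresholds)
    F_reps = np.empty((n, thresholds.k), dtype=int)
    for r, q in enumerate(eng.sample(scheme, n, seed, [quantity])):
        v = q[quantity].astype(float)
        F_reps[r] = bin_count_prefixes(v[~np.isnan(v)], thresholds)
    return _tail_from_prefixes(
        thresholds, F_real, F_reps, alpha, refinement=refinement, seed=seed
    )
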