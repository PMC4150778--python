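"""Permutation null models and empirical p-values.

Two null schemes randomize gene order while fixing everything else:

* ``global`` -- gene labels are reassigned uniformly at random to the fixed
  set of genomic loci across the whole genome, so the locus multiset and
  per-chromosome gene counts are preserved;
* ``within_chromosome`` -- labels are shuffled independently within each
  chromosome, additionally preserving every gene's chromosome (used when
  inter-chromosomal composition must be held fixed, e.g. for intra
  distances and inter-only spatial tests).

The empirical p-value is (k+1)/(n+1) where k counts replicates at least as
extreme as the observed statistic, ties included; it is never smaller than
1/(n+1) and is valid (super-uniform) under the exchangeable null.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .engine import PermutationEngine
from .genome import GeneRecord, GenomeLayout
from .groups import GroupCollection
from .spatial import ContactMap
from .stats import STATISTICS, StatisticUndefinedError

SCHEMES = ("global", "within_chromosome")

__all__ = [
    "SCHEMES",
    "EmpiricalTestResult",
    "permute_layout",
    "empirical_p",
    "bonferroni",
    "run_permutation_test",
]


def permute_layout(
    layout: GenomeLayout,
    scheme: str,
    seed: int | np.random.Generator,
) -> GenomeLayout:
    """Return a new layout with gene labels randomly reassigned to loci."""
    if scheme not in SCHEMES:
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    per_chrom_ids = {
        c: [g.gene_id for g in layout.genes_on(c)] for c in layout.chromosome_names
    }
    if scheme == "global":
        pool = [gid for c in layout.chromosome_names for gid in per_chrom_ids[c]]
        pool = [pool[i] for i in rng.permutation(len(pool))]
        cursor = 0
        shuffled = {}
        for c in layout.chromosome_names:
            n = len(per_chrom_ids[c])
            shuffled[c] = pool[cursor : cursor + n]
            cursor += n
    else:
        shuffled = {
            c: [ids[i] for i in rng.permutation(len(ids))]
            for c, ids in per_chrom_ids.items()
        }
    records = [
        GeneRecord(gid, c, locus.start, locus.end)
        for c in layout.chromosome_names
        for gid, locus in zip(shuffled[c], layout.genes_on(c))
    ]
    return GenomeLayout(records, aliases=layout.aliases)


@dataclass
class EmpiricalTestResult:
    """Observed statistic, replicate values and the empirical p-value."""

    statistic: str
    v0: float
    replicates: np.ndarray
    n: int
    k: int
    direction: str
    p_value: float
    scheme: str | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        assert 0 < self.p_value <= 1


def empirical_p(
    v0: float,
    replicates: Sequence[float] | np.ndarray,
    direction: str,
    statistic: str = "",
    scheme: str | None = None,
    seed: int | None = None,
) -> EmpiricalTestResult:
    """(k+1)/(n+1) permutation p-value; ties count toward k.

    ``direction="ge"`` treats large replicate values as extreme (v >= v0),
    ``"le"`` small ones.  NaN replicates (statistic undefined on that
    permutation) never count as extreme.
    """
    reps = np.asarray(replicates, dtype=float)
    if reps.size == 0:
        raise ValueError("empirical_p needs at least one replicate")
    if np.isnan(v0):
        raise StatisticUndefinedError(
            f"observed statistic {statistic or '<anonymous>'} is undefined"
        )
    if direction == "ge":
        k = int(np.sum(reps >= v0))
    elif direction == "le":
        k = int(np.sum(reps <= v0))
    else:
        raise ValueError(f"direction must be 'ge' or 'le', got {direction!r}")
    n = int(reps.size)
    return EmpiricalTestResult(
        statistic=statistic,
        v0=float(v0),
        replicates=reps,
        n=n,
        k=k,
        direction=direction,
        p_value=(k + 1) / (n + 1),
        scheme=scheme,
        seed=seed,
    )


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-corrected p-value min(1, m*p)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p)


def run_permutation_test(
    layout: GenomeLayout,
    collection: GroupCollection,
    statistic: str | Callable[[GenomeLayout, GroupCollection], float],
    scheme: str | None = None,
    n: int = 999,
    direction: str | None = None,
    seed: int = 0,
    contact_map: ContactMap | None = None,
) -> EmpiricalTestResult:
    """Full Monte-Carlo permutation test of a statistic.

    ``statistic`` is a registered statistic name (fast vectorized path) or
    an arbitrary callable ``f(layout, collection) -> float`` (generic path,
    permuting the layout object for each replicate).  Replicates are drawn
    independently with replacement from the scheme's permutation space and
    the whole run is reproducible from ``seed``.
    """
    if n < 1:
        raise ValueError("need at least one replicate")
    if isinstance(statistic, str):
        spec = STATISTICS[statistic]
        scheme = scheme or spec.scheme
        direction = direction or spec.direction
        if scheme not in SCHEMES:
            raise ValueError(f"unknown permutation scheme {scheme!r}")
        eng = PermutationEngine(layout, collection, contact_map)
        v0 = spec.reduce(eng.observed([spec.quantity])[spec.quantity])
        if np.isnan(v0):
            raise StatisticUndefinedError(
                f"statistic {statistic!r} is undefined on the real layout"
            )
        reps = np.fromiter(
            (
                spec.reduce(q[spec.quantity])
                for q in eng.sample(scheme, n, seed, [spec.quantity])
            ),
            dtype=float,
            count=n,
        )
        name = statistic
    else:
        if scheme is None or direction is None:
            raise ValueError("callable statistics require explicit scheme and direction")
        try:
            v0 = float(statistic(layout, collection))
        except StatisticUndefinedError:
            raise
        rng = np.random.default_rng(seed)
        reps = np.array(
            [
                float(statistic(permute_layout(layout, scheme, rng), collection))
                for _ in range(n)
            ]
        )
        name = getattr(statistic, "__name__", "custom")
    return empirical_p(v0, reps, direction, statistic=name, scheme=scheme, seed=seed)
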