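"""Concentration statistics over a (real or permuted) genome layout.

Three families of statistics, mirroring the three facets of concentration:

* chromosome dispersal -- how many chromosomes a group's genes occupy;
* linear clustering -- mean base-pair distance between same-chromosome
  member pairs of a group (d_i), averaged unweighted over groups;
* spatial clustering -- mean 1-correlation contact-profile distance between
  member pairs, over all pairs or inter-chromosomal pairs only.

All functions here are pure, direct implementations operating on the object
model; the vectorized replicate engine in :mod:`cofunc.engine` is tested
against them.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .genome import GeneRecord, GenomeLayout, linear_distance
from .groups import FunctionalGroup, GroupCollection
from .spatial import ContactMap, gene_pair_distance

__all__ = [
    "StatisticUndefinedError",
    "GroupDistanceRecord",
    "chromosomes_involved",
    "mean_chromosome_count",
    "chromosome_count_histogram",
    "cumulative_chromosome_curve",
    "group_mean_distances",
    "mean_of_group_means",
    "pair_distances",
    "compute_statistic",
    "STATISTICS",
]


class StatisticUndefinedError(ValueError):
    """Raised when a statistic has no eligible groups/pairs on the real layout."""


# -- chromosome dispersal -------------------------------------------------


def _mapped_members(group: FunctionalGroup, layout: GenomeLayout) -> list[GeneRecord]:
    records = []
    seen = set()
    for m in group.members:
        resolved = layout.resolve(m)
        if resolved is not None and resolved not in seen:
            seen.add(resolved)
            records.append(layout.get(m))
    return records


def chromosomes_involved(group: FunctionalGroup, layout: GenomeLayout) -> int:
    """Number of distinct chromosomes holding at least one group member."""
    records = _mapped_members(group, layout)
    if not records:
        raise StatisticUndefinedError(
            f"group {group.group_id}: no members mapped to layout"
        )
    return len({g.chromosome for g in records})


def mean_chromosome_count(collection: GroupCollection, layout: GenomeLayout) -> float:
    """Average of chromosomes_involved over all groups."""
    if len(collection) == 0:
        raise StatisticUndefinedError("empty collection")
    return float(np.mean([chromosomes_involved(g, layout) for g in collection]))


def chromosome_count_histogram(
    collection: GroupCollection, layout: GenomeLayout
) -> np.ndarray:
    """Frequencies f[i] = number of groups involving exactly i chromosomes.

    Returned as an array indexed 0..C where C is the layout's chromosome
    count; f[0] is always 0 and sum(f) equals the number of groups.
    """
    if len(collection) == 0:
        raise StatisticUndefinedError("empty collection")
    counts = [chromosomes_involved(g, layout) for g in collection]
    return np.bincount(counts, minlength=len(layout.chromosome_names) + 1)


def cumulative_chromosome_curve(
    collection: GroupCollection, layout: GenomeLayout
) -> np.ndarray:
    """Number of groups represented on at most c chromosomes, c = 0..C."""
    return np.cumsum(chromosome_count_histogram(collection, layout))


# -- pairwise distances ---------------------------------------------------


@dataclass(frozen=True)
class GroupDistanceRecord:
    """Per-group mean pairwise distance d_i over eligible pairs."""

    group_id: str
    d_i: float
    n_pairs: int
    pair_filter: str
    metric: str


def _pair_rows(
    group: FunctionalGroup,
    layout: GenomeLayout,
    metric: str,
    pair_filter: str,
    cmap: ContactMap | None,
) -> list[tuple[str, str, float, str]]:
    if metric not in ("linear", "spatial"):
        raise ValueError(f"unknown metric {metric!r}")
    if pair_filter not in ("all", "intra_only", "inter_only"):
        raise ValueError(f"unknown pair filter {pair_filter!r}")
    if metric == "spatial" and cmap is None:
        raise ValueError("spatial metric requires a contact map")
    records = sorted(_mapped_members(group, layout), key=lambda g: g.gene_id)
    rows = []
    for a, b in combinations(records, 2):
        pair_class = "intra" if a.chromosome == b.chromosome else "inter"
        if pair_filter == "intra_only" and pair_class != "intra":
            continue
        if pair_filter == "inter_only" and pair_class != "inter":
            continue
        if metric == "linear":
            d = linear_distance(a, b)
            dist = float(d) if d is not None else float("nan")
        else:
            dist, pair_class = gene_pair_distance(a, b, cmap)  # type: ignore[arg-type]
        if not np.isnan(dist):
            rows.append((a.gene_id, b.gene_id, dist, pair_class))
    return rows


def group_mean_distances(
    collection: GroupCollection,
    layout: GenomeLayout,
    metric: str,
    pair_filter: str = "all",
    cmap: ContactMap | None = None,
) -> list[GroupDistanceRecord]:
    """d_i per group; groups with no eligible pair are omitted entirely."""
    out = []
    for g in collection:
        rows = _pair_rows(g, layout, metric, pair_filter, cmap)
        if rows:
            out.append(
                GroupDistanceRecord(
                    g.group_id,
                    float(np.mean([r[2] for r in rows])),
                    len(rows),
                    pair_filter,
                    metric,
                )
            )
    if not out:
        raise StatisticUndefinedError(
            f"no group has an eligible {pair_filter} {metric} pair"
        )
    return out


def mean_of_group_means(records: Sequence[GroupDistanceRecord]) -> float:
    """Unweighted mean of d_i over groups (not pair-weighted)."""
    if not records:
        raise StatisticUndefinedError("no group distance records")
    return float(np.mean([r.d_i for r in records]))


def pair_distances(
    collection: GroupCollection,
    layout: GenomeLayout,
    metric: str,
    pair_filter: str = "all",
    cmap: ContactMap | None = None,
) -> pd.DataFrame:
    """Flat table of individual eligible pair distances, one row per
    (group, unordered pair); a pair shared by several groups appears once
    per group."""
    rows = []
    for g in collection:
        for a, b, dist, pair_class in _pair_rows(g, layout, metric, pair_filter, cmap):
            rows.append((g.group_id, a, b, dist, pair_class))
    return pd.DataFrame(
        rows, columns=["group_id", "gene_a", "gene_b", "distance", "pair_class"]
    )


# -- statistic registry ---------------------------------------------------


@dataclass(frozen=True)
class StatisticSpec:
    """A registered scalar test statistic.

    ``quantity`` names the replicate-engine quantity it reduces;
    ``direction``/``scheme`` are the defaults used by the pipeline
    (direction ``le`` = concentration means a small statistic).
    """

    name: str
    quantity: str
    reduce: Callable[[np.ndarray], float]
    direction: str
    scheme: str
    needs_map: bool


def _mean(v: np.ndarray) -> float:
    return float(np.mean(v))


def _count_single(v: np.ndarray) -> float:
    return float(np.sum(v == 1))


def _mean_defined(v: np.ndarray) -> float:
    d = v[~np.isnan(v)]
    return float(d.mean()) if d.size else float("nan")


STATISTICS: dict[str, StatisticSpec] = {
    s.name: s
    for s in [
        StatisticSpec("mean_chrom_count", "chrom_counts", _mean, "le", "global", False),
        StatisticSpec("single_chrom_enrichment", "chrom_counts", _count_single, "ge", "global", False),
        StatisticSpec("intra_linear_group_mean", "linear_group_means", _mean_defined, "le", "within_chromosome", False),
        StatisticSpec("spatial_all_group_mean", "spatial_all_group_means", _mean_defined, "le", "global", True),
        StatisticSpec("spatial_inter_group_mean", "spatial_inter_group_means", _mean_defined, "le", "within_chromosome", True),
        StatisticSpec("spatial_inter_pairs", "spatial_inter_pair_dists", _mean_defined, "le", "within_chromosome", True),
    ]
}


def compute_statistic(
    name: str,
    layout: GenomeLayout,
    collection: GroupCollection,
    cmap: ContactMap | None = None,
) -> float:
    """Direct (non-vectorized) evaluation of a registered statistic."""
    if name == "mean_chrom_count":
        return mean_chromosome_count(collection, layout)
    if name == "single_chrom_enrichment":
        return float(chromosome_count_histogram(collection, layout)[1])
    if name == "intra_linear_group_mean":
        return mean_of_group_means(
            group_mean_distances(collection, layout, "linear", "intra_only")
        )
    if name == "spatial_all_group_mean":
        return mean_of_group_means(
            group_mean_distances(collection, layout, "spatial", "all", cmap)
        )
    if name == "spatial_inter_group_mean":
        return mean_of_group_means(
            group_mean_distances(collection, layout, "spatial", "inter_only", cmap)
        )
    if name == "spatial_inter_pairs":
        table = pair_distances(collection, layout, "spatial", "inter_only", cmap)
        if table.empty:
            raise StatisticUndefinedError("no eligible inter-chromosomal pairs")
        return float(table["distance"].mean())
    raise KeyError(f"unknown statistic {name!r}")
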