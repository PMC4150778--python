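"""Synthetic genomes, gene groups, family tables and contact maps.

Every generator is a pure function of (config, seed), so ground truth is
always known: group collections can be drawn from the permutation null
(``null`` mode) or with planted signal -- concentration on an anchor
chromosome (``chrom_concentrated``), linear clustering inside a window
around an anchor gene (``linear_clustered``) -- and contact maps combine
intra-chromosomal distance decay with optional planted inter-chromosomal
co-localized segment pairs.  Planted signal strengths are mixture
probabilities (rho for position clustering, sigma for spatial profile
blending), so power is interpretable across configurations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .genome import (
    GeneRecord,
    GenomeLayout,
    write_family_table,
    write_gene_positions,
)
from .groups import FunctionalGroup, GroupCollection, write_groups
from .spatial import ContactMap, write_contact_map

__all__ = [
    "SyntheticConfig",
    "generate_genome",
    "generate_families",
    "generate_groups",
    "generate_contact_map",
    "choose_planted_pairs",
    "write_fixture_bundle",
]

# sub-stream tags so the different generators draw independent streams
# from one config seed
_TAG_GENOME, _TAG_FAMILY, _TAG_GROUPS, _TAG_MAP, _TAG_PLANT = range(5)


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic study.

    Defaults describe the reference study condition used throughout the
    test suite: 2 chromosomes of 100 genes (gene bodies ~10 kb, intergenic
    gaps ~40 kb, so chromosomes of roughly 5 Mb), 50 groups of 2-8 genes,
    250 kb contact-map segments with power-law distance decay.
    """

    n_chromosomes: int = 2
    genes_per_chromosome: tuple[int, ...] | None = None  # default: 100 each
    gene_length_mean: float = 10_000.0
    gene_length_shape: float = 2.0  # gamma shape; lengths ~ Gamma(shape, mean/shape)
    gap_mean: float = 40_000.0  # exponential intergenic gaps
    n_groups: int = 50
    group_size_min: int = 2
    group_size_max: int = 8
    group_type: str = "pathway"
    rho: float = 0.0  # clustering strength (anchor-placement probability)
    window_fraction: float = 0.05  # linear cluster window, fraction of chromosome
    sigma: float = 0.0  # spatial co-localization strength
    n_planted_pairs: int = 20
    alpha_decay: float = 1.0  # intra-chromosomal contact decay exponent
    inter_background: float = 0.05  # inter-chromosomal baseline contact
    noise: float = 0.05  # sd of additive symmetric contact noise
    segment_size: int = 250_000
    min_overlap: int = 10
    n_tandem_runs: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.rho <= 1 and 0 <= self.sigma <= 1):
            raise ValueError("rho and sigma must be in [0, 1]")
        if self.group_size_min < 2 or self.group_size_max < self.group_size_min:
            raise ValueError("group sizes must satisfy 2 <= min <= max")
        if self.genes_per_chromosome is not None and len(
            self.genes_per_chromosome
        ) != self.n_chromosomes:
            raise ValueError("genes_per_chromosome length != n_chromosomes")

    @property
    def chromosome_gene_counts(self) -> tuple[int, ...]:
        if self.genes_per_chromosome is not None:
            return tuple(self.genes_per_chromosome)
        return (100,) * self.n_chromosomes


def _rng(config: SyntheticConfig, tag: int, seed: int | None) -> np.random.Generator:
    base = config.seed if seed is None else seed
    return np.random.default_rng([base, tag])


def generate_genome(config: SyntheticConfig, seed: int | None = None) -> GenomeLayout:
    """Draw non-overlapping genes per chromosome; deterministic under seed."""
    rng = _rng(config, _TAG_GENOME, seed)
    records: list[GeneRecord] = []
    gene_no = 0
    for ci, n_genes in enumerate(config.chromosome_gene_counts, start=1):
        chrom = f"chr{ci}"
        cursor = 0
        for _ in range(n_genes):
            gap = max(1, int(rng.exponential(config.gap_mean)))
            length = max(
                50,
                int(
                    rng.gamma(
                        config.gene_length_shape,
                        config.gene_length_mean / config.gene_length_shape,
                    )
                ),
            )
            start = cursor + gap
            records.append(GeneRecord(f"g{gene_no:05d}", chrom, start, start + length))
            cursor = start + length
            gene_no += 1
    return GenomeLayout(records)


def generate_families(
    layout: GenomeLayout, config: SyntheticConfig, seed: int | None = None
) -> dict[str, str]:
    """Plant tandem runs: adjacent gene pairs/triples sharing a family id.

    Genes outside planted runs are singleton families and stay out of the
    table.  Runs never overlap.
    """
    rng = _rng(config, _TAG_FAMILY, seed)
    families: dict[str, str] = {}
    fam_no = 0
    for chrom in layout.chromosome_names:
        genes = layout.genes_on(chrom)
        if len(genes) < 3:
            continue
        used: set[int] = set()
        for _ in range(config.n_tandem_runs):
            run_len = int(rng.integers(2, 4))
            start = int(rng.integers(0, max(1, len(genes) - run_len)))
            idxs = range(start, start + run_len)
            if any(i in used for i in idxs):
                continue
            used.update(idxs)
            fam = f"fam{fam_no:04d}"
            fam_no += 1
            for i in idxs:
                families[genes[i].gene_id] = fam
    return families


def generate_groups(
    layout: GenomeLayout,
    config: SyntheticConfig,
    mode: str = "null",
    seed: int | None = None,
) -> GroupCollection:
    """Sample a group collection with or without planted arrangement signal.

    ``null``: members uniform without replacement -- exactly the
    permutation null.  ``chrom_concentrated``: each member is drawn from the
    group's anchor chromosome with probability rho, uniformly otherwise.
    ``linear_clustered``: each member is drawn, with probability rho, from
    the genes whose midpoints lie within +-window/2 of an anchor gene
    (window = window_fraction * chromosome length, so every clustered pair
    is at most one window apart), uniformly otherwise.
    """
    if mode not in ("null", "chrom_concentrated", "linear_clustered"):
        raise ValueError(f"unknown group generation mode {mode!r}")
    rng = _rng(config, _TAG_GROUPS, seed)
    genes = list(layout.iter_genes())
    n = len(genes)
    if config.group_size_max > n:
        raise ValueError("group size exceeds gene count")
    by_chrom = {c: list(layout.genes_on(c)) for c in layout.chromosome_names}
    chrom_names = layout.chromosome_names
    chrom_span = {c: by_chrom[c][-1].end for c in chrom_names}

    if config.group_type == "ppi":
        sizes = np.full(config.n_groups, 2)
    else:
        sizes = rng.integers(
            config.group_size_min, config.group_size_max + 1, size=config.n_groups
        )

    groups: list[FunctionalGroup] = []
    for gi, size in enumerate(sizes):
        members: set[str] = set()
        if mode == "null":
            picks = rng.choice(n, size=int(size), replace=False)
            members = {genes[i].gene_id for i in picks}
        else:
            if mode == "chrom_concentrated":
                anchor_chrom = chrom_names[rng.integers(len(chrom_names))]
                pool = [g.gene_id for g in by_chrom[anchor_chrom]]
            else:
                anchor = genes[rng.integers(n)]
                half = config.window_fraction * chrom_span[anchor.chromosome] / 2
                pool = [
                    g.gene_id
                    for g in by_chrom[anchor.chromosome]
                    if abs(g.midpoint - anchor.midpoint) <= half
                ]
            guard = 0
            while len(members) < size:
                guard += 1
                if guard > 10_000 * size:
                    raise ValueError(
                        f"cannot fill group of size {size} in mode {mode!r}; "
                        "window or chromosome too small for rho"
                    )
                clustered = rng.random() < config.rho
                if clustered:
                    remaining = [g for g in pool if g not in members]
                    if remaining:
                        members.add(remaining[rng.integers(len(remaining))])
                        continue
                    if config.rho >= 1.0:
                        raise ValueError(
                            f"rho=1 but only {len(pool)} genes available for a "
                            f"group of size {size}"
                        )
                members.add(genes[rng.integers(n)].gene_id)
        groups.append(
            FunctionalGroup(f"{mode}_{gi:04d}", config.group_type, frozenset(members))
        )
    return GroupCollection(config.group_type, tuple(groups), provenance=f"synthetic:{mode}")


def _segment_grid(
    layout: GenomeLayout, config: SyntheticConfig
) -> tuple[list[str], list[int], list[int]]:
    """Fixed-size segment tiling implied by layout + config.

    Chromosome length is the last gene end plus one mean gap of tail
    sequence, rounded up to a final (possibly partial) segment.
    """
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    for chrom in layout.chromosome_names:
        length = layout.genes_on(chrom)[-1].end + int(config.gap_mean)
        n_seg = -(-length // config.segment_size)  # ceil
        for o in range(n_seg):
            chroms.append(chrom)
            starts.append(o * config.segment_size)
            ends.append(min((o + 1) * config.segment_size, length))
    return chroms, starts, ends


def generate_contact_map(
    layout: GenomeLayout,
    config: SyntheticConfig,
    planted_pairs: Sequence[tuple[int, int]] = (),
    seed: int | None = None,
) -> ContactMap:
    """Contact map with intra-chromosomal distance decay and planted signal.

    Intra-chromosomal entries follow (1 + d)^(-alpha) in segment offset d;
    inter-chromosomal entries sit at a small constant background.  Planted
    inter-chromosomal segment pairs have their contact profiles blended
    toward a shared anchor profile with weight sigma, so at sigma = 1 and
    zero noise planted profiles coincide and their 1-correlation distance
    is exactly 0.  Symmetric Gaussian noise (sd = config.noise) is added
    last.
    """
    rng = _rng(config, _TAG_MAP, seed)
    chroms, starts, ends = _segment_grid(layout, config)
    S = len(chroms)
    chrom_arr = np.array(chroms, dtype=object)
    M = np.full((S, S), config.inter_background)
    i = 0
    while i < S:
        j = i
        while j < S and chroms[j] == chroms[i]:
            j += 1
        offs = np.arange(j - i)
        block = (1.0 + np.abs(offs[:, None] - offs[None, :])) ** (-config.alpha_decay)
        M[i:j, i:j] = block
        i = j
    # Planted pairs may share segments; treat each connected component as
    # one co-localization cluster blended toward a single anchor profile,
    # so overlapping pairs cannot overwrite each other.
    parent: dict[int, int] = {}

    def _find(x: int) -> int:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in planted_pairs:
        if chroms[a] == chroms[b]:
            raise ValueError(f"planted pair ({a}, {b}) is intra-chromosomal")
        parent[_find(a)] = _find(b)
    clusters: dict[int, list[int]] = {}
    for x in parent:
        clusters.setdefault(_find(x), []).append(x)
    direct = config.inter_background + config.sigma * (1 - config.inter_background)
    for members in clusters.values():
        members = sorted(members)
        anchor = members[0]
        outside = np.ones(S, dtype=bool)
        outside[members] = False
        for m in members[1:]:
            blended = (
                (1 - config.sigma) * M[m, outside] + config.sigma * M[anchor, outside]
            )
            M[m, outside] = blended
            M[outside, m] = blended
        for ii, x in enumerate(members):
            for y in members[ii + 1 :]:
                M[x, y] = M[y, x] = direct
    if config.noise > 0:
        E = rng.normal(0.0, config.noise, size=(S, S))
        M = M + (E + E.T) / 2
    return ContactMap(
        chroms, starts, ends, M, config.segment_size, min_overlap=config.min_overlap
    )


def choose_planted_pairs(
    layout: GenomeLayout,
    collection: GroupCollection,
    config: SyntheticConfig,
    n_pairs: int | None = None,
    seed: int | None = None,
) -> list[tuple[int, int]]:
    """Pick the inter-chromosomal segment pairs hosting the most group pairs.

    This couples the planted spatial signal to the collection: the segment
    pairs where co-functioning gene pairs actually sit become co-localized,
    which is the ground truth the individual-pair spatial test looks for.
    Ties are broken by a seeded shuffle.
    """
    rng = _rng(config, _TAG_PLANT, seed)
    n_pairs = config.n_planted_pairs if n_pairs is None else n_pairs
    chroms, starts, ends = _segment_grid(layout, config)
    block: dict[str, int] = {}
    for idx, c in enumerate(chroms):
        block.setdefault(c, idx)
    counts: dict[tuple[int, int], int] = {}
    for group in collection:
        recs = [layout.get(m) for m in group.members]
        recs = [r for r in recs if r is not None]
        segs = sorted(
            {
                block[r.chromosome] + r.midpoint // config.segment_size
                for r in recs
                if r.chromosome in block
            }
        )
        for ai in range(len(segs)):
            for bi in range(ai + 1, len(segs)):
                a, b = segs[ai], segs[bi]
                if chroms[a] != chroms[b]:
                    counts[(a, b)] = counts.get((a, b), 0) + 1
    items = list(counts.items())
    rng.shuffle(items)
    items.sort(key=lambda kv: -kv[1])  # stable: shuffled order breaks ties
    return [pair for pair, _ in items[:n_pairs]]


def write_fixture_bundle(
    layout: GenomeLayout,
    families: Mapping[str, str],
    collections: Sequence[GroupCollection],
    cmap: ContactMap | None,
    out_dir: str | Path,
) -> dict[str, str]:
    """Write a complete loadable input bundle; returns a manifest of paths.

    PPI collections are written as pair lists, others as GMT.  The manifest
    (also written as ``manifest.json``) maps logical names to file names.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    write_gene_positions(layout, out / "genes.bed")
    manifest["genome"] = "genes.bed"
    write_family_table(families, out / "families.tsv")
    manifest["families"] = "families.tsv"
    if not collections:
        manifest["groups"] = ""
    for coll in collections:
        fmt = "pairs" if coll.group_type == "ppi" else "gmt"
        name = f"groups_{coll.group_type}.{'pairs.tsv' if fmt == 'pairs' else 'gmt'}"
        write_groups(coll, out / name, fmt)
        manifest[f"groups_{coll.group_type}"] = name
        manifest[f"groups_{coll.group_type}_format"] = fmt
    if cmap is not None:
        write_contact_map(cmap, out / "contacts.tsv", "dense_tsv")
        manifest["contact_map"] = "contacts.tsv"
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
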