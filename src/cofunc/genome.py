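"""Gene positions on chromosomes.

A :class:`GenomeLayout` is an immutable arrangement of genes over a fixed set
of genomic loci.  The loci (chromosome + interval) are what permutation null
models shuffle gene identities over, so the layout keeps them strictly
separate from the gene labels.  Coordinates are 0-based half-open
throughout; 1-based TSV input is converted on load.

Tandem duplicate genes -- consecutive genes of the same gene family -- are
merged into a single gene spanning the run, to prevent duplicated gene
clusters from masquerading as functional concentration.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

logger = logging.getLogger(__name__)

__all__ = [
    "GeneRecord",
    "GenomeLayout",
    "load_gene_positions",
    "load_family_table",
    "merge_tandem_duplicates",
    "linear_distance",
    "write_gene_positions",
    "write_family_table",
]


@dataclass(frozen=True)
class GeneRecord:
    """A gene occupying the half-open interval [start, end) on a chromosome."""

    gene_id: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"gene {self.gene_id}: negative start {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"gene {self.gene_id}: end {self.end} must exceed start {self.start}"
            )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def _natural_key(name: str) -> tuple:
    """Sort chr2 before chr10."""
    return tuple(int(p) if p.isdigit() else p for p in re.split(r"(\d+)", name))


class GenomeLayout:
    """Ordered gene loci per chromosome.

    Parameters
    ----------
    genes:
        Gene records; ids must be unique.
    aliases:
        Mapping from original gene ids to the id of a merged gene that
        replaced them (produced by :func:`merge_tandem_duplicates`).  Lookups
        through :meth:`resolve` follow this mapping, so functional groups can
        keep referring to pre-merge ids.
    """

    def __init__(
        self,
        genes: Iterable[GeneRecord],
        aliases: Mapping[str, str] | None = None,
    ) -> None:
        by_chrom: dict[str, list[GeneRecord]] = {}
        by_id: dict[str, GeneRecord] = {}
        for g in genes:
            if g.gene_id in by_id:
                raise ValueError(f"duplicate gene id {g.gene_id!r} in layout")
            by_id[g.gene_id] = g
            by_chrom.setdefault(g.chromosome, []).append(g)
        self._by_chrom = {
            c: tuple(sorted(by_chrom[c], key=lambda g: (g.start, g.end, g.gene_id)))
            for c in sorted(by_chrom, key=_natural_key)
        }
        self._by_id = by_id
        self.aliases: dict[str, str] = dict(aliases or {})

    # -- basic access -----------------------------------------------------

    @property
    def chromosome_names(self) -> tuple[str, ...]:
        return tuple(self._by_chrom)

    @property
    def n_genes(self) -> int:
        return len(self._by_id)

    def genes_on(self, chromosome: str) -> tuple[GeneRecord, ...]:
        return self._by_chrom[chromosome]

    def iter_genes(self) -> Iterator[GeneRecord]:
        """Genes in chromosome order, by start within each chromosome."""
        for chrom in self._by_chrom:
            yield from self._by_chrom[chrom]

    def __contains__(self, gene_id: str) -> bool:
        return self.resolve(gene_id) is not None

    def __len__(self) -> int:
        return self.n_genes

    def resolve(self, gene_id: str) -> str | None:
        """Canonical id for ``gene_id`` (following merge aliases), or None."""
        if gene_id in self._by_id:
            return gene_id
        target = self.aliases.get(gene_id)
        if target is not None and target in self._by_id:
            return target
        return None

    def get(self, gene_id: str) -> GeneRecord | None:
        resolved = self.resolve(gene_id)
        return self._by_id[resolved] if resolved is not None else None

    def loci(self) -> list[tuple[str, int, int]]:
        """The fixed (chromosome, start, end) positions genes occupy."""
        return [(g.chromosome, g.start, g.end) for g in self.iter_genes()]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeLayout):
            return NotImplemented
        return self._by_chrom == other._by_chrom and self.aliases == other.aliases

    def __repr__(self) -> str:
        return (
            f"GenomeLayout({self.n_genes} genes on "
            f"{len(self.chromosome_names)} chromosomes)"
        )


# -- IO -------------------------------------------------------------------


def load_gene_positions(path: str | Path, format: str = "bed") -> GenomeLayout:
    """Read gene positions from a BED4+ or headered TSV file.

    BED input is 0-based half-open (chrom, start, end, name).  TSV input has
    a header with columns gene_id/chromosome/start/end and 1-based inclusive
    coordinates, converted internally.  Genes whose id occurs more than once
    (ambiguous position) are dropped entirely, keeping none of the copies.
    """
    path = Path(path)
    if format not in ("bed", "tsv"):
        raise ValueError(f"unknown gene position format {format!r}")
    records: list[GeneRecord] = []
    header: dict[str, int] | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if format == "bed":
                    if len(fields) < 4:
                        raise ValueError("expected at least 4 columns")
                    chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
                else:
                    if header is None:
                        header = {c.strip(): i for i, c in enumerate(fields)}
                        missing = {"gene_id", "chromosome", "start", "end"} - set(header)
                        if missing:
                            raise ValueError(f"missing columns {sorted(missing)}")
                        continue
                    name = fields[header["gene_id"]]
                    chrom = fields[header["chromosome"]]
                    start = int(fields[header["start"]]) - 1  # 1-based -> 0-based
                    end = int(fields[header["end"]])
                records.append(GeneRecord(name, chrom, start, end))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed line: {exc}") from exc
    if not records:
        raise ValueError(f"{path}: no gene records found")
    counts: dict[str, int] = {}
    for r in records:
        counts[r.gene_id] = counts.get(r.gene_id, 0) + 1
    dropped = {gid for gid, c in counts.items() if c > 1}
    if dropped:
        logger.warning(
            "dropping %d gene ids with multiple positions", len(dropped)
        )
    return GenomeLayout(r for r in records if r.gene_id not in dropped)


def write_gene_positions(layout: GenomeLayout, path: str | Path) -> None:
    """Write a layout as BED4 (round-trips through ``load_gene_positions``)."""
    with open(path, "w") as fh:
        for g in layout.iter_genes():
            fh.write(f"{g.chromosome}\t{g.start}\t{g.end}\t{g.gene_id}\n")


def load_family_table(path: str | Path) -> dict[str, str]:
    """Read a gene_id -> family_id TSV (header optional)."""
    families: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            if lineno == 1 and fields[0] in ("gene_id", "gene"):
                continue
            families[fields[0]] = fields[1]
    return families


def write_family_table(families: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tfamily_id\n")
        for gid in sorted(families):
            fh.write(f"{gid}\t{families[gid]}\n")


# -- tandem duplicate merging --------------------------------------------


def merge_tandem_duplicates(
    layout: GenomeLayout, families: Mapping[str, str]
) -> GenomeLayout:
    """Merge maximal runs of adjacent same-family genes into one gene.

    "Adjacent" means consecutive in the per-chromosome gene order with no
    intervening gene of another family.  The merged gene spans the interval
    covered by the run and gets the composite id ``"a|b|..."``; the member
    ids become aliases of it.  Genes absent from ``families`` are singleton
    families and never merge.  Idempotent: composite ids are not in the
    family table, so a second pass changes nothing.
    """
    merged_records: list[GeneRecord] = []
    member_to_merged: dict[str, str] = {}
    for chrom in layout.chromosome_names:
        run: list[GeneRecord] = []

        def flush() -> None:
            if len(run) > 1:
                mid = "|".join(g.gene_id for g in run)
                merged_records.append(
                    GeneRecord(mid, chrom, run[0].start, max(g.end for g in run))
                )
                for g in run:
                    member_to_merged[g.gene_id] = mid
            elif run:
                merged_records.append(run[0])
            run.clear()

        for gene in layout.genes_on(chrom):
            fam = families.get(gene.gene_id)
            if run and fam is not None and families.get(run[-1].gene_id) == fam:
                run.append(gene)
            else:
                flush()
                run.append(gene)
        flush()
    # rewire pre-existing aliases whose targets were just merged away
    aliases = {
        old: member_to_merged.get(target, target)
        for old, target in layout.aliases.items()
    }
    aliases.update(member_to_merged)
    if member_to_merged:
        logger.info(
            "merged %d tandem genes into %d composite genes",
            len(member_to_merged),
            len(set(member_to_merged.values())),
        )
    return GenomeLayout(merged_records, aliases=aliases)


def linear_distance(a: GeneRecord, b: GeneRecord) -> int | None:
    """Midpoint-to-midpoint distance in bases; None across chromosomes."""
    if a.chromosome != b.chromosome:
        return None
    return abs(a.midpoint - b.midpoint)
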