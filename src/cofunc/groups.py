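"""Collections of functional gene groups (PPI pairs, complexes, pathways)."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np

from .genome import GenomeLayout

logger = logging.getLogger(__name__)

GROUP_TYPES = ("ppi", "complex", "pathway")

__all__ = [
    "FunctionalGroup",
    "GroupCollection",
    "CollectionSummary",
    "load_groups",
    "write_groups",
    "restrict_to_layout",
    "summarize",
]


@dataclass(frozen=True)
class FunctionalGroup:
    """A named set of >= 2 genes sharing a functional relation."""

    group_id: str
    group_type: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if self.group_type not in GROUP_TYPES:
            raise ValueError(f"unknown group type {self.group_type!r}")
        if len(self.members) < 2:
            raise ValueError(f"group {self.group_id}: needs >= 2 distinct members")
        if self.group_type == "ppi" and len(self.members) != 2:
            raise ValueError(f"ppi group {self.group_id}: must have exactly 2 members")

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class GroupCollection:
    """All groups of one functional type from one source."""

    group_type: str
    groups: tuple[FunctionalGroup, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        for g in self.groups:
            if g.group_type != self.group_type:
                raise ValueError(
                    f"group {g.group_id} has type {g.group_type}, "
                    f"collection is {self.group_type}"
                )

    def __len__(self) -> int:
        return len(self.groups)

    def __iter__(self) -> Iterator[FunctionalGroup]:
        return iter(self.groups)


def load_groups(
    path: str | Path,
    format: str,
    group_type: str,
    provenance: str | None = None,
) -> GroupCollection:
    """Read groups from a 2-column pair list or a GMT file.

    ``pairs`` lines hold exactly two tab-separated gene ids; self pairs are
    dropped with a warning.  ``gmt`` lines hold id, description, then member
    ids; duplicate members collapse, and groups left with fewer than 2
    members are rejected with a warning.  Identical groups on separate lines
    are kept -- they are distinct database records.
    """
    path = Path(path)
    if format not in ("pairs", "gmt"):
        raise ValueError(f"unknown group format {format!r}")
    groups: list[FunctionalGroup] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if format == "pairs":
                if len(fields) != 2:
                    raise ValueError(
                        f"{path}:{lineno}: pair line has {len(fields)} fields, expected 2"
                    )
                a, b = fields
                if a == b:
                    logger.warning("%s:%d: dropping self pair (%s, %s)", path, lineno, a, b)
                    continue
                groups.append(
                    FunctionalGroup(f"P{len(groups) + 1:06d}", group_type, frozenset((a, b)))
                )
            else:
                if len(fields) < 2:
                    raise ValueError(f"{path}:{lineno}: gmt line needs id and description")
                gid, members = fields[0], frozenset(m for m in fields[2:] if m)
                if len(members) < 2:
                    logger.warning(
                        "%s:%d: rejecting group %s with %d member(s)",
                        path, lineno, gid, len(members),
                    )
                    continue
                if group_type == "ppi" and len(members) > 2:
                    raise ValueError(
                        f"{path}:{lineno}: ppi group {gid} has {len(members)} members"
                    )
                groups.append(FunctionalGroup(gid, group_type, members))
    return GroupCollection(group_type, tuple(groups), provenance or str(path))


def write_groups(collection: GroupCollection, path: str | Path, format: str) -> None:
    """Write a collection as a pair list or GMT (round-trips via ``load_groups``)."""
    with open(path, "w") as fh:
        for g in collection:
            members = sorted(g.members)
            if format == "pairs":
                if len(members) != 2:
                    raise ValueError(f"group {g.group_id} is not a pair")
                fh.write(f"{members[0]}\t{members[1]}\n")
            elif format == "gmt":
                fh.write("\t".join([g.group_id, collection.provenance or "na"] + members) + "\n")
            else:
                raise ValueError(f"unknown group format {format!r}")


def restrict_to_layout(
    collection: GroupCollection, layout: GenomeLayout
) -> GroupCollection:
    """Drop members absent from the layout; drop groups reduced below 2.

    Member ids are resolved through the layout's merge aliases first, so two
    tandem-merged members collapse onto the same merged gene.  Idempotent.
    """
    kept: list[FunctionalGroup] = []
    n_members_dropped = 0
    for g in collection:
        resolved = {layout.resolve(m) for m in g.members}
        resolved.discard(None)
        n_members_dropped += len(g.members) - len(resolved)
        if len(resolved) >= 2:
            kept.append(FunctionalGroup(g.group_id, g.group_type, frozenset(resolved)))  # type: ignore[arg-type]
    n_groups_dropped = len(collection) - len(kept)
    if n_members_dropped or n_groups_dropped:
        logger.info(
            "restrict_to_layout: dropped %d unmapped members and %d groups",
            n_members_dropped,
            n_groups_dropped,
        )
    return GroupCollection(collection.group_type, tuple(kept), collection.provenance)


@dataclass(frozen=True)
class CollectionSummary:
    n_groups: int
    min_size: int
    median_size: float
    max_size: int
    n_genes: int


def summarize(collection: GroupCollection) -> CollectionSummary:
    """Group count, size range/median and number of distinct genes involved."""
    if len(collection) == 0:
        raise ValueError("cannot summarize an empty collection")
    sizes = [g.size for g in collection]
    genes: set[str] = set()
    for g in collection:
        genes |= g.members
    return CollectionSummary(
        n_groups=len(sizes),
        min_size=min(sizes),
        median_size=float(np.median(sizes)),
        max_size=max(sizes),
        n_genes=len(genes),
    )
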