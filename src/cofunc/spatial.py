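"""Binned chromatin contact maps and 1-correlation spatial distances.

A :class:`ContactMap` holds a symmetric segment-by-segment matrix of
normalized contact scores (e.g. 1 Mb Hi-C bins).  The spatial distance
between two segments is 1 minus the Pearson correlation of their contact
profiles (their matrix rows), computed over columns where both profiles are
defined and excluding the two segments' own columns, so the inflated
self/near-diagonal entries do not dominate.  Distances lie in [0, 2]; small
values mean nuclear proximity.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome import GeneRecord

logger = logging.getLogger(__name__)

__all__ = [
    "ContactMap",
    "load_contact_map",
    "write_contact_map",
    "gene_to_segment",
    "segment_distance",
    "gene_pair_distance",
]

_SYM_TOL = 1e-9


class ContactMap:
    """Square contact matrix over fixed-size genomic segments.

    Parameters
    ----------
    chroms, starts, ends:
        Per-segment chromosome and half-open genomic interval.  Segments of
        one chromosome must tile it contiguously from 0, each of length
        ``segment_size`` except possibly a final partial segment.
    matrix:
        Symmetric float matrix; NaN marks missing (unmeasured) entries,
        which are excluded pairwise from correlations, never imputed as 0.
    min_overlap:
        Minimum number of shared defined profile columns required for a
        correlation to count; below it the distance is undefined (NaN).
    """

    def __init__(
        self,
        chroms: Sequence[str],
        starts: Sequence[int],
        ends: Sequence[int],
        matrix: np.ndarray,
        segment_size: int,
        min_overlap: int = 10,
    ) -> None:
        self.chroms = np.asarray(chroms, dtype=object)
        self.starts = np.asarray(starts, dtype=np.int64)
        self.ends = np.asarray(ends, dtype=np.int64)
        self.matrix = np.asarray(matrix, dtype=float)
        self.segment_size = int(segment_size)
        self.min_overlap = int(min_overlap)
        n = len(self.chroms)
        if self.matrix.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match {n} segments"
            )
        both = ~np.isnan(self.matrix) & ~np.isnan(self.matrix.T)
        if np.any(np.abs(self.matrix - self.matrix.T)[both] > _SYM_TOL):
            raise ValueError("contact matrix is asymmetric beyond tolerance")
        # index chromosome blocks and check tiling
        self._chrom_block: dict[str, tuple[int, int]] = {}
        i = 0
        while i < n:
            chrom = self.chroms[i]
            j = i
            expected_start = 0
            while j < n and self.chroms[j] == chrom:
                if self.starts[j] != expected_start:
                    raise ValueError(f"segments of {chrom} do not tile contiguously")
                if self.ends[j] - self.starts[j] > self.segment_size:
                    raise ValueError(f"segment {j} longer than segment_size")
                expected_start = int(self.ends[j])
                j += 1
            if chrom in self._chrom_block:
                raise ValueError(f"chromosome {chrom} segments are not contiguous")
            self._chrom_block[chrom] = (i, j - i)
            i = j
        self._dist: np.ndarray | None = None

    @property
    def n_segments(self) -> int:
        return len(self.chroms)

    @property
    def chromosome_names(self) -> tuple[str, ...]:
        return tuple(self._chrom_block)

    def chrom_block(self, chromosome: str) -> tuple[int, int]:
        """(first segment index, segment count) of a chromosome."""
        return self._chrom_block[chromosome]

    def segment_of(self, chromosome: str, position: int) -> int:
        """Index of the segment containing ``position`` (half-open bins)."""
        if chromosome not in self._chrom_block:
            raise KeyError(f"chromosome {chromosome!r} not in contact map")
        offset, count = self._chrom_block[chromosome]
        ordinal = position // self.segment_size
        if ordinal >= count or position >= self.ends[offset + count - 1]:
            raise ValueError(
                f"position {position} beyond last segment of {chromosome}"
            )
        return offset + int(ordinal)

    def distance_matrix(self) -> np.ndarray:
        """All-pairs 1-Pearson profile distances (NaN where undefined).

        Cached; the diagonal is 0 wherever the segment's own profile is
        usable (enough defined off-diagonal entries and nonzero variance).
        """
        if self._dist is not None:
            return self._dist
        M = self.matrix
        n = self.n_segments
        defined = ~np.isnan(M)
        D = np.full((n, n), np.nan)
        for i in range(n):
            row_i = M[i]
            def_i = defined[i]
            for j in range(i, n):
                mask = def_i & defined[j]
                mask[i] = mask[j] = False
                if int(mask.sum()) < self.min_overlap:
                    continue
                x = row_i[mask]
                y = M[j][mask]
                xm = x - x.mean()
                ym = y - y.mean()
                denom = np.sqrt((xm @ xm) * (ym @ ym))
                if denom == 0:
                    continue
                D[i, j] = D[j, i] = 1.0 - float((xm @ ym) / denom)
        # numerical safety: clamp correlations to [-1, 1]
        np.clip(D, 0.0, 2.0, out=D)
        self._dist = D
        return D

    def equals(self, other: "ContactMap") -> bool:
        return (
            list(self.chroms) == list(other.chroms)
            and np.array_equal(self.starts, other.starts)
            and np.array_equal(self.ends, other.ends)
            and self.segment_size == other.segment_size
            and np.allclose(self.matrix, other.matrix, equal_nan=True, atol=1e-12)
        )

    def __repr__(self) -> str:
        return (
            f"ContactMap({self.n_segments} segments x {self.segment_size} bp, "
            f"{len(self._chrom_block)} chromosomes)"
        )


def _parse_label(label: str) -> tuple[str, int, int]:
    chrom, _, span = label.rpartition(":")
    lo, _, hi = span.partition("-")
    if not chrom or not lo or not hi:
        raise ValueError(f"bad segment label {label!r}, expected 'chrom:start-end'")
    return chrom, int(lo), int(hi)


def load_contact_map(
    path: str | Path,
    format: str = "dense_tsv",
    segment_size: int | None = None,
    min_overlap: int = 10,
) -> ContactMap:
    """Read a contact map from dense or coordinate (COO) TSV.

    Dense: header row and first column carry ``chrom:start-end`` labels;
    empty cells are missing.  COO: ``# segment`` comment lines define the
    segment table, then ``i j value`` triples; unlisted entries are missing,
    and mirror entries are filled in by symmetry.  Conflicting symmetric
    entries (difference > 1e-9) raise.
    """
    path = Path(path)
    if format == "dense_tsv":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError(f"{path}: row and column labels differ")
        parsed = [_parse_label(str(lbl)) for lbl in df.columns]
        matrix = df.to_numpy(dtype=float)
        both = ~np.isnan(matrix) & ~np.isnan(matrix.T)
        if np.any(np.abs(matrix - matrix.T)[both] > _SYM_TOL):
            raise ValueError(f"{path}: asymmetric entries beyond tolerance")
        matrix = np.where(np.isnan(matrix), matrix.T, matrix)
    elif format == "coo_tsv":
        seg_rows: list[tuple[int, str, int, int]] = []
        triples: list[tuple[int, int, float]] = []
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line.strip():
                    continue
                if line.startswith("# segment"):
                    _, idx, chrom, lo, hi = line.split("\t")
                    seg_rows.append((int(idx), chrom, int(lo), int(hi)))
                    continue
                if line.startswith("#") or line.startswith("i\t"):
                    continue
                fields = line.split("\t")
                if len(fields) != 3:
                    raise ValueError(f"{path}:{lineno}: expected 'i j value'")
                triples.append((int(fields[0]), int(fields[1]), float(fields[2])))
        if not seg_rows:
            raise ValueError(f"{path}: no '# segment' definitions found")
        seg_rows.sort()
        if [r[0] for r in seg_rows] != list(range(len(seg_rows))):
            raise ValueError(f"{path}: segment indices are not 0..n-1")
        parsed = [(chrom, lo, hi) for _, chrom, lo, hi in seg_rows]
        n = len(parsed)
        matrix = np.full((n, n), np.nan)
        for i, j, v in triples:
            for a, b in ((i, j), (j, i)):
                if not np.isnan(matrix[a, b]) and abs(matrix[a, b] - v) > _SYM_TOL:
                    raise ValueError(
                        f"{path}: conflicting entries for segment pair ({i}, {j})"
                    )
                matrix[a, b] = v
    else:
        raise ValueError(f"unknown contact map format {format!r}")

    chroms = [p[0] for p in parsed]
    starts = [p[1] for p in parsed]
    ends = [p[2] for p in parsed]
    if segment_size is None:
        segment_size = int(max(e - s for s, e in zip(starts, ends)))
    return ContactMap(chroms, starts, ends, matrix, segment_size, min_overlap)


def write_contact_map(cmap: ContactMap, path: str | Path, format: str = "dense_tsv") -> None:
    """Write a map loadable by :func:`load_contact_map` (lossless)."""
    labels = [
        f"{c}:{s}-{e}" for c, s, e in zip(cmap.chroms, cmap.starts, cmap.ends)
    ]

    def fmt(v: float) -> str:
        return "" if np.isnan(v) else f"{v:.17g}"

    with open(path, "w") as fh:
        if format == "dense_tsv":
            fh.write("\t" + "\t".join(labels) + "\n")
            for lbl, row in zip(labels, cmap.matrix):
                fh.write(lbl + "\t" + "\t".join(fmt(v) for v in row) + "\n")
        elif format == "coo_tsv":
            for idx, (c, s, e) in enumerate(zip(cmap.chroms, cmap.starts, cmap.ends)):
                fh.write(f"# segment\t{idx}\t{c}\t{s}\t{e}\n")
            fh.write("i\tj\tvalue\n")
            n = cmap.n_segments
            for i in range(n):
                for j in range(i, n):
                    if not np.isnan(cmap.matrix[i, j]):
                        fh.write(f"{i}\t{j}\t{cmap.matrix[i, j]:.17g}\n")
        else:
            raise ValueError(f"unknown contact map format {format!r}")


def gene_to_segment(gene: GeneRecord, cmap: ContactMap) -> int:
    """Segment containing the gene midpoint (genes span one segment only)."""
    return cmap.segment_of(gene.chromosome, gene.midpoint)


def segment_distance(i: int, j: int, cmap: ContactMap) -> float:
    """1-Pearson distance between two segments' profiles; NaN if undefined."""
    return float(cmap.distance_matrix()[i, j])


def gene_pair_distance(
    a: GeneRecord, b: GeneRecord, cmap: ContactMap
) -> tuple[float, str]:
    """Spatial distance between two genes' segments and the pair class.

    Genes in the same segment are at distance 0.  The class is ``intra`` or
    ``inter`` by chromosome equality.
    """
    pair_class = "intra" if a.chromosome == b.chromosome else "inter"
    try:
        sa = gene_to_segment(a, cmap)
        sb = gene_to_segment(b, cmap)
    except (KeyError, ValueError) as exc:
        logger.warning("unmappable gene pair (%s, %s): %s", a.gene_id, b.gene_id, exc)
        return float("nan"), pair_class
    if sa == sb:
        return 0.0, pair_class
    return segment_distance(sa, sb, cmap), pair_class
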