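"""Gene and interval data model in TSS-relative coordinates.

All genomic coordinates are 0-based, half-open (BED convention). A gene is
reduced to a single canonical transcription start site (TSS); distances are
reported relative to the TSS with negative values upstream *on the gene's
strand*, so minus-strand genes mirror cleanly onto the same axis as
plus-strand genes.

The promoter is the region from 1,500 bp upstream through 500 bp downstream
of the TSS (2,000 bp total). Genes whose promoter overlaps a CpG island by
at least 1 bp are "CGI genes"; the rest are "noCGI genes".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: promoter extent around the TSS, in bp
PROMOTER_UPSTREAM = 1500
PROMOTER_DOWNSTREAM = 500

#: half-width of the analysis territory around each TSS, in bp
TSS_SPAN = 5000

STRANDS = ("+", "-", ".")


class BedParseError(ValueError):
    """Raised on a malformed BED record, carrying the offending line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval, optionally stranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(f"empty or inverted interval: [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand: {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True on >= 1 bp overlap on the same chromosome."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """One gene collapsed to its canonical TSS.

    ``tss`` is the 0-based position of the transcription start: the BED start
    for a plus-strand record, ``end - 1`` for a minus-strand record.
    """

    gene_id: str
    chrom: str
    tss: int
    strand: str
    promoter: GenomicInterval = field(compare=False)
    is_cgi_gene: bool = False

    @classmethod
    def from_tss(cls, gene_id: str, chrom: str, tss: int, strand: str) -> "GeneModel":
        return cls(
            gene_id=gene_id,
            chrom=chrom,
            tss=tss,
            strand=strand,
            promoter=make_promoter(tss, strand, chrom=chrom),
        )


def make_promoter(tss: int, strand: str, chrom: str = ".") -> GenomicInterval:
    """Promoter interval: 1,500 bp upstream through 500 bp downstream of the TSS.

    Strand-aware: for a minus-strand gene upstream means higher coordinates.
    Clipped at position 0; 2,000 bp long whenever unclipped.
    """
    if tss < 0:
        raise ValueError("tss must be >= 0")
    if strand == "+":
        start, end = tss - PROMOTER_UPSTREAM, tss + PROMOTER_DOWNSTREAM
    elif strand == "-":
        # downstream 500 bp = [tss-499, tss], upstream 1500 bp = [tss+1, tss+1500]
        start, end = tss - (PROMOTER_DOWNSTREAM - 1), tss + PROMOTER_UPSTREAM + 1
    else:
        raise ValueError(f"stranded promoter requires '+' or '-', got {strand!r}")
    return GenomicInterval(chrom=chrom, start=max(start, 0), end=end, strand=strand)


def tss_relative(pos: int | np.ndarray, gene: GeneModel) -> int | np.ndarray:
    """Signed distance of ``pos`` from the gene's TSS; negative = upstream."""
    if gene.strand == "+":
        return pos - gene.tss
    return gene.tss - pos


class IntervalIndex:
    """Merged, sorted per-chromosome intervals supporting vectorized any-overlap queries."""

    def __init__(self, intervals: Iterable[GenomicInterval] | Iterable[tuple]):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            if isinstance(iv, GenomicInterval):
                chrom, start, end = iv.chrom, iv.start, iv.end
            else:
                chrom, start, end = iv[0], int(iv[1]), int(iv[2])
            by_chrom.setdefault(chrom, []).append((start, end))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            merged: list[list[int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            arr = np.asarray(merged, dtype=np.int64)
            self._starts[chrom] = arr[:, 0]
            self._ends[chrom] = arr[:, 1]

    def overlaps_any(self, chrom: str, starts, ends) -> np.ndarray:
        """Boolean array: does each [start, end) overlap any indexed interval by >= 1 bp."""
        starts = np.atleast_1d(np.asarray(starts, dtype=np.int64))
        ends = np.atleast_1d(np.asarray(ends, dtype=np.int64))
        if chrom not in self._starts:
            return np.zeros(starts.shape, dtype=bool)
        ms, me = self._starts[chrom], self._ends[chrom]
        # rightmost merged interval starting before the query end; merged+sorted
        # means it is the only candidate that can still reach into the query
        j = np.searchsorted(ms, ends, side="left") - 1
        hit = j >= 0
        hit[hit] = me[j[hit]] > starts[hit]
        return hit

    def overlaps_interval(self, iv: GenomicInterval) -> bool:
        return bool(self.overlaps_any(iv.chrom, [iv.start], [iv.end])[0])


def classify_cgi_gene(
    gene: GeneModel, cgi_intervals: Iterable[GenomicInterval] | IntervalIndex
) -> bool:
    """True iff any CpG island overlaps the gene's promoter by >= 1 bp."""
    index = (
        cgi_intervals
        if isinstance(cgi_intervals, IntervalIndex)
        else IntervalIndex(cgi_intervals)
    )
    return index.overlaps_interval(gene.promoter)


@dataclass
class AnnotationSet:
    """Genes, CpG islands, and chromosome sizes for one assembly."""

    genes: list[GeneModel]
    cgi_intervals: list[GenomicInterval] = field(default_factory=list)
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate gene ids: {dup[:5]}")
        if self.chrom_sizes:
            for g in self.genes:
                size = self.chrom_sizes.get(g.chrom)
                if size is not None and g.tss >= size:
                    raise ValueError(f"gene {g.gene_id} TSS beyond {g.chrom} length {size}")
        if self.cgi_intervals:
            self.classify_cgi()

    def classify_cgi(self) -> None:
        index = IntervalIndex(self.cgi_intervals)
        self.genes = [
            replace(g, is_cgi_gene=classify_cgi_gene(g, index)) for g in self.genes
        ]

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def cgi_gene_ids(self) -> set[str]:
        return {g.gene_id for g in self.genes if g.is_cgi_gene}

    def by_id(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    @classmethod
    def from_files(
        cls,
        genes_bed: str | Path,
        cgi_bed: str | Path | None = None,
        chrom_sizes: str | Path | None = None,
    ) -> "AnnotationSet":
        return cls(
            genes=read_gene_bed(genes_bed),
            cgi_intervals=read_cgi_bed(cgi_bed) if cgi_bed else [],
            chrom_sizes=read_chrom_sizes(chrom_sizes) if chrom_sizes else {},
        )


def _split_bed_line(line: str, lineno: int, min_fields: int, path) -> list[str]:
    fields = line.rstrip("\n").split("\t") if "\t" in line else line.split()
    if len(fields) < min_fields:
        raise BedParseError(
            f"{path}:{lineno}: expected >= {min_fields} fields, got {len(fields)}"
        )
    return fields


def read_gene_bed(path: str | Path) -> list[GeneModel]:
    """Read a BED6 gene annotation into one :class:`GeneModel` per record.

    The TSS is the record start for '+' genes and ``end - 1`` for '-' genes
    (half-open end). Duplicate gene names and missing strands are rejected.
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = _split_bed_line(line, lineno, 6, path)
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start < 0 or start >= end:
                raise BedParseError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            name, strand = f[3], f[5]
            if strand not in ("+", "-"):
                raise BedParseError(f"{path}:{lineno}: missing or invalid strand {strand!r}")
            if name in seen:
                raise BedParseError(f"{path}:{lineno}: duplicate gene name {name!r}")
            seen.add(name)
            tss = start if strand == "+" else end - 1
            genes.append(GeneModel.from_tss(name, f[0], tss, strand))
    return genes


def read_cgi_bed(path: str | Path) -> list[GenomicInterval]:
    """Read CpG island intervals from BED3+ (UCSC cpgIslandExt accepted, extras ignored)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = _split_bed_line(line, lineno, 3, path)
            try:
                out.append(GenomicInterval(f[0], int(f[1]), int(f[2])))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            f = line.split()
            if len(f) < 2:
                raise BedParseError(f"{path}:{lineno}: expected 'chrom<TAB>length'")
            sizes[f[0]] = int(f[1])
    return sizes
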