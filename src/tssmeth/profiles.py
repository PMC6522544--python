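"""Expression-quartile stratified meta-profiles around the TSS.

Genes are split into expression quartiles (Q1 lowest .. Q4 highest) from
their mean expression across the samples of one arm. Methylation
meta-profiles average the per-segment methylation ratio over the genes of a
quartile in 100-bp TSS-relative bins, separately for segments within and
outside CpG islands. ChIP meta-profiles average strand-aware 10-bp binned
coverage; a randomized background band (signal envelope of many same-size
random gene lists) situates a gene set of interest against the genomic
background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import AnnotationSet, GeneModel, GenomicInterval, IntervalIndex, TSS_SPAN
from .scoring import (
    SEGMENT_SIZE,
    SegmentMethylationMatrix,
    _segment_rows_for_gene,
    methylation_ratio,
)

logger = logging.getLogger(__name__)

QUARTILES = ("Q1", "Q2", "Q3", "Q4")
CHIP_BIN = 10


@dataclass
class QuartileAssignment:
    """gene_id -> quartile label, for one cohort arm; Q4 is the highest expression."""

    assignment: dict[str, str]
    arm: str

    def genes_in(self, quartile: str) -> list[str]:
        return [g for g, q in self.assignment.items() if q == quartile]

    def sizes(self) -> dict[str, int]:
        return {q: len(self.genes_in(q)) for q in QUARTILES}


def assign_quartiles(
    expr: pd.DataFrame,
    samples: Sequence[str],
    arm: str = "",
    center: str = "mean",
) -> QuartileAssignment:
    """Rank genes by mean (or median) expression across arm samples; split into 4.

    Ties break by gene id lexicographically, so the assignment is
    deterministic. When the universe is not divisible by 4 the remainders go
    to the lowest quartiles first, e.g. 10 genes -> sizes (3, 3, 2, 2).
    """
    if len(expr) < 4:
        raise ValueError("need >= 4 genes to assign quartiles")
    sub = expr[list(samples)]
    level = sub.median(axis=1) if center == "median" else sub.mean(axis=1)
    order = sorted(level.index, key=lambda g: (level[g], g))
    n = len(order)
    base, rem = divmod(n, 4)
    sizes = [base + (1 if i < rem else 0) for i in range(4)]
    assignment: dict[str, str] = {}
    start = 0
    for q, size in zip(QUARTILES, sizes):
        for g in order[start : start + size]:
            assignment[g] = q
        start += size
    return QuartileAssignment(assignment=assignment, arm=arm)


@dataclass
class MetaProfile:
    """Mean signal per TSS-relative bin over the genes of one stratum."""

    positions: np.ndarray
    mean_signal: np.ndarray
    n_genes: int
    stratum: str

    def to_series(self) -> pd.Series:
        return pd.Series(self.mean_signal, index=self.positions, name=self.stratum)


def _gene_ratio_track(
    segs: SegmentMethylationMatrix,
    gene: GeneModel,
    ratio: np.ndarray,
    partition_mask: np.ndarray | None,
    span: int,
) -> np.ndarray:
    """Per-gene methylation ratio in 100-bp TSS-relative bins; NaN where no eligible segment."""
    n_bins = 2 * span // SEGMENT_SIZE
    track = np.full(n_bins, np.nan)
    rows, rel = _segment_rows_for_gene(segs, gene, span)
    ok = rows >= 0
    if partition_mask is not None:
        ok &= np.where(rows >= 0, partition_mask[np.maximum(rows, 0)], False)
    bins = ((rel + span) // SEGMENT_SIZE).astype(int)
    track[bins[ok]] = ratio[rows[ok]]
    return track


def methylation_meta_profile(
    segs: SegmentMethylationMatrix,
    annotation: AnnotationSet,
    qa: QuartileAssignment,
    partition: str = "within_cgi",
    cgi_intervals: Sequence[GenomicInterval] | IntervalIndex | None = None,
    group: str | None = None,
    span: int = TSS_SPAN,
) -> dict[str, MetaProfile]:
    """Mean methylation ratio per 100-bp bin, per expression quartile.

    ``partition`` restricts segments to those within or outside CpG islands
    ('within_cgi' / 'outside_cgi' / 'all'); bins with no eligible segment for
    a gene are missing for that gene and skipped in the quartile mean.
    """
    if partition not in ("within_cgi", "outside_cgi", "all"):
        raise ValueError(f"unknown partition {partition!r}")
    ratio = methylation_ratio(segs, group if group is not None else qa.arm)
    mask = None
    if partition != "all":
        if cgi_intervals is None:
            cgi_intervals = annotation.cgi_intervals
        index = (
            cgi_intervals
            if isinstance(cgi_intervals, IntervalIndex)
            else IntervalIndex(cgi_intervals)
        )
        within = np.zeros(segs.n_segments, dtype=bool)
        for chrom, (i0, i1) in segs._blocks.items():
            s = segs.starts[i0:i1]
            within[i0:i1] = index.overlaps_any(chrom, s, s + SEGMENT_SIZE)
        mask = within if partition == "within_cgi" else ~within

    genes = {g.gene_id: g for g in annotation.genes}
    positions = np.arange(-span, span, SEGMENT_SIZE)
    out: dict[str, MetaProfile] = {}
    for quartile in QUARTILES:
        members = [genes[g] for g in qa.genes_in(quartile) if g in genes]
        if members:
            tracks = np.vstack(
                [_gene_ratio_track(segs, g, ratio, mask, span) for g in members]
            )
            counts = np.sum(~np.isnan(tracks), axis=0)
            mean = np.where(
                counts > 0, np.nansum(np.nan_to_num(tracks), axis=0), np.nan
            ) / np.maximum(counts, 1)
        else:
            mean = np.full(len(positions), np.nan)
        out[quartile] = MetaProfile(
            positions=positions,
            mean_signal=mean,
            n_genes=len(members),
            stratum=f"{quartile}:{partition}",
        )
    return out


# ---------------------------------------------------------------------------
# ChIP coverage


class CoverageTrack:
    """Per-chromosome sorted bedGraph intervals with vectorized point lookup."""

    def __init__(self, df: pd.DataFrame):
        required = ["chrom", "start", "end", "value"]
        if list(df.columns[:4]) != required:
            df = df.copy()
            df.columns = required + list(df.columns[4:])
        if (df["value"] < 0).any():
            raise ValueError("coverage must be nonnegative")
        self._chroms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            sub = sub.sort_values("start")
            self._chroms[str(chrom)] = (
                sub["start"].to_numpy(np.int64),
                sub["end"].to_numpy(np.int64),
                sub["value"].to_numpy(float),
            )

    def values_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Per-bp coverage at the given positions (0 in gaps / off-track)."""
        positions = np.asarray(positions, dtype=np.int64)
        out = np.zeros(len(positions), dtype=float)
        trk = self._chroms.get(chrom)
        if trk is None:
            return out
        starts, ends, vals = trk
        j = np.searchsorted(starts, positions, side="right") - 1
        ok = (j >= 0) & (positions < ends[np.maximum(j, 0)])
        out[ok] = vals[j[ok]]
        return out


def read_bedgraph(path: str | Path) -> CoverageTrack:
    """4-column bedGraph (chrom, start, end, value), 0-based half-open."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "value"],
    )
    return CoverageTrack(df)


def gene_binned_coverage(
    track: CoverageTrack, gene: GeneModel, bin_size: int = CHIP_BIN, span: int = TSS_SPAN
) -> np.ndarray:
    """Strand-aware mean coverage in TSS-relative bins of ``bin_size`` bp."""
    offsets = np.arange(-span, span, dtype=np.int64)
    positions = gene.tss + offsets if gene.strand == "+" else gene.tss - offsets
    vals = track.values_at(gene.chrom, positions)
    return vals.reshape(-1, bin_size).mean(axis=1)


def _coverage_matrix(
    track: CoverageTrack,
    annotation: AnnotationSet,
    gene_ids: Sequence[str],
    bin_size: int,
    span: int,
) -> tuple[np.ndarray, list[str]]:
    genes = {g.gene_id: g for g in annotation.genes}
    rows, kept = [], []
    dropped = 0
    for gid in gene_ids:
        gene = genes.get(gid)
        if gene is None:
            continue
        size = annotation.chrom_sizes.get(gene.chrom)
        if gene.tss - span < 0 or (size is not None and gene.tss + span > size):
            dropped += 1
            continue
        rows.append(gene_binned_coverage(track, gene, bin_size, span))
        kept.append(gid)
    if dropped:
        logger.info("chip profile: dropped %d genes extending past contig ends", dropped)
    mat = np.vstack(rows) if rows else np.zeros((0, 2 * span // bin_size))
    return mat, kept


def chip_meta_profile(
    track: CoverageTrack,
    annotation: AnnotationSet,
    qa: QuartileAssignment,
    bin_size: int = CHIP_BIN,
    span: int = TSS_SPAN,
) -> dict[str, MetaProfile]:
    """Mean 10-bp binned ChIP coverage per expression quartile."""
    positions = np.arange(-span, span, bin_size)
    out: dict[str, MetaProfile] = {}
    for quartile in QUARTILES:
        mat, kept = _coverage_matrix(
            track, annotation, qa.genes_in(quartile), bin_size, span
        )
        mean = mat.mean(axis=0) if len(kept) else np.full(len(positions), np.nan)
        out[quartile] = MetaProfile(
            positions=positions, mean_signal=mean, n_genes=len(kept), stratum=quartile
        )
    return out


@dataclass
class BackgroundBand:
    """Per-bin envelope of meta-profiles of randomized same-size gene lists."""

    positions: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_lists: int
    list_size: int
    seed: int

    def contains(self, profile: np.ndarray) -> np.ndarray:
        return (profile >= self.lower) & (profile <= self.upper)


def randomized_background(
    track: CoverageTrack,
    annotation: AnnotationSet,
    universe: Sequence[str],
    list_size: int = 407,
    n_lists: int = 1000,
    seed: int = 0,
    band: str = "minmax",
    bin_size: int = CHIP_BIN,
    span: int = TSS_SPAN,
) -> BackgroundBand:
    """Envelope of coverage meta-profiles of random gene lists from the universe.

    Each list is drawn without replacement; the band is the per-bin min-max
    envelope by default, or the central 95% envelope (``band='central95'``).
    Deterministic given ``seed``.
    """
    universe = list(universe)
    if len(universe) < list_size:
        raise ValueError(
            f"universe ({len(universe)}) smaller than list_size ({list_size})"
        )
    mat, kept = _coverage_matrix(track, annotation, universe, bin_size, span)
    if len(kept) < list_size:
        raise ValueError("universe after dropping out-of-bounds genes is too small")
    rng = np.random.default_rng(seed)
    profiles = np.empty((n_lists, mat.shape[1]))
    for i in range(n_lists):
        idx = rng.choice(len(kept), size=list_size, replace=False)
        profiles[i] = mat[idx].mean(axis=0)
    if band == "minmax":
        lower, upper = profiles.min(axis=0), profiles.max(axis=0)
    elif band == "central95":
        lower = np.quantile(profiles, 0.025, axis=0)
        upper = np.quantile(profiles, 0.975, axis=0)
    else:
        raise ValueError(f"unknown band type {band!r}")
    return BackgroundBand(
        positions=np.arange(-span, span, bin_size),
        lower=lower,
        upper=upper,
        n_lists=n_lists,
        list_size=list_size,
        seed=seed,
    )


def write_meta_profiles(profiles: Mapping[str, MetaProfile], path) -> None:
    df = pd.DataFrame({name: p.to_series() for name, p in profiles.items()})
    df.index.name = "position"
    df.to_csv(path, sep="\t")


def write_background_band(band: BackgroundBand, path) -> None:
    pd.DataFrame(
        {"position": band.positions, "lower": band.lower, "upper": band.upper}
    ).to_csv(path, sep="\t", index=False)
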