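"""Binary 100-bp segment methylation and 500-bp TSS-relative window scores.

The sequencing-mode input is per-sample methylation peak calls (MACS-style
intervals from MBD-seq). Each 100-bp genomic segment is scored 1 in a sample
iff a peak overlaps it by >= 1 bp. Around each gene's TSS the +/- 5 kb
territory is tiled with twenty non-overlapping 500-bp windows anchored on
the TSS-relative grid (-5000, -4500, ..., +4500); a window's score is the
sum of the binary values of the five 100-bp segments whose midpoints fall
inside it (range 0-5).

Array mode maps per-probe beta values into the same TSS-relative frame with
a probe-density correction: each probe's beta is weighted by the width of
its Voronoi cell (half-distance to the flanking probes, clipped at the
domain edges), so dense probe clusters are not over-counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import AnnotationSet, GeneModel, GenomicInterval, IntervalIndex, TSS_SPAN

logger = logging.getLogger(__name__)

SEGMENT_SIZE = 100
WINDOW_SIZE = 500
N_WINDOWS = 2 * TSS_SPAN // WINDOW_SIZE  # 20
SEGMENTS_PER_WINDOW = WINDOW_SIZE // SEGMENT_SIZE  # 5

WINDOW_STARTS = np.arange(-TSS_SPAN, TSS_SPAN, WINDOW_SIZE)


@dataclass
class SegmentMethylationMatrix:
    """Binary methylation calls for 100-bp segments (rows) x samples (columns).

    Segments are sorted by (chrom, start) with starts divisible by 100;
    ``groups`` maps each sample to its cohort arm ('tumor' or 'normal').
    """

    chroms: np.ndarray
    starts: np.ndarray
    sample_ids: list[str]
    groups: dict[str, str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.values = np.asarray(self.values)
        if np.any(self.starts % SEGMENT_SIZE):
            raise ValueError("segment starts must be multiples of 100")
        if self.values.shape != (len(self.starts), len(self.sample_ids)):
            raise ValueError("values shape does not match segments x samples")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("segment values must be binary")
        self.values = self.values.astype(np.uint8)
        # contiguous per-chromosome blocks for O(log n) segment lookup
        self._blocks: dict[str, tuple[int, int]] = {}
        i = 0
        while i < len(self.chroms):
            j = i
            while j < len(self.chroms) and self.chroms[j] == self.chroms[i]:
                j += 1
            chrom = str(self.chroms[i])
            if chrom in self._blocks:
                raise ValueError("segments must be grouped by chromosome")
            if np.any(np.diff(self.starts[i:j]) <= 0):
                raise ValueError(f"segment starts not strictly increasing on {chrom}")
            self._blocks[chrom] = (i, j)
            i = j

    @property
    def n_segments(self) -> int:
        return len(self.starts)

    def sample_index(self, sample_ids: Sequence[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        return np.array([pos[s] for s in sample_ids], dtype=np.intp)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.groups.get(s) == group]

    def locate(self, chrom: str, starts: np.ndarray) -> np.ndarray:
        """Row indices of the given segment starts; -1 where absent."""
        out = np.full(len(starts), -1, dtype=np.int64)
        blk = self._blocks.get(chrom)
        if blk is None:
            return out
        i0, i1 = blk
        seg = self.starts[i0:i1]
        j = np.searchsorted(seg, starts)
        ok = (j < len(seg)) & (seg[np.minimum(j, len(seg) - 1)] == starts)
        out[ok] = j[ok] + i0
        return out


def segment_grid_for_annotation(
    annotation: AnnotationSet, span: int = TSS_SPAN, margin: int = SEGMENT_SIZE
) -> tuple[np.ndarray, np.ndarray]:
    """Union of 100-bp segments covering every gene's TSS +/- span (plus margin)."""
    per_chrom: dict[str, set[int]] = {}
    for g in annotation.genes:
        lo = max(0, (g.tss - span - margin) // SEGMENT_SIZE * SEGMENT_SIZE)
        hi = g.tss + span + margin
        per_chrom.setdefault(g.chrom, set()).update(
            range(int(lo), int(hi), SEGMENT_SIZE)
        )
    chroms, starts = [], []
    for chrom in sorted(per_chrom):
        ss = sorted(per_chrom[chrom])
        chroms.extend([chrom] * len(ss))
        starts.extend(ss)
    return np.asarray(chroms, dtype=object), np.asarray(starts, dtype=np.int64)


def binarize_segments(
    peaks_by_sample: Mapping[str, Iterable[tuple | GenomicInterval]],
    grid: tuple[np.ndarray, np.ndarray],
    groups: Mapping[str, str],
) -> SegmentMethylationMatrix:
    """Score each grid segment 1 in a sample iff any peak overlaps it by >= 1 bp.

    Peaks on chromosomes absent from the grid are skipped with a logged count.
    """
    chroms, starts = grid
    order = np.lexsort((starts, chroms.astype(str)))
    chroms, starts = chroms[order], starts[order]
    blocks: dict[str, tuple[int, int]] = {}
    i = 0
    while i < len(chroms):
        j = i
        while j < len(chroms) and chroms[j] == chroms[i]:
            j += 1
        blocks[str(chroms[i])] = (i, j)
        i = j

    sample_ids = list(peaks_by_sample)
    values = np.zeros((len(starts), len(sample_ids)), dtype=np.uint8)
    skipped = 0
    for col, sample in enumerate(sample_ids):
        for peak in peaks_by_sample[sample]:
            if isinstance(peak, GenomicInterval):
                chrom, p_start, p_end = peak.chrom, peak.start, peak.end
            else:
                chrom, p_start, p_end = str(peak[0]), int(peak[1]), int(peak[2])
            blk = blocks.get(chrom)
            if blk is None:
                skipped += 1
                continue
            i0, i1 = blk
            seg = starts[i0:i1]
            # segment [s, s+100) overlaps [a, b) iff a-100 < s < b
            lo = np.searchsorted(seg, p_start - SEGMENT_SIZE, side="right")
            hi = np.searchsorted(seg, p_end, side="left")
            values[i0 + lo : i0 + hi, col] = 1
    if skipped:
        logger.warning("binarize_segments: skipped %d peaks on unknown chromosomes", skipped)
    return SegmentMethylationMatrix(
        chroms=chroms,
        starts=starts,
        sample_ids=sample_ids,
        groups=dict(groups),
        values=values,
    )


@dataclass
class WindowScoreMatrix:
    """Per-gene 500-bp window scores: values[gene, window, sample] in 0..5.

    Windows are ordered by TSS-relative start -5000, -4500, ..., +4500
    (:data:`WINDOW_STARTS`); minus-strand genes are mirrored onto the same axis.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    groups: dict[str, str]
    values: np.ndarray
    rel_starts: np.ndarray = field(default_factory=lambda: WINDOW_STARTS.copy())

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        expected = (len(self.gene_ids), len(self.rel_starts), len(self.sample_ids))
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != {expected}")
        if self.values.max(initial=0) > SEGMENTS_PER_WINDOW:
            raise ValueError("window scores exceed 5")

    def sample_index(self, sample_ids: Sequence[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        return np.array([pos[s] for s in sample_ids], dtype=np.intp)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.groups.get(s) == group]

    def gene_index(self, gene_id: str) -> int:
        return self.gene_ids.index(gene_id)

    def to_frame(self) -> pd.DataFrame:
        """Long/wide TSV layout: gene_id, tss_rel_start, one column per sample."""
        n_g, n_w, n_s = self.values.shape
        df = pd.DataFrame(
            self.values.reshape(n_g * n_w, n_s), columns=self.sample_ids
        )
        df.insert(0, "tss_rel_start", np.tile(self.rel_starts, n_g))
        df.insert(0, "gene_id", np.repeat(self.gene_ids, n_w))
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, groups: Mapping[str, str]) -> "WindowScoreMatrix":
        sample_ids = [c for c in df.columns if c not in ("gene_id", "tss_rel_start")]
        gene_ids = list(dict.fromkeys(df["gene_id"]))
        n_w = len(WINDOW_STARTS)
        values = (
            df[sample_ids].to_numpy().reshape(len(gene_ids), n_w, len(sample_ids))
        )
        return cls(
            gene_ids=gene_ids,
            sample_ids=sample_ids,
            groups=dict(groups),
            values=values,
        )


def _segment_rows_for_gene(
    segs: SegmentMethylationMatrix, gene: GeneModel, span: int = TSS_SPAN
) -> tuple[np.ndarray, np.ndarray]:
    """(row indices, TSS-relative midpoints) of segments whose midpoint is in [-span, span)."""
    # midpoints sit at start+50; rel in [-span, span) bounds the start range
    if gene.strand == "+":
        lo = gene.tss - span - SEGMENT_SIZE // 2
        hi = gene.tss + span - SEGMENT_SIZE // 2
    else:
        lo = gene.tss - span - SEGMENT_SIZE // 2 + 1
        hi = gene.tss + span - SEGMENT_SIZE // 2 + 1
    starts = np.arange(
        int(np.ceil(lo / SEGMENT_SIZE)) * SEGMENT_SIZE, hi, SEGMENT_SIZE, dtype=np.int64
    )
    starts = starts[starts >= 0]
    mids = starts + SEGMENT_SIZE // 2
    rel = mids - gene.tss if gene.strand == "+" else gene.tss - mids
    keep = (rel >= -span) & (rel < span)
    rows = segs.locate(gene.chrom, starts[keep])
    return rows, rel[keep]


def window_scores(
    segs: SegmentMethylationMatrix,
    annotation: AnnotationSet,
    span: int = TSS_SPAN,
) -> WindowScoreMatrix:
    """Sum binary segment calls into twenty strand-aware 500-bp windows per gene.

    A segment contributes to the window containing its TSS-relative midpoint.
    Genes whose TSS +/- span territory leaves the chromosome are dropped with
    a log entry; segments missing from the matrix count as unmethylated.
    """
    kept_genes: list[str] = []
    rows_list: list[np.ndarray] = []
    win_list: list[np.ndarray] = []
    dropped = 0
    for gene in annotation.genes:
        size = annotation.chrom_sizes.get(gene.chrom)
        if gene.tss - span < 0 or (size is not None and gene.tss + span > size):
            dropped += 1
            continue
        rows, rel = _segment_rows_for_gene(segs, gene, span)
        widx = (rel + span) // WINDOW_SIZE
        ok = rows >= 0
        kept_genes.append(gene.gene_id)
        rows_list.append(rows[ok])
        win_list.append(widx[ok].astype(np.int64))
    if dropped:
        logger.info("window_scores: dropped %d genes with territory out of bounds", dropped)

    n_samples = len(segs.sample_ids)
    values = np.zeros((len(kept_genes), N_WINDOWS, n_samples), dtype=np.uint8)
    for gi, (rows, widx) in enumerate(zip(rows_list, win_list)):
        np.add.at(values[gi], widx, segs.values[rows])
    return WindowScoreMatrix(
        gene_ids=kept_genes,
        sample_ids=list(segs.sample_ids),
        groups=dict(segs.groups),
        values=values,
    )


def methylation_ratio(
    segs: SegmentMethylationMatrix, group: str | Sequence[str]
) -> np.ndarray:
    """Across-sample mean of the binary calls within a group, per segment."""
    samples = segs.samples_in_group(group) if isinstance(group, str) else list(group)
    if not samples:
        raise ValueError(f"no samples in group {group!r}")
    cols = segs.sample_index(samples)
    return segs.values[:, cols].mean(axis=1)


def partition_by_cgi(
    segs: SegmentMethylationMatrix,
    cgi_intervals: Iterable[GenomicInterval] | IntervalIndex,
) -> dict[str, np.ndarray]:
    """Disjoint, exhaustive split of segment rows into within/outside CpG islands.

    A segment straddling a CGI boundary (>= 1 bp overlap) counts as within.
    """
    index = (
        cgi_intervals
        if isinstance(cgi_intervals, IntervalIndex)
        else IntervalIndex(cgi_intervals)
    )
    within = np.zeros(segs.n_segments, dtype=bool)
    for chrom, (i0, i1) in segs._blocks.items():
        s = segs.starts[i0:i1]
        within[i0:i1] = index.overlaps_any(chrom, s, s + SEGMENT_SIZE)
    return {"within_cgi": np.flatnonzero(within), "outside_cgi": np.flatnonzero(~within)}


# ---------------------------------------------------------------------------
# array mode (HM450K-style probe panels)


@dataclass
class ProbePanel:
    """Probe positions plus a probe x sample beta matrix (values in [0, 1])."""

    probe_ids: list[str]
    chroms: np.ndarray
    positions: np.ndarray
    betas: pd.DataFrame

    def __post_init__(self) -> None:
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        vals = self.betas.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0 or np.nanmax(vals, initial=0.0) > 1:
            raise ValueError("beta values must lie in [0, 1]")
        if list(self.betas.index) != list(self.probe_ids):
            self.betas = self.betas.loc[self.probe_ids]


def voronoi_weights(rel_positions: np.ndarray, span: int = TSS_SPAN) -> np.ndarray:
    """Width of each probe's Voronoi cell within [-span, +span].

    Cell boundaries are half-distances to flanking probes, clipped at the
    domain edges; duplicated positions share their cell equally. Weights are
    nonnegative and sum to the domain width (2 * span).
    """
    rel = np.asarray(rel_positions, dtype=float)
    order = np.argsort(rel, kind="stable")
    srt = rel[order]
    uniq, inv, counts = np.unique(srt, return_inverse=True, return_counts=True)
    bounds = np.concatenate(([-span], (uniq[:-1] + uniq[1:]) / 2.0, [span]))
    bounds = np.clip(bounds, -span, span)
    widths = np.maximum(np.diff(bounds), 0.0)
    w_sorted = widths[inv] / counts[inv]
    out = np.empty_like(w_sorted)
    out[order] = w_sorted
    return out


def _bin_inverse_weights(rel_positions: np.ndarray, span: int = TSS_SPAN) -> np.ndarray:
    """Alternative probe weighting: inverse probe count in 500-bp TSS-relative bins."""
    rel = np.asarray(rel_positions, dtype=float)
    bins = np.clip(((rel + span) // WINDOW_SIZE).astype(int), 0, N_WINDOWS - 1)
    counts = np.bincount(bins, minlength=N_WINDOWS)
    return 1.0 / counts[bins]


def probe_weighted_gene_methylation(
    panel: ProbePanel,
    gene: GeneModel,
    span: int = TSS_SPAN,
    scheme: str = "voronoi",
) -> pd.Series | None:
    """Probe-density-corrected per-sample methylation of one gene's TSS +/- span.

    Returns the weighted mean beta per sample, or None (gene excluded
    downstream) when no probe falls inside the window.
    """
    on_chrom = np.flatnonzero(panel.chroms == gene.chrom)
    rel = (
        panel.positions[on_chrom] - gene.tss
        if gene.strand == "+"
        else gene.tss - panel.positions[on_chrom]
    )
    keep = (rel >= -span) & (rel <= span)
    if not keep.any():
        return None
    idx = on_chrom[keep]
    if scheme == "voronoi":
        w = voronoi_weights(rel[keep], span)
    elif scheme == "bin_inverse":
        w = _bin_inverse_weights(rel[keep], span)
    else:
        raise ValueError(f"unknown weighting scheme {scheme!r}")
    betas = panel.betas.iloc[idx].to_numpy(dtype=float)
    return pd.Series(w @ betas / w.sum(), index=panel.betas.columns, name=gene.gene_id)


# ---------------------------------------------------------------------------
# I/O


def read_peaks_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """BED3+ peak calls (MACS narrowPeak accepted; extra columns ignored)."""
    peaks: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            peaks.append((f[0], int(f[1]), int(f[2])))
    return peaks


def read_sample_manifest(path: str | Path) -> pd.DataFrame:
    """Sample manifest TSV with columns sample_id, group[, path]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    return df


def load_segments_from_manifest(
    manifest: pd.DataFrame, annotation: AnnotationSet, base_dir: str | Path = "."
) -> SegmentMethylationMatrix:
    """Binarize per-sample peak BEDs (from a manifest with a ``path`` column)."""
    grid = segment_grid_for_annotation(annotation)
    peaks = {
        row.sample_id: read_peaks_bed(Path(base_dir) / row.path)
        for row in manifest.itertuples()
    }
    groups = dict(zip(manifest["sample_id"], manifest["group"]))
    return binarize_segments(peaks, grid, groups)
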