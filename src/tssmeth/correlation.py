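"""Windowed methylation-expression correlation maps and density profiles.

For every (gene, 500-bp window) pair the methylation window score is
correlated with the gene's normalized expression across the samples of one
cohort arm using Spearman's rank correlation; p-values come from the
large-sample t approximation and are adjusted jointly within the arm by the
Benjamini-Hochberg step-up rule. Windows passing the FDR threshold
contribute their TSS-relative midpoints to a Gaussian kernel density
estimate over the +/- 5 kb domain, truncated and renormalized so the area
under the curve is exactly 1.

The hot inner loop (rank, correlate, adjust) is vectorized over all
(gene, window) records at once so that the permutation test can rerun it
hundreds of times; :class:`ArmEngine` carries the precomputed rank matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .genome import TSS_SPAN
from .scoring import WINDOW_SIZE, WindowScoreMatrix

MIN_SAMPLES = 5

#: default fraction of arm samples in which a gene must be nonzero to count
#: as expressed (the analysis universe)
EXPRESSED_FRACTION = 0.2


class DegenerateInputError(ValueError):
    """A constant vector makes the rank correlation undefined."""


class InsufficientCoordinatesError(ValueError):
    """Fewer than two distinct coordinates; no density can be estimated."""


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    Returns (rho, p) with p from the t approximation on n - 2 degrees of
    freedom. Raises :class:`DegenerateInputError` when either vector is
    constant (rho undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = len(x)
    if n < MIN_SAMPLES:
        raise ValueError(f"need >= {MIN_SAMPLES} samples, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("constant vector: rank correlation undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    rho = float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))
    rho = min(1.0, max(-1.0, rho))
    return rho, _rho_pvalue(np.array([rho]), n)[0]


def _rho_pvalue(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from the t approximation; exactly 0 at |rho| = 1."""
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = np.where(np.abs(rho) >= 1.0, 0.0, 2.0 * special.stdtr(n - 2, -np.abs(t)))
    return np.asarray(p, dtype=float)


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values: q_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def expressed_genes(
    expr: pd.DataFrame, samples: Sequence[str], min_fraction: float = EXPRESSED_FRACTION
) -> list[str]:
    """Genes with nonzero expression in at least ``min_fraction`` of the samples."""
    sub = expr[list(samples)]
    frac = (sub > 0).mean(axis=1)
    return list(sub.index[frac >= min_fraction])


class ArmEngine:
    """Precomputed rank matrices for one cohort arm.

    Rows are the testable (gene, window) records: windows with nonzero
    methylation variance belonging to expressed genes with nonzero expression
    variance. Methylation and expression ranks are centred to zero mean and
    unit norm, so Spearman's rho for record r under an expression permutation
    ``perm`` is the dot product ``M[r] . E[gene_of[r], perm]``.
    """

    def __init__(
        self,
        wsm: WindowScoreMatrix,
        expr: pd.DataFrame,
        samples: Sequence[str] | None = None,
        group: str | None = None,
        min_samples: int = MIN_SAMPLES,
        expressed_fraction: float = EXPRESSED_FRACTION,
    ):
        if samples is None:
            if group is None:
                raise ValueError("provide either samples or group")
            samples = wsm.samples_in_group(group)
        samples = [s for s in samples if s in expr.columns]
        if not samples:
            raise ValueError("no overlapping samples between methylation and expression")
        if len(samples) < min_samples:
            raise ValueError(f"need >= {min_samples} samples in arm, got {len(samples)}")
        self.samples = list(samples)
        self.n = len(samples)

        universe = [
            g
            for g in expressed_genes(expr, samples, expressed_fraction)
            if g in set(wsm.gene_ids)
        ]
        gpos = {g: i for i, g in enumerate(wsm.gene_ids)}
        gidx = np.array([gpos[g] for g in universe], dtype=np.intp)
        scol = wsm.sample_index(samples)

        meth = wsm.values[np.ix_(gidx, np.arange(len(wsm.rel_starts)), scol)].astype(float)
        evals = expr.loc[universe, samples].to_numpy(dtype=float)

        n_g, n_w, n = meth.shape
        flat = meth.reshape(n_g * n_w, n)
        meth_ok = np.ptp(flat, axis=1) > 0
        expr_ok = np.ptp(evals, axis=1) > 0
        keep = meth_ok & np.repeat(expr_ok, n_w)
        self.n_degenerate = int(np.sum(~keep))

        self.record_gene = np.repeat(np.arange(n_g), n_w)[keep]
        self.record_window = np.tile(wsm.rel_starts, n_g)[keep]
        self.gene_ids = list(universe)

        self.M = _rank_center_rows(flat[keep])
        self.E = _rank_center_rows(evals, allow_constant=True)

    def rho(self, perm: np.ndarray | None = None) -> np.ndarray:
        e = self.E if perm is None else self.E[:, perm]
        r = np.einsum("ij,ij->i", self.M, e[self.record_gene])
        return np.clip(r, -1.0, 1.0)

    def rho_p(self, perm: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        r = self.rho(perm)
        return r, _rho_pvalue(r, self.n)

    def to_frame(self, perm: np.ndarray | None = None) -> pd.DataFrame:
        rho, p = self.rho_p(perm)
        return pd.DataFrame(
            {
                "gene_id": np.asarray(self.gene_ids, dtype=object)[self.record_gene],
                "window_start": self.record_window,
                "rho": rho,
                "p": p,
                "q": bh_fdr(p),
                "n": self.n,
            }
        )


def _rank_center_rows(a: np.ndarray, allow_constant: bool = False) -> np.ndarray:
    """Row-wise average ranks, centred to zero mean and unit Euclidean norm."""
    r = stats.rankdata(a, axis=1)
    r -= r.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(r, axis=1, keepdims=True)
    if allow_constant:
        norm = np.where(norm == 0, 1.0, norm)
    return r / norm


def build_correlation_map(
    wsm: WindowScoreMatrix,
    expr: pd.DataFrame,
    group: str | None = None,
    samples: Sequence[str] | None = None,
    expressed_fraction: float = EXPRESSED_FRACTION,
) -> pd.DataFrame:
    """Spearman rho/p/q per (gene, window) across the samples of one arm.

    Zero-variance methylation windows and constant-expression genes are
    excluded before the BH adjustment, so the FDR is taken over testable
    hypotheses only; the adjustment spans all retained gene x window records
    of the arm jointly.
    """
    engine = ArmEngine(
        wsm, expr, samples=samples, group=group, expressed_fraction=expressed_fraction
    )
    return engine.to_frame()


def significant_coordinates(
    cm: pd.DataFrame,
    q_max: float = 0.05,
    sign: str = "any",
    gene_set: set[str] | None = None,
) -> np.ndarray:
    """TSS-relative midpoints (window start + 250) of significant windows.

    ``sign`` filters on the direction of rho ('any', 'negative', 'positive');
    ``gene_set`` restricts to a gene universe (e.g. CGI genes). The result is
    a multiset: one entry per passing record, duplicates retained.
    """
    if sign not in ("any", "negative", "positive"):
        raise ValueError(f"invalid sign filter {sign!r}")
    if len(cm) == 0:
        return np.array([], dtype=float)
    mask = cm["q"].to_numpy() < q_max
    if sign == "negative":
        mask &= cm["rho"].to_numpy() < 0
    elif sign == "positive":
        mask &= cm["rho"].to_numpy() > 0
    if gene_set is not None:
        mask &= cm["gene_id"].isin(gene_set).to_numpy()
    return cm["window_start"].to_numpy(dtype=float)[mask] + WINDOW_SIZE / 2.0


@dataclass
class DensityProfile:
    """Truncated-renormalized KDE of significant coordinates on [-5000, 5000].

    ``density`` is evaluated on ``grid`` (10-bp spacing) and integrates to 1
    by the trapezoidal rule; ``bandwidth`` is the Gaussian kernel SD in bp.
    """

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    n_points: int

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))

    def mode(self) -> float:
        return float(self.grid[np.argmax(self.density)])


def density_profile(
    coords: Sequence[float],
    bandwidth: float | str = "auto",
    span: int = TSS_SPAN,
    grid_step: int = 10,
) -> DensityProfile:
    """Gaussian KDE of coordinates, truncated to [-span, span] and renormalized.

    ``bandwidth`` is either "auto" (Silverman's rule on the coordinate sample)
    or a kernel SD in bp. Requires >= 2 distinct coordinates.
    """
    coords = np.asarray(coords, dtype=float)
    if len(np.unique(coords)) < 2:
        raise InsufficientCoordinatesError(
            f"insufficient coordinates: {len(np.unique(coords))} distinct point(s)"
        )
    sd = float(np.std(coords, ddof=1))
    if bandwidth == "auto":
        kde = stats.gaussian_kde(coords, bw_method="silverman")
    else:
        kde = stats.gaussian_kde(coords, bw_method=float(bandwidth) / sd)
    grid = np.arange(-span, span + grid_step, grid_step, dtype=float)
    dens = kde(grid)
    dens = np.maximum(dens, 0.0)
    area = np.trapezoid(dens, grid)
    if area <= 0:
        raise InsufficientCoordinatesError("degenerate density (zero mass on domain)")
    return DensityProfile(
        grid=grid,
        density=dens / area,
        bandwidth=float(kde.factor * sd),
        n_points=len(coords),
    )


# ---------------------------------------------------------------------------
# I/O


def read_expression(path) -> pd.DataFrame:
    """Gene x sample normalized expression TSV (RSEM-style, nonnegative)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    vals = df.to_numpy(dtype=float)
    if not np.isfinite(vals).all() or (vals < 0).any():
        raise ValueError("expression values must be finite and nonnegative")
    return df


def write_correlation_map(cm: pd.DataFrame, path) -> None:
    cm.to_csv(path, sep="\t", index=False)


def write_density_profile(profile: DensityProfile, path) -> None:
    pd.DataFrame({"position": profile.grid, "density": profile.density}).to_csv(
        path, sep="\t", index=False
    )
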