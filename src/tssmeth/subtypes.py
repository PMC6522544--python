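"""Methylation subtype discovery and mutation association.

Genes whose tumor-arm correlation map shows strongly significant negative
methylation-expression correlation (default FDR q < 0.001) are selected at
their best (minimum-q) window; tumor samples are then clustered on the raw
0-5 window scores of those best windows with Euclidean distance and Ward's
linkage. Cluster labels are ordered by descending mean methylation so that
cluster 1 is always the hypermethylation phenotype. Mutation status is
related to cluster membership by a two-sided Fisher exact test, with a
protein-change parser and a domain-effect rule for classifying variants
against a protein domain (e.g. the CREBBP HAT domain, residues 1342-1649).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy import stats

from .scoring import WindowScoreMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSelection:
    """One selected gene with its most significant window."""

    gene_id: str
    best_window_start: int
    rho: float
    q: float


def select_genes(
    cm: pd.DataFrame, q_max: float = 0.001, sign: str = "negative"
) -> list[GeneSelection]:
    """Per gene, the minimum-q window passing the q and rho-sign filters.

    Ties on q break toward the window closest to the TSS, then upstream
    (more negative start). Deterministic and stable under row permutation.
    """
    if len(cm) == 0:
        return []
    df = cm.copy()
    if sign == "negative":
        df = df[df["rho"] < 0]
    elif sign == "positive":
        df = df[df["rho"] > 0]
    elif sign != "any":
        raise ValueError(f"invalid sign filter {sign!r}")
    df = df[df["q"] < q_max]
    if len(df) == 0:
        return []
    df = df.assign(_absw=df["window_start"].abs()).sort_values(
        ["gene_id", "q", "_absw", "window_start"], kind="stable"
    )
    best = df.groupby("gene_id", sort=True).head(1)
    return [
        GeneSelection(
            gene_id=r.gene_id,
            best_window_start=int(r.window_start),
            rho=float(r.rho),
            q=float(r.q),
        )
        for r in best.itertuples()
    ]


def methylation_change(
    selection: Sequence[GeneSelection],
    wsm: WindowScoreMatrix,
    tumor_group: str = "tumor",
    normal_group: str = "normal",
) -> dict[str, str]:
    """Direction of the tumor-vs-normal mean score at each selected gene's best window.

    'increased' when the tumor mean exceeds the normal mean; exact ties count
    as 'decreased' with a logged warning.
    """
    t_cols = wsm.sample_index(wsm.samples_in_group(tumor_group))
    n_cols = wsm.sample_index(wsm.samples_in_group(normal_group))
    if len(t_cols) == 0 or len(n_cols) == 0:
        raise ValueError("both tumor and normal arms must be present")
    wpos = {int(w): i for i, w in enumerate(wsm.rel_starts)}
    out: dict[str, str] = {}
    for sel in selection:
        gi = wsm.gene_index(sel.gene_id)
        wi = wpos[sel.best_window_start]
        t_mean = wsm.values[gi, wi, t_cols].mean()
        n_mean = wsm.values[gi, wi, n_cols].mean()
        if t_mean == n_mean:
            logger.warning("methylation_change: exact tie for %s; calling 'decreased'", sel.gene_id)
        out[sel.gene_id] = "increased" if t_mean > n_mean else "decreased"
    return out


def selection_matrix(
    selection: Sequence[GeneSelection],
    wsm: WindowScoreMatrix,
    samples: Sequence[str],
    zscore: bool = False,
) -> pd.DataFrame:
    """Samples x selected-genes matrix of best-window scores (clustering input)."""
    cols = wsm.sample_index(samples)
    wpos = {int(w): i for i, w in enumerate(wsm.rel_starts)}
    data = {}
    for sel in selection:
        gi = wsm.gene_index(sel.gene_id)
        v = wsm.values[gi, wpos[sel.best_window_start], cols].astype(float)
        if zscore:
            sd = v.std()
            v = (v - v.mean()) / sd if sd > 0 else v - v.mean()
        data[sel.gene_id] = v
    return pd.DataFrame(data, index=list(samples))


@dataclass
class SubtypeAssignment:
    """sample -> cluster label in 1..k; label 1 has the highest mean methylation."""

    labels: dict[str, int]
    k: int
    linkage_height_at_cut: float

    def samples_in(self, cluster: int) -> list[str]:
        return [s for s, c in self.labels.items() if c == cluster]


def ward_cluster(matrix: pd.DataFrame, k: int = 3) -> SubtypeAssignment:
    """Agglomerative clustering (Euclidean distance, Ward linkage) cut at k clusters.

    Labels are relabelled by descending cluster-mean methylation, so cluster 1
    is the 'high' subtype. Columns with missing values are dropped with a log
    entry; duplicated rows always co-cluster (zero distance).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(matrix):
        raise ValueError(f"k={k} exceeds the number of samples ({len(matrix)})")
    bad = matrix.columns[matrix.isna().any()]
    if len(bad):
        logger.warning("ward_cluster: dropping %d genes with missing windows", len(bad))
        matrix = matrix.drop(columns=bad)
    if k == 1:
        return SubtypeAssignment(
            labels={s: 1 for s in matrix.index}, k=1, linkage_height_at_cut=float("inf")
        )
    Z = hierarchy.linkage(matrix.to_numpy(dtype=float), method="ward", metric="euclidean")
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    heights = np.sort(Z[:, 2])
    cut_height = float(heights[-(k - 1)]) if k - 1 <= len(heights) else 0.0
    # order clusters by descending mean methylation: 1 = high
    means = {c: matrix.to_numpy()[raw == c].mean() for c in np.unique(raw)}
    order = sorted(means, key=lambda c: -means[c])
    remap = {c: i + 1 for i, c in enumerate(order)}
    return SubtypeAssignment(
        labels={s: remap[c] for s, c in zip(matrix.index, raw)},
        k=int(len(order)),
        linkage_height_at_cut=cut_height,
    )


# ---------------------------------------------------------------------------
# protein changes and mutation association

_AA3 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C", "Gln": "Q",
    "Glu": "E", "Gly": "G", "His": "H", "Ile": "I", "Leu": "L", "Lys": "K",
    "Met": "M", "Phe": "F", "Pro": "P", "Ser": "S", "Thr": "T", "Trp": "W",
    "Tyr": "Y", "Val": "V", "Ter": "X",
}


@dataclass(frozen=True)
class ProteinChange:
    """A parsed protein-level variant (compact or simple HGVS p. notation)."""

    raw: str
    kind: str  # missense | nonsense | frameshift | inframe_del | other
    position_start: int
    position_end: int


def _normalize_token(token: str) -> str:
    token = token.strip()
    if token.startswith("p."):
        token = token[2:]
    token = token.strip("()")
    # collapse three-letter amino-acid codes to one-letter
    for three, one in _AA3.items():
        token = token.replace(three, one)
    return token.replace("*", "X")


def parse_protein_change(raw: str) -> ProteinChange:
    """Parse compact notation (R1446C, Q771X, Q2202_Q2203del, E123fs) or HGVS p. forms."""
    token = _normalize_token(raw)
    m = re.fullmatch(r"([A-Z])(\d+)_([A-Z])(\d+)del", token)
    if m:
        start, end = int(m.group(2)), int(m.group(4))
        if not 1 <= start <= end:
            raise ValueError(f"invalid residue range in {raw!r}")
        return ProteinChange(raw=raw, kind="inframe_del", position_start=start, position_end=end)
    m = re.fullmatch(r"([A-Z])(\d+)del", token)
    if m:
        pos = int(m.group(2))
        return ProteinChange(raw=raw, kind="inframe_del", position_start=pos, position_end=pos)
    m = re.fullmatch(r"([A-Z])(\d+)fs.*", token)
    if m:
        pos = int(m.group(2))
        return ProteinChange(raw=raw, kind="frameshift", position_start=pos, position_end=pos)
    m = re.fullmatch(r"([A-Z])(\d+)([A-Z])", token)
    if m:
        pos = int(m.group(2))
        kind = "nonsense" if m.group(3) == "X" else "missense"
        return ProteinChange(raw=raw, kind=kind, position_start=pos, position_end=pos)
    raise ValueError(f"unparseable protein change: {raw!r}")


def classify_domain_effect(
    pc: ProteinChange | str, domain: tuple[int, int]
) -> bool:
    """Does a protein change affect a residue-interval domain?

    True iff (a) any altered residue lies within the domain, or (b) the
    change truncates the protein (nonsense or frameshift) at or upstream of
    the domain end, removing or disrupting the domain.
    """
    if isinstance(pc, str):
        pc = parse_protein_change(pc)
    lo, hi = domain
    if pc.kind in ("nonsense", "frameshift"):
        return pc.position_start <= hi
    return pc.position_start <= hi and pc.position_end >= lo


def fisher_association(
    mutation_status: Mapping[str, str],
    subtypes: SubtypeAssignment,
    target_cluster: int,
) -> tuple[float, float, np.ndarray]:
    """Two-sided Fisher exact test of mutation vs membership in the target cluster.

    The 2x2 table is [[mutant&target, wildtype&target], [mutant&rest,
    wildtype&rest]] over the samples present in both inputs. Returns
    (odds_ratio, p, table); the odds ratio uses the Haldane 0.5 correction
    when any cell is zero. Degenerate margins (an empty row or column) error.
    """
    samples = [s for s in subtypes.labels if s in mutation_status]
    table = np.zeros((2, 2), dtype=int)
    for s in samples:
        row = 0 if subtypes.labels[s] == target_cluster else 1
        col = 0 if mutation_status[s] == "mutant" else 1
        table[row, col] += 1
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError(f"degenerate margin in 2x2 table {table.tolist()}")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    t = table.astype(float)
    if (t == 0).any():
        t = t + 0.5
    odds = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    return float(odds), float(p), table


def write_selection(selection: Sequence[GeneSelection], direction: Mapping[str, str], path) -> None:
    pd.DataFrame(
        {
            "gene_id": [s.gene_id for s in selection],
            "best_window_start": [s.best_window_start for s in selection],
            "rho": [s.rho for s in selection],
            "q": [s.q for s in selection],
            "direction": [direction.get(s.gene_id, "") for s in selection],
        }
    ).to_csv(path, sep="\t", index=False)


def write_subtypes(subtypes: SubtypeAssignment, path) -> None:
    pd.DataFrame(
        {"sample_id": list(subtypes.labels), "cluster": list(subtypes.labels.values())}
    ).to_csv(path, sep="\t", index=False)
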