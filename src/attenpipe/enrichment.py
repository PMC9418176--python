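"""Factor-overlap enrichment over peaks split by down-regulation status.

For each named factor peak set, peaks of the reference set are flagged
for >= 1 bp overlap; the difference in overlap proportion between
down-regulated and not-down-regulated reference peaks is tested with
Fisher's exact test, BH-corrected across factors, and the overlap
indicator vectors of significant factors are clustered with binary
(Jaccard) distance and average linkage (UPGMA).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .core import PeakSet, ValidationError
from .stats import bh_adjust, fisher_exact_two_sided

__all__ = [
    "EnrichmentRow",
    "overlap_indicator",
    "overlap_matrix",
    "factor_enrichment",
    "binary_distance",
    "binary_distance_matrix",
    "average_linkage",
    "dendrogram_to_newick",
]


@dataclass
class EnrichmentRow:
    """One factor's 2x2 overlap table, odds ratio, p and BH FDR.

    Table cells: a = down & overlapped, b = down & not, c = not-down &
    overlapped, d = not-down & not. The odds ratio is Haldane–Anscombe
    corrected (add 0.5 to every cell) when any cell is zero; the
    p-value stays exact and uncorrected.
    """

    factor: str
    a: int
    b: int
    c: int
    d: int
    odds: float
    p: float
    fdr: float = np.nan
    significant: bool = False


def overlap_indicator(reference: PeakSet, factor: PeakSet) -> np.ndarray:
    """Binary vector over reference peaks: 1 iff any factor interval
    shares at least one base, computed by a sweep over sorted intervals."""
    out = np.zeros(len(reference), dtype=np.int8)
    factor_by_chrom: dict[str, list] = factor.by_chrom()
    offset = 0
    for chrom, ref_peaks in reference.by_chrom().items():
        fac = factor_by_chrom.get(chrom, [])
        fs = np.array([p.interval.start for p in fac], dtype=np.int64)
        fe = np.array([p.interval.end for p in fac], dtype=np.int64)
        # factor intervals sorted by start; running max of ends makes the
        # "any earlier-starting interval reaches into us" test a prefix query
        fe_cummax = np.maximum.accumulate(fe) if fe.size else fe
        for i, p in enumerate(ref_peaks):
            if fs.size:
                j = np.searchsorted(fs, p.interval.end, side="left")
                if j > 0 and fe_cummax[j - 1] > p.interval.start:
                    out[offset + i] = 1
        offset += len(ref_peaks)
    return out


def overlap_matrix(reference: PeakSet, factors: list[PeakSet]) -> pd.DataFrame:
    """Factors x reference-peaks binary overlap indicator matrix.

    Reference-peak column order follows the set's sorted peak order.
    """
    rows = {f.name: overlap_indicator(reference, f) for f in factors}
    cols = [p.name for p in reference]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols).astype(np.int8)


def factor_enrichment(
    matrix: pd.DataFrame, down_flags: np.ndarray, fdr_cut: float = 0.05
) -> list[EnrichmentRow]:
    """Per-factor Fisher test of overlap proportion, down vs not-down peaks.

    ``matrix`` is factors x peaks (0/1); ``down_flags`` is the per-peak
    boolean split. FDR is BH across factors; a factor is flagged
    significant at ``fdr < fdr_cut``.
    """
    down = np.asarray(down_flags, dtype=bool)
    if down.size != matrix.shape[1]:
        raise ValidationError("down_flags length must match the peak axis")
    n_down = int(down.sum())
    if n_down == 0 or n_down == down.size:
        raise ValidationError("need >= 1 down and >= 1 not-down peak")
    rows = []
    for factor, ind in matrix.iterrows():
        v = ind.to_numpy().astype(bool)
        a = int((v & down).sum())
        b = n_down - a
        c = int((v & ~down).sum())
        d = int((~down).sum()) - c
        _, p = fisher_exact_two_sided(a, b, c, d)
        if min(a, b, c, d) == 0:
            odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            odds = (a * d) / (b * c)
        rows.append(EnrichmentRow(factor=str(factor), a=a, b=b, c=c, d=d, odds=odds, p=p))
    fdrs = bh_adjust([r.p for r in rows])
    for r, f in zip(rows, fdrs):
        r.fdr = float(f)
        r.significant = f < fdr_cut
    return rows


def binary_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Asymmetric binary (Jaccard) distance: 1 − |u∧v| / |u∨v|."""
    u = np.asarray(u, dtype=bool)
    v = np.asarray(v, dtype=bool)
    if u.shape != v.shape:
        raise ValidationError("vectors must share length")
    union = int((u | v).sum())
    if union == 0:
        raise ValidationError("binary distance undefined for two all-zero vectors")
    return 1.0 - int((u & v).sum()) / union


def binary_distance_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise binary distances between the rows of a 0/1 matrix."""
    n = matrix.shape[0]
    arr = matrix.to_numpy().astype(bool)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = binary_distance(arr[i], arr[j])
    return pd.DataFrame(out, index=matrix.index, columns=matrix.index)


def average_linkage(
    dist: pd.DataFrame, cut_height: float | None = None
) -> tuple[np.ndarray, pd.Series | None]:
    """UPGMA agglomeration of a symmetric distance matrix.

    Returns the scipy-format linkage matrix (merge list with heights)
    and, when ``cut_height`` is given, flat cluster labels from cutting
    the dendrogram at that height.
    """
    arr = dist.to_numpy(dtype=float)
    if arr.shape[0] != arr.shape[1] or not np.allclose(arr, arr.T):
        raise ValidationError("distance matrix must be symmetric")
    if not np.allclose(np.diag(arr), 0):
        raise ValidationError("distance matrix must have a zero diagonal")
    if arr.shape[0] == 1:
        z = np.zeros((0, 4))
        flat = pd.Series([1], index=dist.index) if cut_height is not None else None
        return z, flat
    z = linkage(squareform(arr, checks=False), method="average")
    flat = None
    if cut_height is not None:
        flat = pd.Series(fcluster(z, t=cut_height, criterion="distance"), index=dist.index)
    return z, flat


def dendrogram_to_newick(z: np.ndarray, labels: list[str]) -> str:
    """Render a linkage matrix as a Newick string with branch lengths."""
    n = len(labels)
    if n == 1:
        return f"{labels[0]};"
    heights = {i: 0.0 for i in range(n)}
    nodes: dict[int, str] = {i: labels[i] for i in range(n)}
    for k, (i, j, h, _) in enumerate(z):
        i, j = int(i), int(j)
        bi = (h - heights[i]) / 2.0
        bj = (h - heights[j]) / 2.0
        nodes[n + k] = f"({nodes[i]}:{bi:.6g},{nodes[j]}:{bj:.6g})"
        heights[n + k] = h
    return nodes[n + len(z) - 1] + ";"
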