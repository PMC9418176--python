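"""Signal-over-interval quantification and peak-level integration.

Implements the ``mean0`` averaging convention (bases without coverage
count as zero over the full interval length), depth normalization of
signal tracks, twofold change classification of peaks between
conditions, peak-to-gene association by TSS distance, genomic-context
annotation, metaprofiles around peak centers, and the peak-level
correlation between binding change and accessibility change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenomicInterval, PeakSet, SignalTrack, TSSTable, ValidationError
from .stats import spearman

logger = logging.getLogger(__name__)

__all__ = [
    "PeakSignalRecord",
    "ContextAnnotation",
    "MetaProfile",
    "mean0",
    "genome_wide_mean",
    "normalize_track",
    "classify_peaks",
    "associate_peaks_to_genes",
    "annotate_context",
    "metaprofile",
    "chip_atac_correlation",
]

CONTEXT_CATEGORIES = ("TSS±1kb", "1–10kb", ">10kb intragenic", ">10kb intergenic")


@dataclass
class PeakSignalRecord:
    peak: str
    mean0_wt: float
    mean0_ko: float
    fold: float  # (wt + eps) / (ko + eps)
    log2_fold: float
    klass: str  # down / up / unchanged


@dataclass
class ContextAnnotation:
    peak: str
    tss_distance: int  # center-to-nearest-TSS, bp
    category: str


@dataclass
class MetaProfile:
    offsets: np.ndarray  # bin centers, bp relative to peak center
    mean_signal: np.ndarray
    n_peaks: int
    n_dropped: int


def mean0(track: SignalTrack, interval: GenomicInterval) -> float:
    """Average signal over an interval with uncovered bases counted as 0.

    ``sum(value * covered_bases) / interval.length``. An interval on a
    chromosome the track does not cover returns 0 with a logged warning.
    """
    starts, ends, values = track.steps(interval.chrom)
    if starts.size == 0:
        logger.warning("mean0: chromosome %s absent from track", interval.chrom)
        return 0.0
    lo = np.clip(starts, interval.start, interval.end)
    hi = np.clip(ends, interval.start, interval.end)
    covered = np.maximum(hi - lo, 0)
    return float(np.sum(covered * values) / interval.length)


def genome_wide_mean(track: SignalTrack, genome_span: int | None = None) -> float:
    """Mean per-base signal: total signal over the genome span.

    When ``genome_span`` (sum of chromosome lengths) is not supplied the
    track's covered span is used instead.
    """
    span = genome_span if genome_span is not None else track.covered_span()
    if span <= 0:
        raise ValidationError("genome span must be positive")
    return track.total_signal() / span


def normalize_track(track: SignalTrack, target_total: float = 1e9) -> SignalTrack:
    """Linearly rescale a track so that sum(value * span) equals the target.

    Makes mean0 ratios between two normalized tracks invariant to each
    input's original sequencing depth.
    """
    total = track.total_signal()
    if total <= 0:
        raise ValidationError("cannot normalize a track with no signal")
    return track.scaled(target_total / total)


def classify_peaks(
    peaks: PeakSet,
    track_wt: SignalTrack,
    track_ko: SignalTrack,
    fold_cut: float = 2.0,
    pseudocount_frac: float = 0.05,
    genome_span: int | None = None,
) -> list[PeakSignalRecord]:
    """Classify peaks by WT/KO signal fold change.

    ``fold = (mean0_wt + eps) / (mean0_ko + eps)`` with
    ``eps = pseudocount_frac x genome-wide mean of the WT track``. A
    peak is ``down`` iff fold >= ``fold_cut`` (inclusive — "at least
    twofold"), ``up`` iff fold <= 1/``fold_cut``, else ``unchanged``.
    Tracks are expected to be depth-normalized beforehand.
    """
    eps = (
        pseudocount_frac * genome_wide_mean(track_wt, genome_span)
        if pseudocount_frac > 0
        else 0.0
    )
    records = []
    for p in peaks:
        m_wt = mean0(track_wt, p.interval)
        m_ko = mean0(track_ko, p.interval)
        fold = (m_wt + eps) / (m_ko + eps) if (m_ko + eps) > 0 else np.inf
        if fold >= fold_cut:
            klass = "down"
        elif fold <= 1.0 / fold_cut:
            klass = "up"
        else:
            klass = "unchanged"
        records.append(
            PeakSignalRecord(
                peak=p.name,
                mean0_wt=m_wt,
                mean0_ko=m_ko,
                fold=fold,
                log2_fold=float(np.log2(fold)) if np.isfinite(fold) and fold > 0 else np.nan,
                klass=klass,
            )
        )
    return records


def associate_peaks_to_genes(
    peaks: PeakSet, tss: TSSTable, window: int = 3000
) -> list[tuple[str, str]]:
    """Associate peaks with genes whose TSS lies within ``window`` bp.

    Distance is measured from the nearest peak edge (0 inside the peak)
    to the TSS point and the boundary is inclusive: distance exactly
    ``window`` associates. A peak may pair with several genes and vice
    versa; pairs are returned sorted and unique.
    """
    pairs: set[tuple[str, str]] = set()
    tss_by_chrom = tss.by_chrom()
    for p in peaks:
        sub = tss_by_chrom.get(p.interval.chrom)
        if sub is None:
            continue
        pos = sub["tss"].to_numpy()
        dist = np.maximum(np.maximum(p.interval.start - pos, pos - p.interval.end), 0)
        for gene in sub["gene"].to_numpy()[dist <= window]:
            pairs.add((p.name, str(gene)))
    return sorted(pairs)


def annotate_context(
    peaks: PeakSet, tss: TSSTable, gene_bodies: list[GenomicInterval]
) -> list[ContextAnnotation]:
    """Annotate each peak's genomic context relative to TSSs and gene bodies.

    Distance is peak center to nearest TSS. Categories, in fixed
    precedence: <=1 kb -> ``TSS±1kb``; <=10 kb -> ``1–10kb``; else
    ``>10kb intragenic`` when the center falls inside any gene body,
    otherwise ``>10kb intergenic``.
    """
    tss_by_chrom = tss.by_chrom()
    bodies_by_chrom: dict[str, list[GenomicInterval]] = {}
    for gb in gene_bodies:
        bodies_by_chrom.setdefault(gb.chrom, []).append(gb)
    out = []
    for p in peaks:
        center = p.interval.center
        sub = tss_by_chrom.get(p.interval.chrom)
        if sub is not None and len(sub):
            d = int(np.min(np.abs(sub["tss"].to_numpy() - center)))
        else:
            d = np.iinfo(np.int64).max
        if d <= 1000:
            cat = "TSS±1kb"
        elif d <= 10_000:
            cat = "1–10kb"
        else:
            inside = any(
                gb.start <= center < gb.end
                for gb in bodies_by_chrom.get(p.interval.chrom, [])
            )
            cat = ">10kb intragenic" if inside else ">10kb intergenic"
        out.append(ContextAnnotation(peak=p.name, tss_distance=d, category=cat))
    return out


def metaprofile(
    track: SignalTrack,
    peaks: PeakSet,
    half_window: int = 2000,
    bin_size: int = 50,
    chrom_sizes: dict[str, int] | None = None,
) -> MetaProfile:
    """Average signal profile in bins around peak centers.

    Each bin's value is the mean over peaks of mean0 on the bin interval
    centered on the peak midpoint. Peaks whose window would extend past
    a chromosome edge are dropped and counted in ``n_dropped``
    (right-edge drops require ``chrom_sizes``).
    """
    if (2 * half_window) % bin_size != 0:
        raise ValidationError("bin_size must divide 2 * half_window")
    n_bins = 2 * half_window // bin_size
    offsets = -half_window + bin_size * np.arange(n_bins) + bin_size / 2.0
    sums = np.zeros(n_bins)
    used = 0
    dropped = 0
    for p in peaks:
        center = p.interval.center
        left = center - half_window
        right = center + half_window
        if left < 0:
            dropped += 1
            continue
        if chrom_sizes is not None and right > chrom_sizes.get(p.interval.chrom, np.inf):
            dropped += 1
            continue
        for i in range(n_bins):
            iv = GenomicInterval(
                p.interval.chrom, left + i * bin_size, left + (i + 1) * bin_size
            )
            sums[i] += mean0(track, iv)
        used += 1
    if used == 0:
        raise ValidationError("no usable peaks for metaprofile")
    return MetaProfile(
        offsets=offsets, mean_signal=sums / used, n_peaks=used, n_dropped=dropped
    )


def chip_atac_correlation(
    chip_log2_folds: pd.Series, atac_log2_folds: pd.Series
) -> tuple[float, float]:
    """Spearman correlation between per-peak binding and accessibility changes.

    Both series are log2 fold changes over the same peak universe.
    """
    shared = chip_log2_folds.index.intersection(atac_log2_folds.index)
    if len(shared) < 10:
        raise ValidationError("need >= 10 shared peaks for correlation")
    return spearman(
        chip_log2_folds.loc[shared].to_numpy(), atac_log2_folds.loc[shared].to_numpy()
    )
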