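"""Replicate-consistent accessibility sites and uniform-change domains.

Per-replicate peak sets are union-merged into maximal sites; a site is
significant when every replicate contributes an overlapping FDR < 5%
peak. Per-site accessibility changes (each knockout vs wild type) are
tested with the differential stage; a site is changed-in-both when both
knockouts pass FDR < 5% with fold > 2 in either direction. Domains are
runs of consecutive significant sites spanning more than 100 kb, with
at least 5 sites of which at least 70% are changed in both knockouts;
overlapping qualifying windows merge into one reported domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import CountMatrix, GenomicInterval, PeakSet, SampleSheet, ValidationError
from .stats import bh_adjust, moderated_t_rows

__all__ = ["AtacSite", "DomainCall", "merge_replicate_peaks", "flag_site_changes", "find_domains"]


@dataclass
class AtacSite:
    """A merged accessibility site with replicate support and change flags."""

    site_id: str
    interval: GenomicInterval
    rep_support: list[bool]  # per replicate: contributes an overlapping peak?
    rep_min_fdr: list[float]  # per replicate: best fdr among its overlapping peaks
    significant: bool
    ko_log2_fold: dict[str, float] = field(default_factory=dict)
    ko_fdr: dict[str, float] = field(default_factory=dict)
    changed_in_both: bool = False


@dataclass
class DomainCall:
    interval: GenomicInterval
    n_sites: int
    n_changed: int
    fraction: float
    site_ids: list[str]


def merge_replicate_peaks(
    rep_peaksets: list[PeakSet], fdr_cut: float = 0.05
) -> list[AtacSite]:
    """Union-merge replicate peaks into maximal sites.

    Overlapping peaks across replicates collapse into one site whose
    footprint is the union interval; a site is significant iff every
    replicate contributes >= 1 overlapping peak with fdr < ``fdr_cut``.
    """
    n_reps = len(rep_peaksets)
    if n_reps < 2:
        raise ValidationError("site construction requires >= 2 replicates")
    tagged = []  # (chrom, start, end, rep index, fdr)
    for r, ps in enumerate(rep_peaksets):
        for p in ps:
            tagged.append((p.interval.chrom, p.interval.start, p.interval.end, r, p.fdr))
    tagged.sort(key=lambda t: (t[0], t[1], t[2]))
    sites: list[AtacSite] = []
    cluster: list[tuple[str, int, int, int, float | None]] = []

    def flush() -> None:
        if not cluster:
            return
        chrom = cluster[0][0]
        start = min(t[1] for t in cluster)
        end = max(t[2] for t in cluster)
        support = [False] * n_reps
        min_fdr = [np.nan] * n_reps
        for _, _, _, r, fdr in cluster:
            support[r] = True
            f = 1.0 if fdr is None else fdr
            if np.isnan(min_fdr[r]) or f < min_fdr[r]:
                min_fdr[r] = f
        significant = all(support) and all(f < fdr_cut for f in min_fdr)
        sites.append(
            AtacSite(
                site_id=f"site_{len(sites) + 1}",
                interval=GenomicInterval(chrom, start, end),
                rep_support=support,
                rep_min_fdr=min_fdr,
                significant=significant,
            )
        )

    cur_chrom, cur_end = None, -1
    for t in tagged:
        chrom, start, end = t[0], t[1], t[2]
        if chrom != cur_chrom or start >= cur_end:
            flush()
            cluster = [t]
            cur_chrom, cur_end = chrom, end
        else:
            cluster.append(t)
            cur_end = max(cur_end, end)
    flush()
    return sites


def flag_site_changes(
    sites: list[AtacSite],
    counts: CountMatrix,
    sheet: SampleSheet,
    ko_genotypes: tuple[str, ...] = ("DAXX_KO", "ATRX_KO"),
    fdr_cut: float = 0.05,
    fold_cut: float = 2.0,
    both_directions: bool = True,
) -> list[AtacSite]:
    """Attach per-knockout fold/FDR to sites and flag changed-in-both.

    ``counts`` rows are site ids, columns samples (one condition per
    genotype; treatment metadata is ignored here). Each knockout is
    compared to WT on log2(count + 1) with a variance-moderated t-test
    (variance shrunk across sites — the assay has two replicates per
    condition, too few for a stable per-site estimate), BH-corrected
    across sites per knockout. A site is changed iff fdr < ``fdr_cut``
    and the fold exceeds ``fold_cut`` strictly — with ``both_directions``
    the magnitude |log2 fold| must exceed log2(``fold_cut``), otherwise
    only losses count.
    """
    site_ids = [s.site_id for s in sites]
    missing = set(site_ids) - set(counts.genes)
    if missing:
        raise ValidationError(f"sites missing from count matrix: {sorted(missing)[:5]}")
    mat = np.log2(counts.data.loc[site_ids].to_numpy(dtype=np.float64) + 1.0)
    cols = counts.samples

    def genotype_cols(g: str) -> list[int]:
        df = sheet.data
        names = set(df[df["genotype"] == g]["sample"])
        idx = [i for i, c in enumerate(cols) if c in names]
        if len(idx) < 2:
            raise ValidationError(f"need >= 2 samples for genotype {g}")
        return idx

    wt_idx = genotype_cols("WT")
    log2_cut = np.log2(fold_cut)
    changed = np.ones(len(sites), dtype=bool)
    for ko in ko_genotypes:
        ko_idx = genotype_cols(ko)
        t, _, p = moderated_t_rows(mat[:, ko_idx], mat[:, wt_idx])
        fdr = bh_adjust(p)
        lfc = mat[:, ko_idx].mean(axis=1) - mat[:, wt_idx].mean(axis=1)
        if both_directions:
            passes = (fdr < fdr_cut) & (np.abs(lfc) > log2_cut)
        else:
            passes = (fdr < fdr_cut) & (lfc < -log2_cut)
        changed &= passes
        for s, f, l in zip(sites, fdr, lfc):
            s.ko_fdr[ko] = float(f)
            s.ko_log2_fold[ko] = float(l)
    for s, c in zip(sites, changed):
        s.changed_in_both = bool(c)
    return sites


def find_domains(
    sites: list[AtacSite],
    min_span: int = 100_000,
    min_sites: int = 5,
    min_frac: float = 0.7,
) -> list[DomainCall]:
    """Detect large domains of uniform accessibility change.

    Over each chromosome's significant sites (sorted by start), every
    window of consecutive sites i..j with footprint span strictly
    greater than ``min_span``, at least ``min_sites`` sites and a
    changed fraction of at least ``min_frac`` qualifies; overlapping
    qualifying windows are merged and each merged footprint is reported
    once with its statistics recomputed over the sites it contains.
    """
    sig = [s for s in sites if s.significant]
    by_chrom: dict[str, list[AtacSite]] = {}
    for s in sig:
        by_chrom.setdefault(s.interval.chrom, []).append(s)
    calls: list[DomainCall] = []
    for chrom in sorted(by_chrom):
        ss = sorted(by_chrom[chrom], key=lambda s: (s.interval.start, s.interval.end))
        n = len(ss)
        starts = np.array([s.interval.start for s in ss])
        ends = np.array([s.interval.end for s in ss])
        flags = np.array([s.changed_in_both for s in ss], dtype=np.int64)
        cum = np.concatenate([[0], np.cumsum(flags)])
        windows: list[tuple[int, int]] = []  # footprint [start, end)
        for i in range(n):
            # farthest end seen grows with j, so track the running max
            far_end = 0
            for j in range(i, n):
                far_end = max(far_end, int(ends[j]))
                count = j - i + 1
                if count < min_sites:
                    continue
                if far_end - int(starts[i]) <= min_span:
                    continue
                n_changed = int(cum[j + 1] - cum[i])
                if n_changed / count >= min_frac:
                    windows.append((int(starts[i]), far_end))
        if not windows:
            continue
        windows.sort()
        merged: list[list[int]] = []
        for s0, e0 in windows:
            if merged and s0 <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e0)
            else:
                merged.append([s0, e0])
        for s0, e0 in merged:
            members = [s for s in ss if s.interval.start >= s0 and s.interval.end <= e0]
            n_changed = sum(s.changed_in_both for s in members)
            calls.append(
                DomainCall(
                    interval=GenomicInterval(chrom, s0, e0),
                    n_sites=len(members),
                    n_changed=n_changed,
                    fraction=n_changed / len(members),
                    site_ids=[s.site_id for s in members],
                )
            )
    return calls
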