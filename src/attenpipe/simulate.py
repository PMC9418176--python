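"""Seeded generators for every pipeline input, with planted ground truth.

The generators emulate the statistical structure the analysis assumes:

* negative-binomial gene counts for a genotype x treatment design with a
  planted etoposide response in wild type and a planted, partially
  overlapping attenuation of that response in each knockout;
* non-overlapping peaks with plateau-shaped signal tracks whose
  knockout track scales planted "down" peaks by 1/fold and "up" peaks
  by fold, plus truncated Gaussian step noise;
* named factor peak sets overlapping down-flagged peaks at elevated
  odds (enriched factors) or uniformly (null factors);
* accessibility sites arranged into large (>100 kb) planted domains of
  uniform change, plus isolated background sites.

Randomness comes from one seed: each generator draws from its own
sub-stream derived with a fixed spawn key, so outputs are byte-identical
for a given config regardless of generator call order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    CountMatrix,
    GENOTYPES,
    GenomicInterval,
    Peak,
    PeakSet,
    SampleSheet,
    SignalTrack,
    ValidationError,
)

__all__ = ["SimConfig", "TruthTables", "AtacSim", "generate_counts",
           "generate_peaks_and_tracks", "generate_factor_sets", "generate_atac_sites",
           "generate_matched_atac_tracks", "generate_tss_table"]

# fixed sub-stream ids; changing these changes every downstream draw
_STREAM_COUNTS = 0
_STREAM_PEAKS = 1
_STREAM_FACTORS = 2
_STREAM_ATAC = 3
_STREAM_ATAC_TRACKS = 4
_STREAM_TSS = 5


@dataclass
class SimConfig:
    """All knobs for the synthetic inputs; defaults are the study conditions.

    Expression: ``n_genes`` genes, ``n_replicates`` per genotype x
    treatment cell, negative-binomial counts with Var = mu + alpha mu^2
    (``nb_dispersion`` = alpha). A fraction ``frac_responsive`` of genes
    gains ``response_log2fc`` (mean, sd) under etoposide in WT; a
    fraction ``frac_attenuated`` of genes (drawn from the responsive
    ones) retains only ``attenuation_retained_frac`` of that effect in
    the flagged knockout, with ``overlap_fraction`` of the attenuated
    sets shared between knockouts.

    Peaks/tracks: ``n_peaks`` non-overlapping peaks over ``genome``,
    class fractions over (down_in_KO, unchanged, up_in_KO), planted
    WT/KO ratio ``peak_fold`` for the down class, plateau signal split
    into ``track_step_bp`` steps with Gaussian noise ``track_noise_sd``
    truncated at zero.

    Accessibility: ``n_planted_domains`` regions of ``domain_span_bp``
    each carrying ``sites_per_domain`` sites changed in both knockouts,
    against ``n_atac_sites`` background sites changed at
    ``background_change_rate``; two replicates per condition, matching
    the assay's replicate design.
    """

    seed: int = 0
    # expression
    n_genes: int = 2000
    n_replicates: int = 3
    nb_dispersion: float = 0.05
    baseline_mean: float = 200.0
    frac_responsive: float = 0.2
    response_log2fc_mean: float = 2.0
    response_log2fc_sd: float = 0.5
    frac_attenuated: float = 0.1
    attenuation_retained_frac: float = 0.25
    overlap_fraction: float = 0.5
    # peaks and tracks
    genome: Sequence[tuple[str, int]] = (("chr1", 2_000_000), ("chr2", 2_000_000))
    n_peaks: int = 200
    peak_class_fracs: tuple[float, float, float] = (0.3, 0.6, 0.1)
    peak_fold: float = 4.0
    peak_width: int = 500
    track_step_bp: int = 50
    track_noise_sd: float = 0.1
    # factor sets
    n_factor_sets: int = 6
    factor_enrichment_odds: float = 6.0
    factor_base_rate: float = 0.2
    # accessibility sites and domains
    n_atac_sites: int = 40
    n_planted_domains: int = 2
    domain_span_bp: int = 150_000
    sites_per_domain: int = 8
    atac_site_width: int = 300
    atac_fold: float = 8.0
    atac_mean: float = 1000.0
    atac_dispersion: float = 0.01
    background_change_rate: float = 0.05
    frac_rep_inconsistent: float = 0.05
    n_atac_replicates: int = 2

    def __post_init__(self) -> None:
        fracs = self.peak_class_fracs
        if abs(sum(fracs) - 1.0) > 1e-9 or any(f < 0 for f in fracs):
            raise ValidationError("peak_class_fracs must be nonnegative and sum to 1")
        for name in ("frac_responsive", "frac_attenuated", "overlap_fraction",
                     "attenuation_retained_frac", "background_change_rate",
                     "factor_base_rate", "frac_rep_inconsistent"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.frac_attenuated > self.frac_responsive:
            raise ValidationError("frac_attenuated cannot exceed frac_responsive")
        if self.n_replicates < 2:
            raise ValidationError("n_replicates must be >= 2 (tests need variance)")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stream,))
        )


@dataclass
class TruthTables:
    """Planted ground truth, one table per generator."""

    genes: pd.DataFrame | None = None      # responsive, attenuated_*, response_log2fc
    peaks: pd.DataFrame | None = None      # class per peak
    factors: pd.DataFrame | None = None    # enriched per factor
    sites: pd.DataFrame | None = None      # changed_in_both, in_domain, significant
    domains: list[GenomicInterval] = field(default_factory=list)


@dataclass
class AtacSim:
    """Outputs of the accessibility-site generator."""

    rep_peaksets: dict[str, list[PeakSet]]  # condition -> per-replicate sets
    counts: CountMatrix                     # site x sample counts
    sheet: SampleSheet
    truth: TruthTables


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with Var = mu + alpha mu^2 (Poisson at alpha = 0)."""
    mean = np.asarray(mean, dtype=np.float64)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def generate_counts(config: SimConfig) -> tuple[CountMatrix, SampleSheet, TruthTables]:
    """Simulate the genotype x treatment x replicate count matrix.

    Counts are NB(mu_g * 2^effect, alpha): responsive genes gain their
    drawn log2 effect under etoposide; in a knockout where the gene is
    planted attenuated, the effect is multiplied by
    ``attenuation_retained_frac``.
    """
    rng = config.rng(_STREAM_COUNTS)
    n = config.n_genes
    genes = [f"gene_{i + 1}" for i in range(n)]
    base = config.baseline_mean * rng.lognormal(mean=0.0, sigma=0.7, size=n)

    n_resp = round(config.frac_responsive * n)
    responsive_idx = rng.choice(n, size=n_resp, replace=False)
    responsive = np.zeros(n, dtype=bool)
    responsive[responsive_idx] = True
    lfc = np.zeros(n)
    lfc[responsive_idx] = rng.normal(
        config.response_log2fc_mean, config.response_log2fc_sd, size=n_resp
    )

    n_att = round(config.frac_attenuated * n)
    n_shared = round(config.overlap_fraction * n_att)
    n_extra = n_att - n_shared
    if n_shared + 2 * n_extra > n_resp:
        raise ValidationError("attenuated sets do not fit inside the responsive set")
    pool = rng.permutation(responsive_idx)
    shared = pool[:n_shared]
    extra_daxx = pool[n_shared : n_shared + n_extra]
    extra_atrx = pool[n_shared + n_extra : n_shared + 2 * n_extra]
    att = {g: np.zeros(n, dtype=bool) for g in ("DAXX_KO", "ATRX_KO")}
    att["DAXX_KO"][np.concatenate([shared, extra_daxx]).astype(int)] = True
    att["ATRX_KO"][np.concatenate([shared, extra_atrx]).astype(int)] = True

    rows = []
    columns: dict[str, np.ndarray] = {}
    for genotype in GENOTYPES:
        for treatment in ("DMSO", "etoposide"):
            for rep in range(1, config.n_replicates + 1):
                sample = f"{genotype}_{treatment}_r{rep}"
                effect = np.zeros(n)
                if treatment == "etoposide":
                    effect = lfc.copy()
                    if genotype != "WT":
                        effect[att[genotype]] *= config.attenuation_retained_frac
                mu = base * np.exp2(effect)
                columns[sample] = _nb_draw(rng, mu, config.nb_dispersion)
                rows.append(
                    {"sample": sample, "genotype": genotype,
                     "treatment": treatment, "replicate": rep}
                )
    counts = CountMatrix(pd.DataFrame(columns, index=genes))
    sheet = SampleSheet(pd.DataFrame(rows))
    truth = TruthTables(
        genes=pd.DataFrame(
            {
                "responsive": responsive,
                "attenuated_in_DAXX": att["DAXX_KO"],
                "attenuated_in_ATRX": att["ATRX_KO"],
                "response_log2fc": lfc,
            },
            index=genes,
        )
    )
    return counts, sheet, truth


def generate_peaks_and_tracks(
    config: SimConfig,
) -> tuple[PeakSet, dict[str, SignalTrack], TruthTables]:
    """Simulate non-overlapping peaks and WT/KO plateau signal tracks.

    Peaks occupy disjoint 2 kb slots; the WT track carries a flat
    plateau of the peak's height across its footprint, the KO track
    scales down-class plateaus by 1/``peak_fold`` and up-class plateaus
    by ``peak_fold``. Plateaus are emitted as ``track_step_bp`` steps
    with iid Gaussian noise (sd ``track_noise_sd``) truncated at zero.
    """
    rng = config.rng(_STREAM_PEAKS)
    slot = 2000
    if config.peak_width > slot:
        raise ValidationError(f"peak_width must be <= {slot}")
    slots = []  # (chrom, slot_start)
    for chrom, length in config.genome:
        for s in range(0, length - slot + 1, slot):
            slots.append((chrom, s))
    if config.n_peaks > len(slots):
        raise ValidationError(
            f"cannot place {config.n_peaks} non-overlapping peaks in "
            f"{len(slots)} x {slot} bp slots"
        )
    chosen = rng.choice(len(slots), size=config.n_peaks, replace=False)
    jitter = rng.integers(0, slot - config.peak_width + 1, size=config.n_peaks)

    f_down, f_unch, f_up = config.peak_class_fracs
    n_down = round(f_down * config.n_peaks)
    n_up = round(f_up * config.n_peaks)
    classes = np.array(
        ["down"] * n_down + ["up"] * n_up + ["unchanged"] * (config.n_peaks - n_down - n_up)
    )
    rng.shuffle(classes)
    heights = rng.uniform(2.0, 8.0, size=config.n_peaks)

    placements = []
    for slot_i, jit, klass, h in zip(chosen, jitter, classes, heights):
        chrom, slot_start = slots[slot_i]
        start = slot_start + int(jit)
        placements.append((chrom, start, start + config.peak_width, klass, h))
    # name peaks in coordinate order so truth rows align with the sorted set
    placements.sort(key=lambda t: (t[0], t[1]))
    placements = [
        (chrom, start, end, f"peak_{i + 1}", klass, h)
        for i, (chrom, start, end, klass, h) in enumerate(placements)
    ]
    peaks = [
        Peak(GenomicInterval(chrom, start, end), name, score=float(h))
        for chrom, start, end, name, _klass, h in placements
    ]

    def build_track(scale_for) -> SignalTrack:
        steps: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, _name, klass, h in placements:
            level = h * scale_for(klass)
            for s in range(start, end, config.track_step_bp):
                e = min(s + config.track_step_bp, end)
                noise = rng.normal(0.0, config.track_noise_sd) if config.track_noise_sd > 0 else 0.0
                steps.setdefault(chrom, []).append((s, e, max(level + noise, 0.0)))
        return SignalTrack(steps)

    wt = build_track(lambda k: 1.0)
    ko = build_track(
        lambda k: {"down": 1.0 / config.peak_fold, "up": config.peak_fold, "unchanged": 1.0}[k]
    )
    names = [p[3] for p in placements]
    truth = TruthTables(
        peaks=pd.DataFrame({"class": [p[4] for p in placements]}, index=names)
    )
    return PeakSet("p53_peaks", peaks), {"WT": wt, "KO": ko}, truth


def generate_factor_sets(
    config: SimConfig, p53_peaks: PeakSet, down_flags: np.ndarray
) -> tuple[list[PeakSet], TruthTables]:
    """Simulate named factor peak sets with planted enrichment.

    The first half of the factors are enriched: they overlap down-flagged
    peaks with overlap odds ``factor_enrichment_odds`` times the base
    odds; null factors overlap every peak at ``factor_base_rate``. A
    factor's peak, when present, is a sub-interval of the target peak
    (guaranteeing >= 1 bp overlap).
    """
    rng = config.rng(_STREAM_FACTORS)
    down = np.asarray(down_flags, dtype=bool)
    if down.size != len(p53_peaks):
        raise ValidationError("down_flags length must match the peak set")
    p0 = config.factor_base_rate
    base_odds = p0 / (1.0 - p0)
    rich_odds = base_odds * config.factor_enrichment_odds
    p1 = rich_odds / (1.0 + rich_odds)
    n_enriched = config.n_factor_sets // 2
    factor_sets = []
    enriched_flags = []
    for k in range(config.n_factor_sets):
        enriched = k < n_enriched
        name = f"factor_{k + 1}"
        probs = np.where(down & enriched, p1, p0)
        hits = rng.random(len(p53_peaks)) < probs
        fpeaks = []
        for m, (p, hit) in enumerate(zip(p53_peaks, hits)):
            if not hit:
                continue
            iv = p.interval
            width = max(iv.length // 2, 50)
            start = iv.start + (iv.length - width) // 2
            fpeaks.append(
                Peak(GenomicInterval(iv.chrom, start, start + width), f"{name}_{m + 1}")
            )
        factor_sets.append(PeakSet(name, fpeaks))
        enriched_flags.append(enriched)
    truth = TruthTables(
        factors=pd.DataFrame(
            {"enriched": enriched_flags},
            index=[f"factor_{k + 1}" for k in range(config.n_factor_sets)],
        )
    )
    return factor_sets, truth


def generate_atac_sites(config: SimConfig) -> AtacSim:
    """Simulate replicate accessibility peak sets, site counts and domains.

    Planted domains are laid out on every chromosome except the last
    (which stays unstructured), each holding ``sites_per_domain``
    equally spaced sites all changed in both knockouts; background
    sites are scattered outside domains and changed at
    ``background_change_rate``. Counts for changed sites drop by
    ``atac_fold`` in both knockouts. A small fraction of background
    sites is emitted in replicate 1 only, so the replicate-consistency
    filter has something to reject.
    """
    rng = config.rng(_STREAM_ATAC)
    genome = list(config.genome)
    domain_chroms = [g[0] for g in genome[:-1]] or [genome[0][0]]
    chrom_len = dict(genome)
    width = config.atac_site_width

    records = []  # (chrom, start, end, changed, in_domain, rep_consistent)
    domains: list[GenomicInterval] = []
    margin = 50_000
    for d in range(config.n_planted_domains):
        chrom = domain_chroms[d % len(domain_chroms)]
        slot_on_chrom = d // len(domain_chroms)
        region_start = margin + slot_on_chrom * (config.domain_span_bp + 2 * margin)
        if region_start + config.domain_span_bp > chrom_len[chrom]:
            raise ValidationError("genome too small for the planted domains")
        spacing = (config.domain_span_bp - width) // max(config.sites_per_domain - 1, 1)
        for s in range(config.sites_per_domain):
            start = region_start + s * spacing
            records.append((chrom, start, start + width, True, True, True))
        domains.append(
            GenomicInterval(chrom, region_start, region_start + config.domain_span_bp)
        )

    # background sites: random slots well away from the planted regions
    bg_slot = 25_000
    candidates = []
    for chrom, length in genome:
        for s in range(0, length - bg_slot, bg_slot):
            mid = s + bg_slot // 2
            if any(d.chrom == chrom and d.start - bg_slot <= mid < d.end + bg_slot for d in domains):
                continue
            candidates.append((chrom, s))
    if config.n_atac_sites > len(candidates):
        raise ValidationError("genome too small for the requested background sites")
    picks = rng.choice(len(candidates), size=config.n_atac_sites, replace=False)
    changed_bg = rng.random(config.n_atac_sites) < config.background_change_rate
    inconsistent = rng.random(config.n_atac_sites) < config.frac_rep_inconsistent
    for i, pick in enumerate(picks):
        chrom, slot_start = candidates[pick]
        start = slot_start + int(rng.integers(0, bg_slot - width))
        records.append(
            (chrom, start, start + width, bool(changed_bg[i]), False, not inconsistent[i])
        )
    records.sort(key=lambda r: (r[0], r[1]))

    site_ids = [f"site_{i + 1}" for i in range(len(records))]
    conditions = list(GENOTYPES)
    rep_peaksets: dict[str, list[PeakSet]] = {c: [] for c in conditions}
    for cond in conditions:
        for rep in range(1, config.n_atac_replicates + 1):
            peaks = []
            for sid, (chrom, start, end, _ch, _dom, consistent) in zip(site_ids, records):
                if not consistent and rep > 1:
                    continue
                peaks.append(
                    Peak(GenomicInterval(chrom, start, end), f"{sid}_{cond}_r{rep}",
                         score=1.0, fdr=0.01)
                )
            rep_peaksets[cond].append(PeakSet(f"{cond}_rep{rep}", peaks))

    base_mean = config.atac_mean * rng.lognormal(0.0, 0.3, size=len(records))
    columns: dict[str, np.ndarray] = {}
    sheet_rows = []
    for cond in conditions:
        for rep in range(1, config.n_atac_replicates + 1):
            sample = f"{cond}_atac_r{rep}"
            mu = base_mean.copy()
            if cond != "WT":
                changed = np.array([r[3] for r in records])
                mu = np.where(changed, mu / config.atac_fold, mu)
            columns[sample] = _nb_draw(rng, mu, config.atac_dispersion)
            sheet_rows.append(
                {"sample": sample, "genotype": cond, "treatment": "etoposide",
                 "replicate": rep}
            )
    counts = CountMatrix(pd.DataFrame(columns, index=site_ids))
    sheet = SampleSheet(pd.DataFrame(sheet_rows))
    truth = TruthTables(
        sites=pd.DataFrame(
            {
                "chrom": [r[0] for r in records],
                "start": [r[1] for r in records],
                "end": [r[2] for r in records],
                "changed_in_both": [r[3] for r in records],
                "in_domain": [r[4] for r in records],
                "rep_consistent": [r[5] for r in records],
            },
            index=site_ids,
        ),
        domains=domains,
    )
    return AtacSim(rep_peaksets=rep_peaksets, counts=counts, sheet=sheet, truth=truth)


def generate_matched_atac_tracks(
    config: SimConfig, peaks: PeakSet, peak_truth: pd.DataFrame
) -> dict[str, SignalTrack]:
    """Accessibility tracks coupled to the planted peak classes.

    Emulates the coupling between binding loss and accessibility loss:
    over the same peak footprints, the knockout track scales down-class
    plateaus by 1/``atac_fold`` and up-class plateaus by ``atac_fold``,
    with the same step/noise scheme as the binding tracks but an
    independent noise stream.
    """
    rng = config.rng(_STREAM_ATAC_TRACKS)
    heights = rng.uniform(2.0, 8.0, size=len(peaks))

    def build(scale_for) -> SignalTrack:
        steps: dict[str, list[tuple[int, int, float]]] = {}
        for p, h in zip(peaks, heights):
            klass = str(peak_truth.loc[p.name, "class"])
            level = h * scale_for(klass)
            iv = p.interval
            for s in range(iv.start, iv.end, config.track_step_bp):
                e = min(s + config.track_step_bp, iv.end)
                noise = rng.normal(0.0, config.track_noise_sd) if config.track_noise_sd > 0 else 0.0
                steps.setdefault(iv.chrom, []).append((s, e, max(level + noise, 0.0)))
        return SignalTrack(steps)

    wt = build(lambda k: 1.0)
    ko = build(
        lambda k: {"down": 1.0 / config.atac_fold, "up": config.atac_fold, "unchanged": 1.0}[k]
    )
    return {"WT": wt, "KO": ko}


def generate_tss_table(config: SimConfig):
    """Random transcript start sites and gene bodies over the genome.

    One TSS per gene (gene ids match :func:`generate_counts`), placed
    uniformly; the gene body extends 20 kb downstream of the TSS on the
    drawn strand, clipped at chromosome edges.
    """
    from .core import TSSTable

    rng = config.rng(_STREAM_TSS)
    genome = list(config.genome)
    lengths = np.array([g[1] for g in genome], dtype=np.float64)
    chrom_idx = rng.choice(len(genome), size=config.n_genes, p=lengths / lengths.sum())
    rows = []
    bodies = []
    body_len = 20_000
    for i in range(config.n_genes):
        chrom, length = genome[chrom_idx[i]]
        tss = int(rng.integers(0, length))
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append({"gene": f"gene_{i + 1}", "chrom": chrom, "tss": tss, "strand": strand})
        if strand == "+":
            start, end = tss, min(tss + body_len, length)
        else:
            start, end = max(tss - body_len, 0), tss
        if end > start:
            bodies.append(GenomicInterval(chrom, start, end, strand))
    return TSSTable(pd.DataFrame(rows)), bodies
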