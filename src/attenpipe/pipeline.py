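"""End-to-end orchestration on synthetic inputs.

``run_pipeline`` drives simulate -> respond -> attenuate -> quantify /
classify -> associate / context -> enrich -> metaprofile -> domains ->
correlations, writes every stage output under an output directory, and
returns a :class:`RunReport` summarizing record counts, the headline
statistics and, because the inputs are simulated, recovery against the
planted truth.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .attenuation import attenuation_correlation, call_attenuated, set_overlap_enrichment
from .core import ValidationError
from .domains import find_domains, flag_site_changes, merge_replicate_peaks
from .enrichment import (
    average_linkage,
    binary_distance_matrix,
    dendrogram_to_newick,
    factor_enrichment,
    overlap_matrix,
)
from .io import write_bed, write_bedgraph, write_counts, write_sample_sheet, write_tss_table
from .peaksignal import (
    annotate_context,
    associate_peaks_to_genes,
    chip_atac_correlation,
    classify_peaks,
    metaprofile,
    normalize_track,
)
from .simulate import (
    SimConfig,
    generate_atac_sites,
    generate_counts,
    generate_factor_sets,
    generate_matched_atac_tracks,
    generate_peaks_and_tracks,
    generate_tss_table,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Thresholds and the simulation config for one pipeline run.

    Defaults are the analysis' stated cutoffs: FDR < 5% for response
    and enrichment calls, P < 0.05 for the attenuation comparison,
    twofold for peak signal change, 3 kb for peak-gene association,
    and >100 kb / >= 5 sites / >= 70% changed for domains.
    """

    sim: SimConfig = field(default_factory=SimConfig)
    outdir: str | Path = "attenpipe_out"
    fdr_cut: float = 0.05
    p_cut: float = 0.05
    fold_cut: float = 2.0
    pseudocount_frac: float = 0.05
    tss_window: int = 3000
    domain_min_span: int = 100_000
    domain_min_sites: int = 5
    domain_min_frac: float = 0.7
    metaprofile_half_window: int = 2000
    metaprofile_bin: int = 50
    cluster_cut_height: float = 0.5

    def __post_init__(self) -> None:
        for name in ("fdr_cut", "p_cut", "domain_min_frac"):
            if not 0.0 < getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} must lie in (0, 1]")
        if self.fold_cut < 1.0:
            raise ValidationError("fold_cut must be >= 1")

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        raw = dict(raw)
        sim_raw = raw.pop("sim", {})
        sim = SimConfig(**sim_raw) if isinstance(sim_raw, dict) else sim_raw
        known = {f.name for f in dataclasses.fields(cls)} - {"sim"}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(sim=sim, **raw)


@dataclass
class RunReport:
    """Serializable summary of one pipeline run."""

    version: str
    seed: int
    parameters: dict[str, Any]
    counts: dict[str, int]
    summary: dict[str, Any]
    recovery: dict[str, float]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _recovery(called: set[str], truth: set[str]) -> tuple[float, float]:
    """(sensitivity, precision) of a called set against a planted set."""
    tp = len(called & truth)
    sens = tp / len(truth) if truth else float("nan")
    prec = tp / len(called) if called else float("nan")
    return sens, prec


def run_pipeline(config: PipelineConfig) -> RunReport:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.sim
    stage_counts: dict[str, int] = {}
    summary: dict[str, Any] = {}
    recovery: dict[str, float] = {}

    def stage(name):
        logger.info("stage %s", name)
        return time.perf_counter()

    # --- expression: simulate, respond, attenuate --------------------------
    t0 = stage("simulate_counts")
    counts, sheet, gene_truth = generate_counts(sim)
    write_counts(counts, outdir / "counts.tsv")
    write_sample_sheet(sheet, outdir / "sample_sheet.tsv")
    gene_truth.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index_label="gene")
    stage_counts["genes"] = len(counts.genes)
    stage_counts["samples"] = len(counts.samples)

    stage("attenuate")
    calls = {}
    for ko in ("DAXX_KO", "ATRX_KO"):
        call = call_attenuated(
            counts, sheet, ko, fdr_cut=config.fdr_cut, p_cut=config.p_cut
        )
        call.table.to_csv(outdir / f"attenuation_{ko}.tsv", sep="\t", index_label="gene")
        calls[ko] = call
    calls["DAXX_KO"].wt_result.table.to_csv(
        outdir / "response_WT.tsv", sep="\t", index_label="gene"
    )
    set_daxx = calls["DAXX_KO"].attenuated
    set_atrx = calls["ATRX_KO"].attenuated
    universe = set(counts.genes)
    enr = set_overlap_enrichment(set_daxx, set_atrx, universe)
    rho, rho_p = attenuation_correlation(
        calls["DAXX_KO"].deltas, calls["ATRX_KO"].deltas
    )
    stage_counts["attenuated_DAXX_KO"] = len(set_daxx)
    stage_counts["attenuated_ATRX_KO"] = len(set_atrx)
    summary["wt_upregulated"] = len(calls["DAXX_KO"].wt_result.upregulated)
    summary["attenuation_overlap"] = enr.observed
    summary["attenuation_overlap_fold"] = enr.fold
    summary["attenuation_overlap_p"] = enr.p
    summary["attenuation_spearman_rho"] = rho
    summary["attenuation_spearman_p"] = rho_p
    tg = gene_truth.genes
    for ko, col in (("DAXX_KO", "attenuated_in_DAXX"), ("ATRX_KO", "attenuated_in_ATRX")):
        truth_set = set(tg.index[tg[col]])
        sens, prec = _recovery(calls[ko].attenuated, truth_set)
        recovery[f"attenuation_sensitivity_{ko}"] = sens
        recovery[f"attenuation_precision_{ko}"] = prec
    logger.info("expression stages done in %.1fs", time.perf_counter() - t0)

    # --- peaks, tracks, classification, association, context ---------------
    t0 = stage("peaks_and_tracks")
    peaks, tracks, peak_truth = generate_peaks_and_tracks(sim)
    write_bed(peaks, outdir / "peaks.bed")
    for cond, tr in tracks.items():
        write_bedgraph(tr, outdir / f"track_{cond}.bedgraph")
    peak_truth.peaks.to_csv(outdir / "truth_peaks.tsv", sep="\t", index_label="peak")
    genome_span = sum(length for _, length in sim.genome)
    norm_wt = normalize_track(tracks["WT"])
    norm_ko = normalize_track(tracks["KO"])
    records = classify_peaks(
        peaks, norm_wt, norm_ko,
        fold_cut=config.fold_cut,
        pseudocount_frac=config.pseudocount_frac,
        genome_span=genome_span,
    )
    class_df = pd.DataFrame(
        [dataclasses.asdict(r) for r in records]
    ).set_index("peak")
    class_df.to_csv(outdir / "peak_classes.tsv", sep="\t")
    stage_counts["peaks"] = len(peaks)
    stage_counts["peaks_down"] = int((class_df["klass"] == "down").sum())
    stage_counts["peaks_up"] = int((class_df["klass"] == "up").sum())
    agreement = float(
        (class_df["klass"] == peak_truth.peaks["class"].reindex(class_df.index)).mean()
    )
    recovery["peak_class_agreement"] = agreement

    tss, gene_bodies = generate_tss_table(sim)
    write_tss_table(tss, outdir / "tss.tsv")
    pairs = associate_peaks_to_genes(peaks, tss, window=config.tss_window)
    pd.DataFrame(pairs, columns=["peak", "gene"]).to_csv(
        outdir / "peak_gene_associations.tsv", sep="\t", index=False
    )
    stage_counts["peak_gene_pairs"] = len(pairs)
    context = annotate_context(peaks, tss, gene_bodies)
    ctx_df = pd.DataFrame([dataclasses.asdict(c) for c in context]).set_index("peak")
    ctx_df.to_csv(outdir / "peak_context.tsv", sep="\t")
    summary["context_counts"] = ctx_df["category"].value_counts().to_dict()
    logger.info("peak stages done in %.1fs", time.perf_counter() - t0)

    # --- factor-overlap enrichment -----------------------------------------
    t0 = stage("enrich")
    down_truth = (
        peak_truth.peaks["class"].reindex([p.name for p in peaks]) == "down"
    ).to_numpy()
    factors, factor_truth = generate_factor_sets(sim, peaks, down_truth)
    factor_truth.factors.to_csv(outdir / "truth_factors.tsv", sep="\t", index_label="factor")
    mat = overlap_matrix(peaks, factors)
    down_called = (class_df["klass"].reindex([p.name for p in peaks]) == "down").to_numpy()
    rows = factor_enrichment(mat, down_called, fdr_cut=config.fdr_cut)
    enr_df = pd.DataFrame([dataclasses.asdict(r) for r in rows]).set_index("factor")
    enr_df.to_csv(outdir / "factor_enrichment.tsv", sep="\t")
    stage_counts["factors"] = len(rows)
    stage_counts["factors_significant"] = int(enr_df["significant"].sum())
    sig_factors = list(enr_df.index[enr_df["significant"]])
    if len(sig_factors) >= 2:
        dist = binary_distance_matrix(mat.loc[sig_factors])
        z, flat = average_linkage(dist, cut_height=config.cluster_cut_height)
        (outdir / "factor_dendrogram.nwk").write_text(
            dendrogram_to_newick(z, sig_factors) + "\n"
        )
        summary["factor_clusters_at_cut"] = int(flat.nunique())
    truth_enriched = set(
        factor_truth.factors.index[factor_truth.factors["enriched"]]
    )
    sens, prec = _recovery(set(sig_factors), truth_enriched)
    recovery["factor_enrichment_sensitivity"] = sens
    recovery["factor_enrichment_precision"] = prec
    logger.info("enrichment done in %.1fs", time.perf_counter() - t0)

    # --- accessibility: metaprofile, correlation, sites, domains -----------
    t0 = stage("domains")
    atac_tracks = generate_matched_atac_tracks(sim, peaks, peak_truth.peaks)
    prof = metaprofile(
        normalize_track(atac_tracks["WT"]), peaks,
        half_window=config.metaprofile_half_window, bin_size=config.metaprofile_bin,
    )
    pd.DataFrame({"offset": prof.offsets, "mean_signal": prof.mean_signal}).to_csv(
        outdir / "metaprofile.tsv", sep="\t", index=False
    )
    atac_records = classify_peaks(
        peaks, normalize_track(atac_tracks["WT"]), normalize_track(atac_tracks["KO"]),
        fold_cut=config.fold_cut, pseudocount_frac=config.pseudocount_frac,
        genome_span=genome_span,
    )
    chip_folds = class_df["log2_fold"]
    atac_folds = pd.Series(
        {r.peak: r.log2_fold for r in atac_records}, name="atac_log2_fold"
    )
    rho_ca, rho_ca_p = chip_atac_correlation(chip_folds, atac_folds)
    summary["chip_atac_spearman_rho"] = rho_ca
    summary["chip_atac_spearman_p"] = rho_ca_p

    atac = generate_atac_sites(sim)
    atac.truth.sites.to_csv(outdir / "truth_atac_sites.tsv", sep="\t", index_label="site")
    write_counts(atac.counts, outdir / "atac_site_counts.tsv")
    all_rep_sets = [ps for cond in sorted(atac.rep_peaksets) for ps in atac.rep_peaksets[cond]]
    sites = merge_replicate_peaks(all_rep_sets, fdr_cut=config.fdr_cut)
    sites = flag_site_changes(
        sites, atac.counts, atac.sheet,
        fdr_cut=config.fdr_cut, fold_cut=config.fold_cut,
    )
    site_df = pd.DataFrame(
        {
            "chrom": [s.interval.chrom for s in sites],
            "start": [s.interval.start for s in sites],
            "end": [s.interval.end for s in sites],
            "significant": [s.significant for s in sites],
            "changed_in_both": [s.changed_in_both for s in sites],
        },
        index=[s.site_id for s in sites],
    )
    site_df.to_csv(outdir / "atac_sites.tsv", sep="\t", index_label="site")
    domains = find_domains(
        sites,
        min_span=config.domain_min_span,
        min_sites=config.domain_min_sites,
        min_frac=config.domain_min_frac,
    )
    dom_df = pd.DataFrame(
        [
            {
                "chrom": d.interval.chrom, "start": d.interval.start,
                "end": d.interval.end, "n_sites": d.n_sites,
                "n_changed": d.n_changed, "fraction": d.fraction,
            }
            for d in domains
        ]
    )
    dom_df.to_csv(outdir / "domains.tsv", sep="\t", index=False)
    stage_counts["atac_sites"] = len(sites)
    stage_counts["atac_sites_significant"] = int(site_df["significant"].sum())
    stage_counts["domains"] = len(domains)
    planted = atac.truth.domains
    recovered = sum(
        any(d.interval.overlaps(p) for d in domains) for p in planted
    )
    recovery["domain_recall"] = recovered / len(planted) if planted else float("nan")
    structured = {p.chrom for p in planted}
    false_doms = sum(d.interval.chrom not in structured for d in domains)
    stage_counts["domains_on_unstructured_chroms"] = false_doms
    logger.info("accessibility stages done in %.1fs", time.perf_counter() - t0)

    report = RunReport(
        version=__version__,
        seed=sim.seed,
        parameters={
            **{f"sim.{k}": v for k, v in dataclasses.asdict(sim).items()},
            "fdr_cut": config.fdr_cut,
            "p_cut": config.p_cut,
            "fold_cut": config.fold_cut,
            "tss_window": config.tss_window,
            "domain_min_span": config.domain_min_span,
            "domain_min_sites": config.domain_min_sites,
            "domain_min_frac": config.domain_min_frac,
        },
        counts=stage_counts,
        summary=summary,
        recovery=recovery,
    )
    (outdir / "report.json").write_text(report.to_json() + "\n")
    return report
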