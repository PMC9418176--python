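"""Normalization and per-gene treatment-response significance.

This stage calls, per genotype, which genes respond to etoposide: counts
are normalized by median-of-ratios size factors, per-replicate response
values ``r = log2((eto + 1) / (dmso + 1))`` are formed with replicates
paired by index, and each gene's response is tested against zero with
Welch's t-test, BH-corrected across genes. It is a deliberately
self-contained, formula-level-testable differential stage; a
shrinkage-based GLM (e.g. DESeq2-style) could be plugged in behind the
same interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CountMatrix, SampleSheet, ValidationError
from .stats import bh_adjust, welch_test_rows

__all__ = [
    "SizeFactors",
    "ResponseResult",
    "size_factors",
    "normalize_counts",
    "response_values",
    "call_response",
]


@dataclass
class SizeFactors:
    """Per-sample positive scale factors (median-of-ratios)."""

    factors: pd.Series

    def __post_init__(self) -> None:
        if (self.factors <= 0).any() or not np.isfinite(self.factors).all():
            raise ValidationError("size factors must be positive and finite")


@dataclass
class ResponseResult:
    """Per-gene etoposide-vs-DMSO response for one genotype.

    ``table`` columns: gene (index), ``log2fc`` (mean per-replicate
    response), ``t``, ``p``, ``fdr``, ``mean_dmso``, ``mean_eto``
    (mean normalized counts per treatment), ``called`` (upregulated at
    the FDR cut).
    """

    genotype: str
    table: pd.DataFrame
    responses: pd.DataFrame  # genes x replicates per-replicate log2 responses

    @property
    def upregulated(self) -> set[str]:
        return set(self.table.index[self.table["called"]])


def size_factors(counts: CountMatrix) -> SizeFactors:
    """Median-of-ratios size factors.

    For each sample s, ``factor_s = median_g count[g, s] / geomean_g``
    over genes whose geometric mean across samples is positive.
    """
    mat = counts.data.to_numpy(dtype=np.float64)
    with np.errstate(divide="ignore"):
        logs = np.log(mat)
    all_positive = np.all(mat > 0, axis=1)
    if not all_positive.any():
        raise ValidationError("no gene has nonzero counts in every sample")
    geomean = np.exp(logs[all_positive].mean(axis=1))
    ratios = mat[all_positive] / geomean[:, None]
    factors = np.median(ratios, axis=0)
    return SizeFactors(pd.Series(factors, index=counts.samples))


def normalize_counts(counts: CountMatrix, factors: SizeFactors) -> pd.DataFrame:
    """Counts divided by their sample's size factor (float-valued frame)."""
    return counts.data.div(factors.factors, axis=1)


def response_values(
    norm: pd.DataFrame, sheet: SampleSheet, genotype: str
) -> pd.DataFrame:
    """Per-gene, per-replicate log2 treatment response for one genotype.

    Replicates are paired by index across treatments:
    ``r = log2((norm_eto + 1) / (norm_dmso + 1))``. Unpaired replicate
    indices are rejected rather than silently averaged.
    """
    reps_d = sheet.replicates_for(genotype, "DMSO")
    reps_e = sheet.replicates_for(genotype, "etoposide")
    if reps_d != reps_e or not reps_d:
        raise ValidationError(
            f"{genotype}: replicate indices differ between treatments "
            f"(DMSO {reps_d}, etoposide {reps_e})"
        )
    dmso = sheet.samples_for(genotype, "DMSO")
    eto = sheet.samples_for(genotype, "etoposide")
    r = np.log2((norm[eto].to_numpy() + 1.0) / (norm[dmso].to_numpy() + 1.0))
    return pd.DataFrame(r, index=norm.index, columns=[f"rep{i}" for i in reps_d])


def call_response(
    counts: CountMatrix,
    sheet: SampleSheet,
    genotype: str,
    fdr_cut: float = 0.05,
    factors: SizeFactors | None = None,
) -> ResponseResult:
    """Call genes upregulated by etoposide in one genotype.

    A gene is called iff its BH-adjusted p-value is strictly below
    ``fdr_cut`` and its mean response is positive. The test is Welch's
    t on per-replicate paired log2 responses between treatments — i.e.
    etoposide vs DMSO normalized counts on the log scale.
    """
    sheet.validate_against(counts)
    if factors is None:
        factors = size_factors(counts)
    norm = normalize_counts(counts, factors)
    dmso = sheet.samples_for(genotype, "DMSO")
    eto = sheet.samples_for(genotype, "etoposide")
    log_d = np.log2(norm[dmso].to_numpy() + 1.0)
    log_e = np.log2(norm[eto].to_numpy() + 1.0)
    t, _, p = welch_test_rows(log_e, log_d)
    fdr = bh_adjust(p)
    resp = response_values(norm, sheet, genotype)
    log2fc = resp.mean(axis=1).to_numpy()
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "t": t,
            "p": p,
            "fdr": fdr,
            "mean_dmso": norm[dmso].mean(axis=1),
            "mean_eto": norm[eto].mean(axis=1),
        },
        index=norm.index,
    )
    table["called"] = (table["fdr"] < fdr_cut) & (table["log2fc"] > 0)
    return ResponseResult(genotype=genotype, table=table, responses=resp)
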