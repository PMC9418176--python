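"""Attenuated-response gene calling and between-knockout overlap statistics.

An attenuated gene is one that is upregulated by etoposide in wild-type
cells (FDR < 5%) but significantly less upregulated in a knockout
(P < 0.05, with the knockout's point estimate below the wild-type's).
The overlap of the two knockouts' attenuated sets is scored against a
gene universe with a fold-over-expectation and a two-sided Fisher exact
p-value, and the per-gene attenuation magnitudes of the two knockouts
are compared by Spearman correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CountMatrix, SampleSheet, ValidationError
from .diffexpr import (
    ResponseResult,
    SizeFactors,
    call_response,
    normalize_counts,
    response_values,
    size_factors,
)
from .stats import fisher_exact_two_sided, moderated_t_rows, spearman, welch_test_rows

__all__ = [
    "AttenuationCall",
    "OverlapEnrichment",
    "call_attenuated",
    "set_overlap_enrichment",
    "attenuation_correlation",
]


@dataclass
class AttenuationCall:
    """Per-gene attenuation calls for one knockout vs wild type.

    ``table`` columns: ``wt_up``, ``wt_response``, ``ko_response``,
    ``delta`` (WT − KO response), ``less_up_p`` (two-sided Welch p for
    the WT-vs-KO response comparison), ``attenuated``.
    """

    ko_genotype: str
    table: pd.DataFrame
    wt_result: ResponseResult
    ko_result: ResponseResult

    @property
    def attenuated(self) -> set[str]:
        return set(self.table.index[self.table["attenuated"]])

    @property
    def deltas(self) -> pd.Series:
        """Per-gene attenuation magnitude: WT response − KO response."""
        return self.table["delta"]


@dataclass
class OverlapEnrichment:
    """Fold and Fisher p for the overlap of two gene sets in a universe."""

    size_a: int
    size_b: int
    observed: int
    universe: int
    expected: float
    fold: float
    p: float


def call_attenuated(
    counts: CountMatrix,
    sheet: SampleSheet,
    ko_genotype: str,
    fdr_cut: float = 0.05,
    p_cut: float = 0.05,
    factors: SizeFactors | None = None,
    wt_result: ResponseResult | None = None,
    moderation_prior_df: float | None = 20.0,
) -> AttenuationCall:
    """Call genes whose etoposide response is attenuated in a knockout.

    A gene is attenuated iff (i) it is in the wild-type upregulated set
    (FDR < ``fdr_cut``), (ii) the WT-vs-KO comparison of per-replicate
    response values gives two-sided p < ``p_cut``, and (iii) the mean
    KO response is below the mean WT response. Direction is enforced by
    the point-estimate condition rather than a one-sided p.

    The comparison shrinks per-gene variances toward the across-gene
    mean with ``moderation_prior_df`` pseudo-degrees of freedom —
    designs with three or four replicates give noisy per-gene variance
    estimates, and sharing information across genes is how count-based
    differential tools handle this. Pass ``None`` for a plain
    unmoderated Welch comparison.
    """
    if ko_genotype == "WT":
        raise ValidationError("ko_genotype must be a knockout, not WT")
    sheet.validate_against(counts)
    if factors is None:
        factors = size_factors(counts)
    norm = normalize_counts(counts, factors)
    if wt_result is None:
        wt_result = call_response(counts, sheet, "WT", fdr_cut=fdr_cut, factors=factors)
    ko_result = call_response(counts, sheet, ko_genotype, fdr_cut=fdr_cut, factors=factors)
    resp_wt = response_values(norm, sheet, "WT")
    resp_ko = response_values(norm, sheet, ko_genotype)
    if moderation_prior_df is None:
        _, _, p = welch_test_rows(resp_wt.to_numpy(), resp_ko.to_numpy())
    else:
        _, _, p = moderated_t_rows(
            resp_wt.to_numpy(), resp_ko.to_numpy(), prior_df=moderation_prior_df
        )
    wt_mean = resp_wt.mean(axis=1)
    ko_mean = resp_ko.mean(axis=1)
    table = pd.DataFrame(
        {
            "wt_up": wt_result.table["called"],
            "wt_response": wt_mean,
            "ko_response": ko_mean,
            "delta": wt_mean - ko_mean,
            "less_up_p": p,
        },
        index=norm.index,
    )
    table["attenuated"] = (
        table["wt_up"] & (table["less_up_p"] < p_cut) & (table["ko_response"] < table["wt_response"])
    )
    return AttenuationCall(
        ko_genotype=ko_genotype, table=table, wt_result=wt_result, ko_result=ko_result
    )


def set_overlap_enrichment(
    set_a: set[str], set_b: set[str], universe: set[str]
) -> OverlapEnrichment:
    """Fold over chance and Fisher exact p for the overlap of two sets.

    The 2x2 table partitions the universe into A∩B, A\\B, B\\A and
    neither; ``expected = |A||B|/N`` and ``fold = observed / expected``.
    """
    if not universe:
        raise ValidationError("universe must be non-empty")
    if not set_a <= universe or not set_b <= universe:
        raise ValidationError("sets must be subsets of the universe")
    n = len(universe)
    a = len(set_a & set_b)
    b = len(set_a - set_b)
    c = len(set_b - set_a)
    d = n - a - b - c
    _, p = fisher_exact_two_sided(a, b, c, d)
    expected = len(set_a) * len(set_b) / n
    fold = a / expected if expected > 0 else np.nan
    return OverlapEnrichment(
        size_a=len(set_a),
        size_b=len(set_b),
        observed=a,
        universe=n,
        expected=expected,
        fold=fold,
        p=p,
    )


def attenuation_correlation(
    deltas_a: pd.Series, deltas_b: pd.Series
) -> tuple[float, float]:
    """Spearman correlation of per-gene attenuation magnitudes of two KOs.

    The magnitudes are the per-gene WT-minus-KO response differences;
    the two series must share a gene universe of at least 10 genes.
    """
    shared = deltas_a.index.intersection(deltas_b.index)
    if len(shared) < 10:
        raise ValidationError("need >= 10 shared genes for correlation")
    return spearman(deltas_a.loc[shared].to_numpy(), deltas_b.loc[shared].to_numpy())
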