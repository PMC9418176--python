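"""Shared statistical primitives: Welch's test, BH adjustment, Fisher's
exact test, and Spearman correlation.

The Fisher two-sided p-value is computed by direct summation of the
hypergeometric probabilities of all tables (at the observed margins)
whose probability does not exceed the observed table's — the textbook
definition of the two-sided exact test — vectorized via log-gamma so
that large sweeps stay cheap.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .core import ValidationError

__all__ = [
    "welch_test",
    "welch_test_rows",
    "moderated_t_rows",
    "bh_adjust",
    "fisher_exact_two_sided",
    "spearman",
]

# relative slack when comparing hypergeometric masses for "as or more
# extreme"; guards against float round-off flipping ties
_REL_TIE_EPS = 1e-7


def welch_test(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test, two-sided.

    Returns ``(t, df, p)`` with the Welch–Satterthwaite degrees of
    freedom; ``t > 0`` when ``mean(a) > mean(b)``. Degenerate inputs
    follow documented conventions: both samples with zero variance and
    equal means give ``t = 0, p = 1``; zero pooled variance with unequal
    means gives ``t = ±inf, p = 0``.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValidationError("welch_test requires >= 2 observations per group")
    t, df, p = welch_test_rows(a[None, :], b[None, :])
    return float(t[0]), float(df[0]), float(p[0])


def welch_test_rows(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise Welch's test for (n_rows, n_obs) arrays; returns (t, df, p)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValidationError("welch_test requires >= 2 observations per group")
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    sa, sb = va / na, vb / nb
    denom = np.sqrt(sa + sb)
    diff = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
        df = (sa + sb) ** 2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
    zero_var = denom == 0
    equal_means = np.isclose(diff, 0.0)
    t = np.where(zero_var & equal_means, 0.0, t)
    with np.errstate(invalid="ignore"):
        t = np.where(zero_var & ~equal_means, np.sign(diff) * np.inf, t)
    df = np.where(zero_var, 1.0, df)
    p = 2.0 * sps.t.sf(np.abs(t), df)
    p = np.where(zero_var & equal_means, 1.0, p)
    p = np.where(zero_var & ~equal_means, 0.0, p)
    return t, df, np.clip(p, 0.0, 1.0)


def moderated_t_rows(
    a: np.ndarray, b: np.ndarray, prior_df: float = 20.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise two-sample t with variance shrunk across rows.

    For designs with very few replicates per group the per-row pooled
    variance is an unstable estimate; borrowing strength across rows —
    the idea behind moderated differential tests — stabilizes it. Each
    row's pooled within-group variance ``s2`` (``d = na + nb - 2`` df)
    is shrunk toward the across-row mean variance ``s2_0`` with
    ``prior_df`` pseudo-degrees of freedom:

        s2_mod = (prior_df * s2_0 + d * s2) / (prior_df + d)

    and the t statistic is referred to a t distribution with
    ``prior_df + d`` degrees of freedom. Returns ``(t, df, p)``.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValidationError("moderated test requires >= 2 observations per group")
    d = na + nb - 2
    ss = a.var(axis=1, ddof=1) * (na - 1) + b.var(axis=1, ddof=1) * (nb - 1)
    s2 = ss / d
    s2_0 = float(s2.mean())
    s2_mod = (prior_df * s2_0 + d * s2) / (prior_df + d)
    se = np.sqrt(s2_mod * (1.0 / na + 1.0 / nb))
    diff = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    df = np.full_like(t, prior_df + d)
    zero = se == 0
    t = np.where(zero & np.isclose(diff, 0.0), 0.0, t)
    with np.errstate(invalid="ignore"):
        t = np.where(zero & ~np.isclose(diff, 0.0), np.sign(diff) * np.inf, t)
    p = 2.0 * sps.t.sf(np.abs(t), df)
    p = np.where(zero & np.isclose(diff, 0.0), 1.0, p)
    return t, df, np.clip(p, 0.0, 1.0)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, clipped at 1."""
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _log_hypergeom_pmf(k: np.ndarray, N: int, K: int, n: int) -> np.ndarray:
    # log C(K, k) + log C(N-K, n-k) - log C(N, n)
    def logC(nn, kk):
        return gammaln(nn + 1) - gammaln(kk + 1) - gammaln(nn - kk + 1)

    return logC(K, k) + logC(N - K, n - k) - logC(N, n)


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    Returns ``(odds_ratio, p)``. The p-value sums hypergeometric
    probabilities of all tables with the observed margins whose mass is
    at most the observed table's (two-sided by probability mass). The
    odds ratio is the sample odds ratio ``ad / bc`` (``inf`` when
    ``bc = 0`` and ``ad > 0``; callers wanting finite reporting apply a
    Haldane correction themselves).
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValidationError("table cells must be nonnegative integers")
    N = a + b + c + d
    if N == 0:
        return np.nan, 1.0
    K = a + b  # row-1 total
    n = a + c  # col-1 total
    lo, hi = max(0, n + K - N), min(n, K)
    support = np.arange(lo, hi + 1)
    logpmf = _log_hypergeom_pmf(support, N, K, n)
    pmf = np.exp(logpmf - logpmf.max())
    obs = pmf[a - lo]
    p = float(pmf[pmf <= obs * (1.0 + _REL_TIE_EPS)].sum() / pmf.sum())
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = (a * d) / (b * c)
    return odds, min(p, 1.0)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) and its p-value."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValidationError("vectors must share length")
    if x.size < 10:
        raise ValidationError("spearman requires >= 10 observations")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)
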