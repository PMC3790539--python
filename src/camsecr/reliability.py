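"""Interobserver-agreement statistics for individual-identification tests.

Participants judge pairs of video stills as "same" or "different"
individual; agreement with the expert gold standard is summarised by
Cohen's kappa.  Differences between participant categories are compared
with exact Wilcoxon signed-ranks matched-pairs tests (small samples, so
the null distribution of the positive-rank sum is enumerated exactly),
and differences between species with tie-corrected Friedman tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2, norm, rankdata

from .datamodel import ParameterError

__all__ = [
    "KappaResult", "TestResult", "cohens_kappa",
    "wilcoxon_signed_rank_exact", "friedman_test", "chi2_upper_tail",
]

#: above this many nonzero differences the exact Wilcoxon enumeration is
#: replaced by the usual normal approximation (flagged on the result).
EXACT_WILCOXON_MAX_N = 25


@dataclass
class KappaResult:
    kappa: float
    po: float          # observed agreement
    pe: float          # chance agreement from the marginals
    n: int


@dataclass
class TestResult:
    name: str
    statistic: float
    n: int | None
    df: int | None
    p_value: float
    exact: bool
    n_zeros_dropped: int = 0


def cohens_kappa(a, b) -> KappaResult:
    """Cohen's kappa for two binary judgment vectors.

    kappa = (po - pe) / (1 - pe) with pe the chance agreement implied by
    the raters' marginal frequencies.  When both raters are constant and
    identical, agreement is perfect but pe = 1; kappa is defined as 1.
    """
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.shape != b.shape or len(a) == 0:
        raise ParameterError("judgment vectors must be equal length >= 1")
    vals = np.unique(np.concatenate([a, b]))
    if len(vals) > 2:
        raise ParameterError("kappa here is for binary judgments")
    po = float(np.mean(a == b))
    pe = 0.0
    for v in vals:
        pe += float(np.mean(a == v)) * float(np.mean(b == v))
    if pe >= 1.0:
        if po == 1.0:
            return KappaResult(kappa=1.0, po=po, pe=pe, n=len(a))
        raise ParameterError("chance agreement is 1 but observed is not")
    return KappaResult(kappa=(po - pe) / (1.0 - pe), po=po, pe=pe, n=len(a))


def _signed_rank_distribution(double_ranks: np.ndarray) -> np.ndarray:
    """Exact null distribution of the positive-rank sum.

    ``double_ranks`` are mid-ranks times two (integers even with ties).
    Returns counts over T+ (on the doubled scale) across all 2^n equally
    likely sign assignments, via the standard generating-polynomial
    convolution — numerically identical to full enumeration.
    """
    total = int(double_ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in double_ranks.astype(int):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank_exact(diffs) -> TestResult:
    """Exact two-sided Wilcoxon signed-ranks test on paired differences.

    Zero differences are dropped (their count is reported); tied absolute
    differences receive mid-ranks.  The statistic is T+, the sum of ranks
    of positive differences.  For n <= 25 the two-sided p-value doubles
    the smaller exact tail (capped at 1); larger n fall back to the
    normal approximation with tie correction.
    """
    d = np.asarray(diffs, dtype=float).ravel()
    if len(d) == 0:
        raise ParameterError("no differences supplied")
    nz = d[d != 0]
    n_zeros = len(d) - len(nz)
    if len(nz) == 0:
        raise ParameterError("all differences are zero; test undefined")
    ranks = rankdata(np.abs(nz))
    t_plus = float(ranks[nz > 0].sum())
    n = len(nz)
    if n <= EXACT_WILCOXON_MAX_N:
        dr = np.round(2 * ranks).astype(int)
        counts = _signed_rank_distribution(dr)
        total = counts.sum()
        obs = int(round(2 * t_plus))
        p_ge = counts[obs:].sum() / total
        p_le = counts[: obs + 1].sum() / total
        p = min(1.0, 2.0 * min(p_ge, p_le))
        exact = True
    else:
        mu = n * (n + 1) / 4.0
        var = ranks @ ranks / 4.0          # sum r_i^2 / 4, tie-safe
        z = (t_plus - mu) / np.sqrt(var)
        p = float(min(1.0, 2.0 * norm.sf(abs(z))))
        exact = False
    return TestResult(
        name="wilcoxon_signed_rank", statistic=t_plus, n=n, df=None,
        p_value=float(p), exact=exact, n_zeros_dropped=n_zeros,
    )


def friedman_test(scores) -> TestResult:
    """Tie-corrected Friedman test on a blocks x treatments score matrix.

    Scores are mid-ranked within each block; the chi-square statistic
    uses the general tie-corrected form and is referred to the
    chi-square distribution with k - 1 degrees of freedom.
    """
    x = np.asarray(scores, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ParameterError("need a 2-D matrix with >=2 blocks and >=2 treatments")
    n, k = x.shape
    r = np.vstack([rankdata(row) for row in x])
    Rj = r.sum(axis=0)
    num = (k - 1) * ((Rj - n * (k + 1) / 2.0) ** 2).sum()
    den = (r ** 2).sum() - n * k * (k + 1) ** 2 / 4.0
    if den <= 0:
        # every block ranks all treatments equal: no information
        return TestResult(name="friedman", statistic=0.0, n=n, df=k - 1,
                          p_value=1.0, exact=False)
    stat = num / den
    return TestResult(
        name="friedman", statistic=float(stat), n=n, df=k - 1,
        p_value=chi2_upper_tail(stat, k - 1), exact=False,
    )


def chi2_upper_tail(x: float, df: int) -> float:
    """Survival function of the chi-square distribution (for df = 2 this
    is exp(-x/2))."""
    if x < 0:
        raise ParameterError("statistic must be non-negative")
    if df < 1:
        raise ParameterError("df must be >= 1")
    return float(chi2.sf(x, df))
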