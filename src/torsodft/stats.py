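"""Paired nonparametric statistics for cohort comparisons.

Implements the Wilcoxon signed-rank test with an exact null distribution
for small samples: zero differences are dropped, ties receive mid-ranks,
and the null distribution of the positive-rank sum W+ is enumerated by
dynamic programming over the 2^n sign assignments (feasible well past the
cohort sizes used here). Larger samples fall back to the normal
approximation with tie correction and continuity correction.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import rankdata

__all__ = ["wilcoxon_signed_rank", "WilcoxonResult"]


class WilcoxonResult(tuple):
    """(statistic W+, two-sided p-value) with attribute access."""

    def __new__(cls, statistic, pvalue, n_used):
        obj = super().__new__(cls, (statistic, pvalue))
        obj.statistic = statistic
        obj.pvalue = pvalue
        obj.n_used = n_used
        return obj


def _exact_two_sided_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for W+ given the (mid-)ranks of |differences|.

    Works on doubled ranks so mid-ranks (k + 0.5) become integers; the
    distribution of 2*W+ is built by convolving (1 + x^(2r)) polynomials.
    """
    r2 = np.rint(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[:total + 1 - r]
        pmf = 0.5 * (pmf + shifted)
    w2 = int(np.rint(2 * w_plus))
    cdf = pmf[:w2 + 1].sum()
    sf = pmf[w2:].sum()
    return float(min(1.0, 2.0 * min(cdf, sf)))


def wilcoxon_signed_rank(x, y=None, exact_max_n: int = 25) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test, two-sided.

    ``x`` may be the paired differences directly, or paired samples with
    ``y``. Zero differences are dropped; ties get mid-ranks. For up to
    ``exact_max_n`` non-zero differences the null distribution is exact.
    """
    d = np.asarray(x, float)
    if y is not None:
        d = d - np.asarray(y, float)
    if d.ndim != 1:
        raise ValueError("paired samples must be one-dimensional")
    if len(d) < 5:
        raise ValueError("need at least 5 pairs")
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        warnings.warn("all paired differences are zero", RuntimeWarning)
        return WilcoxonResult(0.0, 1.0, 0)
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        p = _exact_two_sided_p(ranks, w_plus)
    else:
        mu = n * (n + 1) / 4.0
        # tie correction on the variance of W+
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = (counts**3 - counts).sum() / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / np.sqrt(var)
        from scipy.stats import norm
        p = float(2 * norm.sf(abs(z)))
    return WilcoxonResult(w_plus, min(1.0, p), n)
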