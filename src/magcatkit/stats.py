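"""Statistical primitives shared across modules.

Thin, explicitly-contracted wrappers around scipy/statsmodels so that every
test statistic used elsewhere (Fisher's exact test, Mann-Whitney U,
one-sample Kolmogorov-Smirnov against a fitted normal, Benjamini-Hochberg
q-values) has a single, oracle-checkable implementation.
"""

from __future__ import annotations

import math
from typing import NamedTuple, Sequence

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests


class FisherResult(NamedTuple):
    odds_ratio: float
    p_value: float


class MwuResult(NamedTuple):
    u_statistic: float
    p_value: float


class KsResult(NamedTuple):
    statistic: float
    p_value: float
    degenerate: bool


def fisher_exact(a: int, b: int, c: int, d: int) -> FisherResult:
    """Two-sided Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    The odds ratio is the sample OR (a/b)/(c/d); when any cell is zero the
    Haldane correction (+0.5 to every cell) is applied to the point estimate
    only — the p-value always comes from the unmodified table.  A zero row
    or column margin gives p = 1 and an undefined (NaN) odds ratio.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("contingency cells must be non-negative")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return FisherResult(odds_ratio=math.nan, p_value=1.0)
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) / (b + 0.5)) / ((c + 0.5) / (d + 0.5))
    else:
        odds = (a / b) / (c / d)
    # scipy's two-sided p sums hypergeometric probabilities <= that of the
    # observed table over all tables with the same margins.
    _, p = scipy.stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return FisherResult(odds_ratio=float(odds), p_value=float(p))


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> MwuResult:
    """Mann-Whitney U test.

    Exact enumeration for small samples (both sides <= 8, no ties),
    otherwise the tie-corrected normal approximation.  If every value in
    both samples is identical, p = 1 and U sits at its mean n1*n2/2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return MwuResult(u_statistic=x.size * y.size / 2.0, p_value=1.0)
    has_ties = np.unique(pooled).size < pooled.size
    if max(x.size, y.size) <= 8 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = scipy.stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return MwuResult(u_statistic=float(res.statistic), p_value=float(res.pvalue))


def ks_normal(counts: Sequence[float]) -> KsResult:
    """One-sample KS test of ``counts`` against Normal(sample mean, sample SD).

    Uses the asymptotic Kolmogorov distribution for the p-value.  Parameters
    are estimated from the sample, so the test is conservative
    (Lilliefors-biased) — documented, accepted.  Zero sample SD is
    degenerate: p = 0 with the ``degenerate`` flag set.
    """
    x = np.asarray(counts, dtype=float)
    if x.size < 5:
        raise ValueError("ks_normal requires n >= 5")
    mu = x.mean()
    sd = x.std(ddof=1)
    if sd == 0:
        return KsResult(statistic=1.0, p_value=0.0, degenerate=True)
    d, p = scipy.stats.kstest(x, "norm", args=(mu, sd))
    return KsResult(statistic=float(d), p_value=float(p), degenerate=False)


def bh_qvalues(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
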