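"""Statistical primitives: exact 2x2 Fisher tests (vectorised), BH-FDR,
and a Mann-Whitney U wrapper.

The window pipeline runs Fisher's exact test on ~1e5 tables per contrast,
so the two-sided p-value is computed here by vectorised enumeration of the
hypergeometric support (log-pmf via ``gammaln``) rather than one SciPy call
per table.  The two-sided rule is the usual one: sum the probabilities of
all tables (fixed margins) whose probability does not exceed that of the
observed table, with a relative tolerance of 1e-7 on the comparison to
absorb floating-point ties between analytically equal tables.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

_REL_TOL = 1e-7


def fisher_exact_batch(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray, chunk: int = 4096
) -> np.ndarray:
    """Two-sided Fisher exact p-values for tables [[a, b], [c, d]].

    All arguments are broadcastable integer arrays of non-negative counts.
    Tables with an empty margin (all-zero row or column pair making the
    distribution degenerate) get p = 1.
    """
    a, b, c, d = np.broadcast_arrays(
        np.asarray(a, dtype=np.int64),
        np.asarray(b, dtype=np.int64),
        np.asarray(c, dtype=np.int64),
        np.asarray(d, dtype=np.int64),
    )
    if min(a.min(initial=0), b.min(initial=0), c.min(initial=0), d.min(initial=0)) < 0:
        raise ValueError("counts must be non-negative")
    shape = a.shape
    a, b, c, d = (x.ravel() for x in (a, b, c, d))
    p = np.ones(a.size, dtype=np.float64)
    for lo in range(0, a.size, chunk):
        hi = min(lo + chunk, a.size)
        p[lo:hi] = _fisher_chunk(a[lo:hi], b[lo:hi], c[lo:hi], d[lo:hi])
    return p.reshape(shape)


def _fisher_chunk(a, b, c, d):
    r1 = a + b  # first row margin
    r2 = c + d
    c1 = a + c  # first column margin
    n = r1 + r2
    kmin = np.maximum(0, c1 - r2)
    kmax = np.minimum(r1, c1)
    width = int((kmax - kmin).max(initial=0)) + 1
    ks = kmin[:, None] + np.arange(width)[None, :]
    valid = ks <= kmax[:, None]
    ks = np.where(valid, ks, kmin[:, None])

    # log P(K = k) for hypergeometric with margins (r1, r2; c1)
    def logpmf(k):
        return (
            gammaln(r1[:, None] + 1)
            - gammaln(k + 1)
            - gammaln(r1[:, None] - k + 1)
            + gammaln(r2[:, None] + 1)
            - gammaln(c1[:, None] - k + 1)
            - gammaln(r2[:, None] - (c1[:, None] - k) + 1)
            - (gammaln(n[:, None] + 1) - gammaln(c1[:, None] + 1) - gammaln((n - c1)[:, None] + 1))
        )

    lp = logpmf(ks)
    lp_obs = np.take_along_axis(lp, (a - kmin)[:, None], axis=1)
    include = valid & (lp <= lp_obs + np.log1p(_REL_TOL))
    pmf = np.where(include, np.exp(lp), 0.0)
    p = pmf.sum(axis=1)
    return np.clip(p, 0.0, 1.0)


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for one table [[a, b], [c, d]]."""
    return float(fisher_exact_batch(np.array([a]), np.array([b]), np.array([c]), np.array([d]))[0])


def fdr_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} min(1, m * p_(j) / j) along sorted p; output is in
    the input order.  Empty input returns an empty array.
    """
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def mann_whitney_u(
    x: np.ndarray, y: np.ndarray, exact_max: int = 50
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of x, p).

    Uses the exact null distribution when the pooled sample size is at most
    ``exact_max`` and there are no ties; otherwise the normal approximation
    with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 1 or y.size < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if x.size + y.size <= exact_max and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
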