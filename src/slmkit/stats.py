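"""Count statistics shared by the locus and DMR callers.

The central primitive is a vectorised two-sided Fisher's exact test on
2x2 tables of (methylated, unmethylated) read counts.  The two-sided
p-value is the classical "sum of at-most-as-likely tables" definition:
conditioning on both margins, every table probability not exceeding the
observed hypergeometric probability (up to a small relative tolerance
guarding against floating-point ties) is added up.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import hypergeom

# Relative tolerance for pmf comparisons; analytic ties (symmetric tables)
# must land on the "include" side despite floating-point noise.
_REL_TOL = 1e-7

_CHUNK = 4096


def fisher_exact_two_sided(m1, u1, m2, u2) -> np.ndarray:
    """Two-sided Fisher's exact p-values for arrays of 2x2 count tables.

    Parameters
    ----------
    m1, u1
        Methylated / unmethylated counts in condition 1.
    m2, u2
        Methylated / unmethylated counts in condition 2.

    Returns
    -------
    numpy.ndarray
        p-values in [0, 1], one per table.  Tables with a zero margin
        (e.g. no reads in one condition) are assigned p = 1.

    Notes
    -----
    Equivalent to ``scipy.stats.fisher_exact(..., alternative="two-sided")``
    applied row-wise, but evaluates the full hypergeometric support as a
    matrix so that many thousands of windows can be tested at once.
    """
    a = np.atleast_1d(np.asarray(m1, dtype=np.int64))
    b = np.atleast_1d(np.asarray(u1, dtype=np.int64))
    c = np.atleast_1d(np.asarray(m2, dtype=np.int64))
    d = np.atleast_1d(np.asarray(u2, dtype=np.int64))
    if not (a.shape == b.shape == c.shape == d.shape):
        raise ValueError("count arrays must share a shape")
    if min(a.min(initial=0), b.min(initial=0), c.min(initial=0), d.min(initial=0)) < 0:
        raise ValueError("negative counts in contingency table")

    out = np.ones(a.shape[0], dtype=np.float64)
    for lo_i in range(0, a.shape[0], _CHUNK):
        sl = slice(lo_i, min(lo_i + _CHUNK, a.shape[0]))
        out[sl] = _fisher_chunk(a[sl], b[sl], c[sl], d[sl])
    return out


def _fisher_chunk(a, b, c, d) -> np.ndarray:
    N = a + b + c + d
    K = a + b          # row-1 margin
    n = a + c          # column-1 margin
    lo = np.maximum(0, n - (N - K))
    hi = np.minimum(K, n)
    width = int((hi - lo).max(initial=0))

    support = lo[:, None] + np.arange(width + 1)[None, :]
    valid = support <= hi[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        pmf = hypergeom.pmf(support, N[:, None], K[:, None], n[:, None])
    pmf = np.where(valid, pmf, 0.0)
    obs = hypergeom.pmf(a, N, K, n)

    include = pmf <= obs[:, None] * (1.0 + _REL_TOL)
    p = np.where(include, pmf, 0.0).sum(axis=1)
    # a zero margin collapses the support to a single certain table: p = 1
    p = np.where(hi == lo, 1.0, p)
    return np.clip(p, 0.0, 1.0)  # guards accumulated rounding on wide supports


def bh_qvalues(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone adjusted p-values)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
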