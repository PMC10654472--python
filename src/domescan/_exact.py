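"""Shared exact-test kernels for 2x2 (and small RxC) contingency tables.

The scan applies Fisher's exact test to tens of thousands of SNPs per
chromosome, so the two-sided hypergeometric sum is implemented over a
pre-computed log-factorial table instead of calling a scalar library
routine per site.
"""

from __future__ import annotations

import itertools
import math
import warnings

import numpy as np

__all__ = ["fisher_exact_2x2", "fisher_exact_many", "fisher_freeman_halton_3x2"]

# Tables whose probability is within (1 + _REL_EPS) of the observed one are
# counted as "as extreme" (same convention as R's fisher.test).
_REL_EPS = 1e-7


class _LgammaTable:
    """Cached ``lgamma(n + 1)`` lookups, grown on demand."""

    def __init__(self) -> None:
        self._tab = np.zeros(1)

    def __call__(self, n_max: int) -> np.ndarray:
        if n_max >= self._tab.size:
            new = max(n_max + 1, 2 * self._tab.size, 1024)
            from scipy.special import gammaln

            self._tab = gammaln(np.arange(new, dtype=float) + 1.0)
        return self._tab


_lfact = _LgammaTable()


def _two_sided_p(a: int, b: int, c: int, d: int, lf: np.ndarray) -> float:
    """Two-sided Fisher p for one table via the hypergeometric distribution."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    lo = max(0, c1 - r2)
    hi = min(c1, r1)
    k = np.arange(lo, hi + 1)
    # log P(X = k) up to the shared constant, which cancels in the comparison
    logp = -(lf[k] + lf[r1 - k] + lf[c1 - k] + lf[r2 - c1 + k])
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    obs = p[a - lo]
    total = p[p <= obs * (1.0 + _REL_EPS)].sum()
    return 1.0 if total >= 1.0 - 1e-12 else float(total)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 count table.

    Parameters
    ----------
    table : array-like, shape (2, 2)
        Non-negative integer counts ``[[a, b], [c, d]]``.

    Returns
    -------
    float
        The two-sided p-value: the sum of hypergeometric probabilities of
        all tables (with the observed margins) no more probable than the
        observed one.  A table with a zero margin carries no information
        and returns 1.0 with a warning.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    a, b, c, d = (int(x) for x in t.ravel())
    n = a + b + c + d
    if min(a + b, c + d) == 0 or min(a + c, b + d) == 0:
        warnings.warn("zero margin in 2x2 table; p-value undefined, returning 1.0")
        return 1.0
    return _two_sided_p(a, b, c, d, _lfact(n))


def fisher_exact_many(a, b, c, d) -> np.ndarray:
    """Vectorised two-sided Fisher exact test over parallel 2x2 tables.

    ``a, b`` are the two cell counts of the first row and ``c, d`` of the
    second, each an array over tables (e.g. SNPs). Tables with a zero
    margin yield p = 1.
    """
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    c = np.asarray(c, dtype=np.int64)
    d = np.asarray(d, dtype=np.int64)
    if not (a.shape == b.shape == c.shape == d.shape):
        raise ValueError("cell-count arrays must share a shape")
    if min(x.min(initial=0) for x in (a, b, c, d)) < 0:
        raise ValueError("counts must be non-negative")
    n_tot = a + b + c + d
    lf = _lfact(int(n_tot.max(initial=0)))
    out = np.ones(a.shape, dtype=float)
    flat = out.ravel()
    for i, (ai, bi, ci, di) in enumerate(
        zip(a.ravel().tolist(), b.ravel().tolist(), c.ravel().tolist(), d.ravel().tolist())
    ):
        if min(ai + bi, ci + di) == 0 or min(ai + ci, bi + di) == 0:
            continue
        flat[i] = _two_sided_p(ai, bi, ci, di, lf)
    return out


def fisher_freeman_halton_3x2(table) -> float:
    """Exact conditional p-value for a 3x2 table (Freeman–Halton extension).

    Enumerates all tables with the observed margins and sums the
    multivariate-hypergeometric probabilities of those no more probable
    than the observed table.  Intended for genotype-level (AA/Aa/aa vs
    origin) contrasts at gene-level sample sizes; complexity is
    O(margin^2).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (3, 2):
        raise ValueError(f"expected a 3x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    n = int(t.sum())
    if n == 0 or cols.min() == 0:
        warnings.warn("degenerate 3x2 table; returning p = 1.0")
        return 1.0
    lf = _lfact(n)

    def log_prob(x0: int, x1: int, x2: int) -> float:
        # P(table | margins) for first-column counts (x0, x1, x2)
        lp = float(lf[cols[0]] + lf[cols[1]] + lf[rows].sum() - lf[n])
        for xi, ri in zip((x0, x1, x2), rows.tolist()):
            lp -= float(lf[xi] + lf[ri - xi])
        return lp

    obs = log_prob(int(t[0, 0]), int(t[1, 0]), int(t[2, 0]))
    thresh = obs + math.log1p(_REL_EPS)
    total = 0.0
    c0 = int(cols[0])
    for x0 in range(min(int(rows[0]), c0) + 1):
        for x1 in range(min(int(rows[1]), c0 - x0) + 1):
            x2 = c0 - x0 - x1
            if x2 > rows[2]:
                continue
            lp = log_prob(x0, x1, x2)
            if lp <= thresh:
                total += math.exp(lp)
    return float(min(1.0, total))
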