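"""Independent brute-force / closed-form oracles used only by the tests.

These deliberately re-derive each statistic from its textbook definition by
a different route than the package (log-factorial enumeration, explicit
loops, pairwise counting) so that agreement is a two-implementation check.
"""
from __future__ import annotations

import math

import numpy as np

_TIE_GAMMA = 1.0 + 1e-7  # same tie convention as the package / scipy


def fisher_enum(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by explicit enumeration with log-factorials."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    lf = [math.lgamma(i + 1) for i in range(n + 1)]

    def logp(k: int) -> float:
        return (lf[r1] - lf[k] - lf[r1 - k]
                + lf[r2] - lf[c1 - k] - lf[r2 - (c1 - k)]
                - (lf[n] - lf[c1] - lf[n - c1]))

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = math.exp(logp(a))
    total = 0.0
    for k in range(lo, hi + 1):
        pk = math.exp(logp(k))
        if pk <= p_obs * _TIE_GAMMA:
            total += pk
    return min(total, 1.0)


def bh_stepup(pvals: np.ndarray, alpha: float) -> np.ndarray:
    """Textbook Benjamini-Hochberg step-up: reject H_(1..k*) where k* is the
    largest k with p_(k) <= k * alpha / m."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    k_star = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * alpha / m:
            k_star = rank
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


def binom_tail(meth: int, depth: int, e: float) -> float:
    """P(X >= meth) for X ~ Binomial(depth, e), by direct summation."""
    total = 0.0
    for k in range(meth, depth + 1):
        total += math.comb(depth, k) * e**k * (1 - e) ** (depth - k)
    return min(total, 1.0)


def wc_fst_site(dos_a, dos_b):
    """Weir & Cockerham (1984) per-site components (a, b, c), plain scalars."""
    def stats(dos):
        dos = [g for g in dos if g >= 0]
        n = len(dos)
        p = sum(dos) / (2.0 * n)
        h = sum(1 for g in dos if g == 1) / n
        return n, p, h

    n1, p1, h1 = stats(dos_a)
    n2, p2, h2 = stats(dos_b)
    if n1 < 2 or n2 < 2:
        return math.nan, math.nan, math.nan
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


def wc_fst_window(dos_a: np.ndarray, dos_b: np.ndarray) -> float:
    num = den = 0.0
    for i in range(dos_a.shape[0]):
        a, b, c = wc_fst_site(dos_a[i], dos_b[i])
        if not math.isnan(a):
            num += a
            den += a + b + c
    return num / den


def tajima_direct(dosages: np.ndarray) -> float:
    """Tajima's D from the published formula, written out step by step."""
    dos = [row for row in np.asarray(dosages) if min(row) >= 0]
    if not dos:
        return math.nan
    n = 2 * len(dos[0])
    if n < 4:
        return math.nan
    S = 0
    pi_hat = 0.0
    for row in dos:
        k = int(sum(row))
        if 0 < k < n:
            S += 1
            p = k / n
            pi_hat += 2 * p * (1 - p) * n / (n - 1)
    if S == 0:
        return math.nan
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (pi_hat - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def pi_pairwise(dosages: np.ndarray, window_length: int) -> float:
    """Nucleotide diversity as the mean pairwise haplotype difference,
    counted pair by pair after expanding dosages to alleles."""
    total = 0.0
    for row in np.asarray(dosages):
        alleles = []
        for g in row:
            if g >= 0:
                alleles += [1] * int(g) + [0] * (2 - int(g))
        n = len(alleles)
        if n < 2:
            continue
        diff = sum(1 for i in range(n) for j in range(i + 1, n)
                   if alleles[i] != alleles[j])
        total += diff / (n * (n - 1) / 2)
    return total / window_length


def all_tables_up_to(total: int) -> np.ndarray:
    """Every 2x2 non-negative integer table with grand total <= ``total``."""
    out = []
    for n in range(total + 1):
        for a in range(n + 1):
            for b in range(n - a + 1):
                for c in range(n - a - b + 1):
                    out.append((a, b, c, n - a - b - c))
    return np.array(out, dtype=np.int64)


def fisher_enum_sweep(tables: np.ndarray) -> np.ndarray:
    """Vectorized log-factorial Fisher enumeration (independent of the
    package's hypergeometric-distribution route)."""
    lf = np.array([math.lgamma(i + 1) for i in range(int(tables.sum(axis=1).max()) + 1)])
    a, b, c, d = tables.T
    r1, r2, c1, n = a + b, c + d, a + c, a + b + c + d
    lo = np.maximum(0, c1 - r2)
    hi = np.minimum(r1, c1)
    width = int((hi - lo).max()) + 1
    k = lo[:, None] + np.arange(width)[None, :]
    valid = k <= hi[:, None]
    kk = np.where(valid, k, lo[:, None])
    logp = (lf[r1][:, None] - lf[kk] - lf[r1[:, None] - kk]
            + lf[r2][:, None] - lf[c1[:, None] - kk]
            - lf[r2[:, None] - (c1[:, None] - kk)]
            - (lf[n] - lf[c1] - lf[n - c1])[:, None])
    pmf = np.where(valid, np.exp(logp), 0.0)
    pobs = np.exp(logp[np.arange(len(tables)), a - lo])
    take = pmf <= pobs[:, None] * _TIE_GAMMA
    p = np.minimum((pmf * take).sum(axis=1), 1.0)
    degenerate = (r1 == 0) | (r2 == 0) | (c1 == 0) | (c1 == n)
    p[degenerate] = 1.0
    return p
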