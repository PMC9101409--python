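"""Independent reference implementations used only to check the package."""

from __future__ import annotations

import math

from scipy.stats import hypergeom


def smith_waterman_score(q: str, s: str, match: int = 2, mismatch: int = -3,
                         gap_open: int = 5, gap_extend: int = 2) -> int:
    """Exhaustive affine-gap local-alignment score (pure-python DP).

    A gap of length k costs gap_open + k * gap_extend.
    """
    m, n = len(q), len(s)
    NEG = -(10 ** 9)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_extend,
                          E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_extend,
                          F[i - 1][j] - gap_extend)
            sub = match if q[i - 1] == s[j - 1] else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def fisher_greater(a: int, b: int, c: int, d: int) -> float:
    """One-sided (enrichment) Fisher p by hypergeometric tail sum."""
    N = a + b + c + d
    K = a + c
    n = a + b
    return float(hypergeom.sf(a - 1, N, K, n))


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p: sum of hypergeometric probabilities of all tables
    with the same margins and probability <= the observed table's."""
    import numpy as np

    N = a + b + c + d
    K = a + c
    n = a + b
    lo = max(0, n - (N - K))
    hi = min(n, K)
    xs = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(xs, N, K, n)
    p_obs = pmf[a - lo]
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-9)].sum()))


def fisher_combined(ps) -> float:
    """Fisher's method via the chi-square upper tail (series for even df)."""
    x = -2.0 * sum(math.log(p) for p in ps)
    k = len(ps)
    # upper tail of chi2 with 2k df: exp(-x/2) * sum_{i<k} (x/2)^i / i!
    term = 1.0
    acc = 1.0
    for i in range(1, k):
        term *= (x / 2) / i
        acc += term
    return math.exp(-x / 2) * acc
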