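"""Independent brute-force oracles used by unit and acceptance tests."""

import math

import numpy as np


def brute_force_binomial_quantile(q: float, n: int, p: float) -> int:
    """Smallest k with Binomial CDF(k; n, p) >= q, by exact integer arithmetic.

    Floats are dyadic rationals, so p = pm/2^ps and q = qm/2^qs exactly; the
    CDF comparison reduces to an exact integer inequality, immune to rounding
    even at ties (e.g. CDF(23; 47, 1/2) = 1/2).
    """
    if p == 0.0:
        return 0
    if p == 1.0:
        return n
    pm, pd = p.as_integer_ratio()
    qm, qd = q.as_integer_ratio()
    # CDF(k)*pd^n = sum_{j<=k} C(n,j) * pm^j * (pd-pm)^(n-j)
    acc = 0
    for k in range(n + 1):
        acc += math.comb(n, k) * pm**k * (pd - pm) ** (n - k)
        if acc * qd >= qm * pd**n:
            return k
    return n


def brute_force_glocal(read: str, ref: str, match=1, mismatch=-2, gap=-2) -> float:
    """Global-in-read, local-in-reference score by plain quadratic DP."""
    n, m = len(read), len(ref)
    H = np.zeros((n + 1, m + 1))
    H[1:, 0] = gap * np.arange(1, n + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if read[i - 1] == ref[j - 1] else mismatch
            H[i, j] = max(H[i - 1, j - 1] + s, H[i - 1, j] + gap, H[i, j - 1] + gap)
    return float(H[n].max())
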