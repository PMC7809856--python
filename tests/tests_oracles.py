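"""Shared independent oracles used across test modules."""

from fractions import Fraction
from math import comb


def fisher_oracle(a, b, c, d):
    """Two-tailed Fisher p by exact-rational enumeration over all tables
    with the observed margins (point-probability criterion)."""
    n = a + b + c + d
    if n == 0:
        return 1.0
    row1, col1 = a + b, a + c
    denom = comb(n, col1)

    def pmf(x):
        return Fraction(comb(row1, x) * comb(n - row1, col1 - x), denom)

    lo = max(0, col1 - (c + d))
    hi = min(row1, col1)
    p_obs = pmf(a)
    return float(sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= p_obs))
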