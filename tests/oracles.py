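"""Independent brute-force oracles used by the test suite only."""

from math import comb


def fisher_greater_oracle(a: int, b: int, c: int, d: int) -> float:
    """One-sided (greater) Fisher p by exhaustive hypergeometric enumeration
    over all 2x2 tables with the observed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    total = 0
    for x in range(lo, hi + 1):
        if x >= a:
            total += comb(r1, x) * comb(r2, c1 - x)
    return total / denom
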