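"""Independent brute-force oracles in exact rational arithmetic.

These enumerate contingency-table families directly with
fractions.Fraction and math.factorial, sharing no code with the package's
log-factorial implementations.
"""

from fractions import Fraction
from math import comb, factorial


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher P by full hypergeometric enumeration."""
    n1, n2, k = a + b, c + d, a + c
    n = n1 + n2
    denom = comb(n, k)
    lo, hi = max(0, k - n2), min(k, n1)
    probs = {
        x: Fraction(comb(n1, x) * comb(n2, k - x), denom)
        for x in range(lo, hi + 1)
    }
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs)


def flint_oracle(case: tuple, control: tuple) -> Fraction:
    """Exact conditional no-three-way-interaction P by direct enumeration.

    Fixes all three two-way margins of the 2x2x2 table and enumerates the
    one-parameter family over the pivot cell case[0] (joint-carrier
    cases); each table weighted by 1 / prod(cell!).
    """
    c11, c10, c01, c00 = case
    k11, k10, k01, k00 = control
    case_a, case_b, n_case = c11 + c10, c11 + c01, sum(case)
    m11, m10, m01, m00 = c11 + k11, c10 + k10, c01 + k01, c00 + k00

    def cells(p):
        return (
            p,
            case_a - p,
            case_b - p,
            n_case - case_a - case_b + p,
            m11 - p,
            m10 - case_a + p,
            m01 - case_b + p,
            m00 - n_case + case_a + case_b - p,
        )

    weights = {}
    for p in range(0, sum(case) + sum(control) + 1):
        cs = cells(p)
        if min(cs) < 0:
            continue
        w = Fraction(1)
        for x in cs:
            w /= factorial(x)
        weights[p] = w
    total = sum(weights.values())
    probs = {p: w / total for p, w in weights.items()}
    p_obs = probs[c11]
    return sum(p for p in probs.values() if p <= p_obs)
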