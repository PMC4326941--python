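"""Independent brute-force oracles used to validate the exact tests.

Everything here works in exact integer / rational arithmetic and is written
from the definitions, not from the package's implementation.
"""

from fractions import Fraction
from math import comb, factorial

# two-sided inclusion rule: include tables with probability <= observed,
# with a 1e-7 relative tolerance on the comparison (integer-exact form:
# 10^7 * w <= (10^7 + 1) * w_obs).
_TEN7 = 10 ** 7


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher P by exhaustive hypergeometric enumeration."""
    n = a + b + c + d
    m, k = a + b, a + c
    if m == 0 or k == 0 or m == n or k == n:
        return 1.0
    x0, x1 = max(0, k - (n - m)), min(m, k)
    weights = {x: comb(m, x) * comb(n - m, k - x) for x in range(x0, x1 + 1)}
    w_obs = weights[a]
    included = sum(w for w in weights.values()
                   if _TEN7 * w <= (_TEN7 + 1) * w_obs)
    return included / comb(n, k)


def fisher_oracle_all_tables(n: int, m: int, k: int):
    """Oracle P for every observed cell a given margins (m, n-m) x (k, n-k).

    Returns ``(support, pvalues)`` as parallel lists.
    """
    x0, x1 = max(0, k - (n - m)), min(m, k)
    xs = list(range(x0, x1 + 1))
    ws = [comb(m, x) * comb(n - m, k - x) for x in xs]
    total = comb(n, k)
    ps = []
    for w_obs in ws:
        bound = (_TEN7 + 1) * w_obs
        ps.append(sum(w for w in ws if _TEN7 * w <= bound) / total)
    return xs, ps


def _hwe_probs(n: int, r: int):
    """Exact conditional heterozygote-count distribution, as Fractions.

    P(h heterozygotes | n subjects, r copies of the rarer allele)
    = 2^h n! / (n_rr! h! n_cc!) * r! (2n - r)! / (2n)!.
    """
    norm = Fraction(factorial(r) * factorial(2 * n - r), factorial(2 * n))
    probs = {}
    for h in range(r % 2, r + 1, 2):
        n_rr = (r - h) // 2
        n_cc = n - h - n_rr
        probs[h] = (Fraction(2 ** h * factorial(n),
                             factorial(n_rr) * factorial(h) * factorial(n_cc))
                    * norm)
    return probs


def hwe_oracle(n0: int, n1: int, n2: int) -> float:
    """Exact conditional HWE P by full enumeration with rational arithmetic."""
    n = n0 + n1 + n2
    r = min(n1 + 2 * n2, n1 + 2 * n0)
    probs = _hwe_probs(n, r)
    p_obs = probs[n1]
    return float(sum(p for p in probs.values() if p <= p_obs))


def hwe_oracle_all(n: int, r: int):
    """Oracle P for every heterozygote count given n subjects, r rare alleles.

    Returns a dict {h: p}.
    """
    probs = _hwe_probs(n, r)
    return {h: float(sum(p for p in probs.values() if p <= p_h))
            for h, p_h in probs.items()}
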