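"""Independent oracles for the exact-test machinery.

Exact rational enumeration of all genotype configurations under
Hardy-Weinberg sampling, conditioned on the observed allele counts, using
Fraction arithmetic throughout.  The conditional distributions are
parameter-free, which the oracles can verify by evaluating at different
allele frequencies.
"""

from fractions import Fraction
from math import factorial


def autosomal_conditional(n: int, n_a: int, p: Fraction = Fraction(1, 3)) -> dict[int, Fraction]:
    """Conditional distribution of the heterozygote count given the minor
    allele count, from the unconditional HWE multinomial at frequency p."""
    q = 1 - p
    probs: dict[int, Fraction] = {}
    for n_aa in range(n + 1):
        for n_ab in range(n + 1 - n_aa):
            n_bb = n - n_aa - n_ab
            if 2 * n_aa + n_ab != n_a:
                continue
            coeff = Fraction(factorial(n), factorial(n_aa) * factorial(n_ab) * factorial(n_bb))
            probs[n_ab] = coeff * (p * p) ** n_aa * (2 * p * q) ** n_ab * (q * q) ** n_bb
    total = sum(probs.values())
    return {k: v / total for k, v in probs.items()}


def x_conditional(
    n_m: int, n_f: int, n_a: int, p: Fraction = Fraction(1, 3)
) -> dict[tuple[int, int], Fraction]:
    """Joint conditional distribution of (A males, heterozygous females)
    given the minor allele count, from binomial male hemizygotes and
    multinomial HWE female genotypes at frequency p."""
    q = 1 - p
    probs: dict[tuple[int, int], Fraction] = {}
    for m_a in range(n_m + 1):
        pm = Fraction(factorial(n_m), factorial(m_a) * factorial(n_m - m_a)) * p**m_a * q ** (n_m - m_a)
        for f_aa in range(n_f + 1):
            for f_ab in range(n_f + 1 - f_aa):
                f_bb = n_f - f_aa - f_ab
                if m_a + 2 * f_aa + f_ab != n_a:
                    continue
                coeff = Fraction(
                    factorial(n_f), factorial(f_aa) * factorial(f_ab) * factorial(f_bb)
                )
                pf = coeff * (p * p) ** f_aa * (2 * p * q) ** f_ab * (q * q) ** f_bb
                key = (m_a, f_ab)
                probs[key] = probs.get(key, Fraction(0)) + pm * pf
    total = sum(probs.values())
    return {k: v / total for k, v in probs.items()}


def exact_p_values(pmf: dict, observed) -> tuple[Fraction, Fraction]:
    """(standard, mid) two-sided p by probability ordering, in exact
    rational arithmetic."""
    p_obs = pmf[observed]
    std = sum(v for v in pmf.values() if v <= p_obs)
    mid = sum(v for v in pmf.values() if v < p_obs) + Fraction(1, 2) * sum(
        v for v in pmf.values() if v == p_obs
    )
    return std, mid
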