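"""Exact Hardy-Weinberg test machinery.

Implements the conditional null distribution of the heterozygote count given
the minor-allele count for autosomal bi-allelic markers (the Levene-Haldane
distribution), its bivariate analogue for X-chromosomal markers with
hemizygous males, the corresponding two-sided exact tests with standard and
mid p-values, and the inbreeding coefficient.

All probabilities are computed in log-factorial space so that sample sizes in
the thousands neither overflow nor lose precision; the per-(n, n_A) tables
are cached, which makes genome scans over a fixed cohort cheap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import gammaln

__all__ = [
    "GenotypeCounts",
    "XGenotypeCounts",
    "TestResult",
    "levene_haldane_support",
    "levene_haldane_pmf",
    "autosomal_exact",
    "x_support",
    "x_pmf",
    "x_exact",
    "inbreeding_f",
    "test_autosomal",
    "test_x",
]

#: Relative tolerance under which two outcome probabilities are treated as
#: tied in the probability ordering.  Tied outcomes enter the standard
#: p-value at full weight and the mid p-value at half weight (the observed
#: outcome is a member of its own tie set); this is the unique convention
#: for which the mid p-value has expectation exactly 0.5 under the null.
TIE_RTOL = 1e-12

STATUS_TESTED = "tested"
STATUS_MONOMORPHIC = "monomorphic"
STATUS_SKIPPED = "skipped"


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts for one bi-allelic autosomal variant.

    The first allele ("A") is the minor allele by convention: constructing
    counts with more A than B alleles raises.  Use :meth:`from_unoriented`
    to orient raw REF/ALT-ordered counts (ties are resolved to the ALT
    allele; the exact tests are symmetric in the two alleles, so the choice
    does not affect p-values).
    """

    n_aa: int
    n_ab: int
    n_bb: int
    n_missing: int = 0

    def __post_init__(self) -> None:
        if min(self.n_aa, self.n_ab, self.n_bb, self.n_missing) < 0:
            raise ValueError("genotype counts must be non-negative")
        if self.n_minor > self.n_major:
            raise ValueError(
                f"minor-allele convention violated: n_A={self.n_minor} > n_B={self.n_major}"
            )

    @classmethod
    def from_unoriented(
        cls, n_hom_ref: int, n_het: int, n_hom_alt: int, n_missing: int = 0
    ) -> "GenotypeCounts":
        """Orient REF/ALT-ordered counts so that A is the minor allele."""
        n_alt = 2 * n_hom_alt + n_het
        n_ref = 2 * n_hom_ref + n_het
        if n_alt <= n_ref:  # tie -> ALT designated minor
            return cls(n_hom_alt, n_het, n_hom_ref, n_missing)
        return cls(n_hom_ref, n_het, n_hom_alt, n_missing)

    @property
    def n(self) -> int:
        return self.n_aa + self.n_ab + self.n_bb

    @property
    def n_minor(self) -> int:
        return 2 * self.n_aa + self.n_ab

    @property
    def n_major(self) -> int:
        return 2 * self.n_bb + self.n_ab

    @property
    def maf(self) -> float:
        return self.n_minor / (2 * self.n) if self.n else math.nan

    @property
    def is_monomorphic(self) -> bool:
        return self.n_minor == 0 or self.n_major == 0


@dataclass(frozen=True)
class XGenotypeCounts:
    """Male hemizygote and female genotype counts for one X-linked variant.

    ``m_a``/``m_b`` count male hemizygous calls, ``f_aa``/``f_ab``/``f_bb``
    female diploid genotypes.  A is the minor allele over both sexes
    combined (total allele count n_t = 2 n_f + n_m).
    """

    m_a: int
    m_b: int
    f_aa: int
    f_ab: int
    f_bb: int
    n_missing: int = 0

    def __post_init__(self) -> None:
        fields = (self.m_a, self.m_b, self.f_aa, self.f_ab, self.f_bb, self.n_missing)
        if min(fields) < 0:
            raise ValueError("genotype counts must be non-negative")
        if self.n_minor > self.n_major:
            raise ValueError(
                f"minor-allele convention violated: n_A={self.n_minor} > n_B={self.n_major}"
            )

    @classmethod
    def from_unoriented(
        cls,
        m_ref: int,
        m_alt: int,
        f_hom_ref: int,
        f_het: int,
        f_hom_alt: int,
        n_missing: int = 0,
    ) -> "XGenotypeCounts":
        n_alt = m_alt + 2 * f_hom_alt + f_het
        n_ref = m_ref + 2 * f_hom_ref + f_het
        if n_alt <= n_ref:
            return cls(m_alt, m_ref, f_hom_alt, f_het, f_hom_ref, n_missing)
        return cls(m_ref, m_alt, f_hom_ref, f_het, f_hom_alt, n_missing)

    @property
    def n_m(self) -> int:
        return self.m_a + self.m_b

    @property
    def n_f(self) -> int:
        return self.f_aa + self.f_ab + self.f_bb

    @property
    def n_t(self) -> int:
        return 2 * self.n_f + self.n_m

    @property
    def n_minor(self) -> int:
        return self.m_a + 2 * self.f_aa + self.f_ab

    @property
    def n_major(self) -> int:
        return self.n_t - self.n_minor

    @property
    def maf(self) -> float:
        return self.n_minor / self.n_t if self.n_t else math.nan

    @property
    def is_monomorphic(self) -> bool:
        return self.n_minor == 0 or self.n_major == 0

    @property
    def female_counts(self) -> GenotypeCounts:
        return GenotypeCounts.from_unoriented(self.f_bb, self.f_ab, self.f_aa)


@dataclass(frozen=True)
class TestResult:
    """Outcome of one exact HWE test.

    For a tested variant ``p_std`` and ``p_mid`` are the standard and mid
    p-values (``p_mid <= p_std`` always), ``f`` the inbreeding coefficient
    (negative for heterozygote excess) and ``maf`` the minor allele
    frequency.  Monomorphic variants carry no p-values or f.
    """

    p_std: float
    p_mid: float
    f: float
    maf: float
    status: str


def _logfact(k: np.ndarray | int) -> np.ndarray | float:
    return gammaln(np.asarray(k, dtype=float) + 1.0)


def levene_haldane_support(n: int, n_a: int) -> list[int]:
    """Feasible heterozygote counts given sample size ``n`` and minor allele
    count ``n_a``, in increasing order.

    Every returned ``n_ab`` shares the parity of ``n_a`` and yields
    non-negative homozygote counts ``n_aa = (n_a - n_ab)/2`` and
    ``n_bb = n - n_aa - n_ab``.
    """
    if n < 1:
        raise ValueError("sample size must be >= 1")
    if not 0 <= n_a <= n:
        raise ValueError(
            f"minor allele count n_A={n_a} outside [0, n={n}]: minor-allele convention violated"
        )
    lo = n_a % 2
    return list(range(lo, n_a + 1, 2))


@lru_cache(maxsize=65536)
def _lh_table(n: int, n_a: int) -> tuple[np.ndarray, np.ndarray]:
    """Cached (support, pmf) arrays of the Levene-Haldane distribution."""
    support = np.array(levene_haldane_support(n, n_a), dtype=np.int64)
    n_b = 2 * n - n_a
    n_aa = (n_a - support) // 2
    n_bb = n - n_aa - support
    logp = (
        _logfact(n_a)
        + _logfact(n_b)
        + _logfact(n)
        + support * math.log(2.0)
        - _logfact(n_aa)
        - _logfact(support)
        - _logfact(n_bb)
        - _logfact(2 * n)
    )
    probs = np.exp(logp)
    probs.flags.writeable = False
    support.flags.writeable = False
    return support, probs


def levene_haldane_pmf(n: int, n_a: int) -> dict[int, float]:
    """P(N_AB = k | N_A = n_a) for each feasible heterozygote count k.

    This is the parameter-free conditional distribution of the heterozygote
    count given the observed allele counts under Hardy-Weinberg equilibrium.
    """
    support, probs = _lh_table(n, n_a)
    return {int(k): float(p) for k, p in zip(support, probs)}


def _tail_p(probs: np.ndarray, idx: int, mode: str) -> float:
    """Two-sided exact p by probability ordering.

    standard: sum of probabilities <= P(observed) (ties fully included);
    mid: probabilities strictly below P(observed) plus half the tie mass,
    the observed outcome belonging to its own tie set.
    """
    p_obs = probs[idx]
    tol = TIE_RTOL * p_obs
    tie = np.abs(probs - p_obs) <= tol
    below = (probs < p_obs) & ~tie
    if mode == "standard":
        return float(probs[below].sum() + probs[tie].sum())
    if mode == "mid":
        return float(probs[below].sum() + 0.5 * probs[tie].sum())
    raise ValueError(f"unknown mode {mode!r}")


def autosomal_exact(counts: GenotypeCounts, mode: str = "mid") -> float:
    """Two-sided exact HWE p-value for an autosomal variant.

    ``mode='standard'`` gives the classical exact p (probability of the
    observed sample plus all samples no more probable); ``mode='mid'``
    halves the weight of the observed sample's probability class.
    """
    if counts.is_monomorphic:
        raise ValueError("monomorphic variant: exact test undefined")
    support, probs = _lh_table(counts.n, counts.n_minor)
    idx = int(np.searchsorted(support, counts.n_ab))
    if idx >= len(support) or support[idx] != counts.n_ab:
        raise ValueError("observed heterozygote count outside the support")
    return _tail_p(probs, idx, mode)


def x_support(n_m: int, n_f: int, n_a: int) -> list[tuple[int, int]]:
    """Feasible (male A count, female heterozygote count) pairs given the
    sex-specific sample sizes and the minor allele count."""
    if n_m < 0 or n_f < 0:
        raise ValueError("sample sizes must be non-negative")
    n_t = 2 * n_f + n_m
    if not 0 <= n_a <= n_t - n_a:
        raise ValueError(
            f"minor allele count n_A={n_a} violates the minor-allele convention for n_t={n_t}"
        )
    out = []
    for m_a in range(min(n_m, n_a) + 1):
        rem = n_a - m_a
        for f_ab in range(rem % 2, min(n_f, rem) + 1, 2):
            f_aa = (rem - f_ab) // 2
            if f_aa + f_ab <= n_f:
                out.append((m_a, f_ab))
    if not out:
        raise ValueError(f"empty support for (n_m={n_m}, n_f={n_f}, n_A={n_a})")
    return out


@lru_cache(maxsize=65536)
def _x_table(n_m: int, n_f: int, n_a: int) -> tuple[tuple[tuple[int, int], ...], np.ndarray]:
    support = tuple(x_support(n_m, n_f, n_a))
    n_t = 2 * n_f + n_m
    n_b = n_t - n_a
    m_a = np.array([s[0] for s in support], dtype=np.int64)
    f_ab = np.array([s[1] for s in support], dtype=np.int64)
    m_b = n_m - m_a
    f_aa = (n_a - m_a - f_ab) // 2
    f_bb = n_f - f_aa - f_ab
    logp = (
        _logfact(n_a)
        + _logfact(n_b)
        + _logfact(n_m)
        + _logfact(n_f)
        + f_ab * math.log(2.0)
        - _logfact(m_a)
        - _logfact(m_b)
        - _logfact(f_aa)
        - _logfact(f_ab)
        - _logfact(f_bb)
        - _logfact(n_t)
    )
    probs = np.exp(logp)
    probs.flags.writeable = False
    return support, probs


def x_pmf(n_m: int, n_f: int, n_a: int) -> dict[tuple[int, int], float]:
    """Joint null pmf of (number of A males, number of heterozygous females)
    given the minor allele count, under HWE in females and equal allele
    frequencies in the sexes."""
    support, probs = _x_table(n_m, n_f, n_a)
    return {pair: float(p) for pair, p in zip(support, probs)}


def x_exact(counts: XGenotypeCounts, mode: str = "mid") -> float:
    """Omnibus exact X-chromosomal test: HWE in females jointly with
    equality of male and female allele frequencies.

    With no males this reduces exactly to the autosomal test on the female
    genotype counts.
    """
    if counts.is_monomorphic:
        raise ValueError("monomorphic variant: exact test undefined")
    support, probs = _x_table(counts.n_m, counts.n_f, counts.n_minor)
    try:
        idx = support.index((counts.m_a, counts.f_ab))
    except ValueError:
        raise ValueError("observed configuration outside the support") from None
    return _tail_p(probs, idx, mode)


def inbreeding_f(counts: GenotypeCounts) -> float:
    """Inbreeding coefficient f = 1 - H_obs / H_exp.

    H_obs is the observed heterozygote fraction, H_exp = 2 p (1 - p) the
    Hardy-Weinberg expectation at the sample allele frequency.  Negative f
    means heterozygote excess.  Undefined for monomorphic variants.
    """
    if counts.is_monomorphic:
        raise ValueError("monomorphic variant: inbreeding coefficient undefined")
    p = counts.n_minor / (2 * counts.n)
    h_obs = counts.n_ab / counts.n
    h_exp = 2.0 * p * (1.0 - p)
    return 1.0 - h_obs / h_exp


def test_autosomal(counts: GenotypeCounts) -> TestResult:
    """Run the autosomal exact test, returning both p-values, f and MAF."""
    if counts.n == 0:
        return TestResult(math.nan, math.nan, math.nan, math.nan, STATUS_SKIPPED)
    if counts.is_monomorphic:
        return TestResult(math.nan, math.nan, math.nan, counts.maf, STATUS_MONOMORPHIC)
    return TestResult(
        p_std=autosomal_exact(counts, "standard"),
        p_mid=autosomal_exact(counts, "mid"),
        f=inbreeding_f(counts),
        maf=counts.maf,
        status=STATUS_TESTED,
    )


def test_x(counts: XGenotypeCounts) -> TestResult:
    """Run the omnibus X test.  f is computed from the female genotypes
    only (hemizygous males carry no heterozygosity information); it is NaN
    when the females are monomorphic."""
    if counts.n_t == 0:
        return TestResult(math.nan, math.nan, math.nan, math.nan, STATUS_SKIPPED)
    if counts.is_monomorphic:
        return TestResult(math.nan, math.nan, math.nan, counts.maf, STATUS_MONOMORPHIC)
    fem = counts.female_counts
    f = inbreeding_f(fem) if (counts.n_f > 0 and not fem.is_monomorphic) else math.nan
    return TestResult(
        p_std=x_exact(counts, "standard"),
        p_mid=x_exact(counts, "mid"),
        f=f,
        maf=counts.maf,
        status=STATUS_TESTED,
    )
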