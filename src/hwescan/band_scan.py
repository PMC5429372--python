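"""Horizontal-band detection.

In chromosome-wide tracks of HW p-values, runs of variants sharing exactly
the same genotypic composition show up as horizontal bands.  This module
groups polymorphic variants by their (minor-oriented) composition, reports
bands, and checks whether a band's multi-locus genotypes are explained by
exactly two haplotypes — the long-range-LD interpretation — with an exact
combinatorial check rather than EM phasing: homozygous individuals pin the
phase, and every remaining individual must be heterozygous at all
segregating members with a compatible dosage pattern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .variant_io import HET, HOM_ALT, HOM_REF, MISSING, VariantRecord

logger = logging.getLogger(__name__)

__all__ = ["CompositionBand", "find_bands", "two_haplotype_consistent", "minor_dosage"]


@dataclass
class CompositionBand:
    """A set of nearby variants sharing one genotypic composition.

    ``composition`` is minor-allele oriented (n_AA, n_AB, n_BB) so REF/ALT
    labelling cannot split a band; ``identical_vectors`` is True when all
    members carry identical per-sample genotype vectors up to a global
    relabelling of the two alleles.
    """

    chrom: str
    composition: tuple[int, int, int]
    positions: list[int]
    identical_vectors: bool

    @property
    def n_members(self) -> int:
        return len(self.positions)

    @property
    def span(self) -> tuple[int, int]:
        return (self.positions[0], self.positions[-1])


def minor_dosage(genotypes: np.ndarray) -> np.ndarray:
    """Per-sample dosage of the minor allele (0/1/2, -1 for missing or
    haploid), orienting so the first allele is minor (ties -> ALT)."""
    d = np.full(len(genotypes), -1, dtype=np.int8)
    d[genotypes == HOM_REF] = 0
    d[genotypes == HET] = 1
    d[genotypes == HOM_ALT] = 2
    called = d >= 0
    n_alt = int(d[called].sum())
    n_ref = int(2 * called.sum() - n_alt)
    if n_alt > n_ref:
        d[called] = 2 - d[called]
    return d


def _composition_key(dosage: np.ndarray) -> tuple[int, int, int]:
    return (int((dosage == 2).sum()), int((dosage == 1).sum()), int((dosage == 0).sum()))


def _vectors_identical(dosages: list[np.ndarray]) -> bool:
    first = dosages[0]
    return all(np.array_equal(first, d) for d in dosages[1:])


def find_bands(
    records: Sequence[VariantRecord],
    min_members: int = 10,
    max_span: int = 1_000_000,
) -> list[CompositionBand]:
    """Group one chromosome's polymorphic variants into composition bands.

    Members of a band need not be contiguous — monomorphic or
    different-composition variants interleave freely.  Within a
    composition, variants are segmented greedily so a band never spans more
    than ``max_span`` bases; groups smaller than ``min_members`` are
    dropped.
    """
    chroms = {r.chrom for r in records}
    if len(chroms) > 1:
        raise ValueError(f"band scan expects one chromosome, got {sorted(chroms)}")
    by_comp: dict[tuple[int, int, int], list[tuple[int, np.ndarray]]] = {}
    for rec in records:
        d = minor_dosage(rec.genotypes)
        key = _composition_key(d)
        if key[0] == 0 and key[1] == 0:  # monomorphic
            continue
        by_comp.setdefault(key, []).append((rec.pos, d))
    bands = []
    for key, members in by_comp.items():
        members.sort(key=lambda t: t[0])
        start_idx = 0
        for i in range(1, len(members) + 1):
            if i == len(members) or members[i][0] - members[start_idx][0] > max_span:
                chunk = members[start_idx:i]
                if len(chunk) >= min_members:
                    bands.append(
                        CompositionBand(
                            chrom=next(iter(chroms)),
                            composition=key,
                            positions=[p for p, _ in chunk],
                            identical_vectors=_vectors_identical([d for _, d in chunk]),
                        )
                    )
                start_idx = i
    bands.sort(key=lambda b: (b.positions[0], -b.n_members))
    return bands


def two_haplotype_consistent(
    matrix: np.ndarray,
) -> tuple[bool, tuple[np.ndarray, np.ndarray] | None]:
    """Whether two haplotypes h1, h2 explain every row of a genotype
    matrix (individuals x variants, entries = dosage 0/1/2, -1 missing).

    True iff there exist binary haplotypes such that each individual's row
    equals h1+h1, h1+h2 or h2+h2.  Rows with missing entries are excluded
    (logged); a single-variant matrix is trivially consistent (warned).
    Returns the two haplotypes on success; when every individual is
    heterozygous everywhere the phase is ambiguous and a complementary pair
    is returned.
    """
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[1] < 1:
        raise ValueError("need a 2-D individuals x variants matrix")
    complete = ~(matrix < 0).any(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("two-haplotype check: dropped %d rows with missing entries", n_dropped)
    rows = matrix[complete]
    if rows.shape[1] == 1:
        logger.warning("two-haplotype check on a single variant is trivially consistent")
    if rows.shape[0] == 0:
        return True, None
    hom = rows[~(rows == 1).any(axis=1)]  # rows homozygous at every variant
    het = rows[(rows == 1).any(axis=1)]
    hom_haps = np.unique(hom // 2, axis=0) if len(hom) else np.empty((0, rows.shape[1]), dtype=rows.dtype)
    if len(hom_haps) > 2:
        return False, None
    if len(het) == 0:
        if len(hom_haps) == 0:
            return True, None
        h1 = hom_haps[0]
        h2 = hom_haps[1] if len(hom_haps) == 2 else h1
        return True, (h1, h2)
    # all heterozygous rows must share one dosage pattern r with h1 + h2 = r
    r = het[0]
    if not (het == r).all():
        return False, None
    if len(hom_haps) == 2:
        h1, h2 = hom_haps
        ok = np.array_equal(h1 + h2, r)
        return (True, (h1, h2)) if ok else (False, None)
    if len(hom_haps) == 1:
        h1 = hom_haps[0]
        h2 = r - h1
        if ((h2 == 0) | (h2 == 1)).all():
            return True, (h1, h2)
        return False, None
    # no homozygote anywhere: any shared dosage row r splits as h1 + h2
    # (0 -> 0+0, 1 -> 0+1, 2 -> 1+1), so this case is always consistent
    h1 = (r == 2).astype(rows.dtype)
    h2 = (r - h1).astype(rows.dtype)
    return True, (h1, h2)
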