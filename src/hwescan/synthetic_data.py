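"""Synthetic genome generator.

Emits VCF + BED annotation tracks + a per-variant truth table with the
statistical structure the scan assumes: a Hardy-Weinberg baseline with a
large monomorphic fraction, hemizygous males on the X, and the
genotyping-error mechanisms that generate disequilibrium in sequence data —
null alleles (homozygote misclassification, reduced depth, missingness),
collapsed segmental duplications (false heterozygotes, doubled depth),
fixed divergent duplications (100% heterozygosity) and two-haplotype LD
bands.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .qc_pipeline import HG19_PAR, X_NAMES
from .variant_io import (
    HAP_ALT,
    HAP_REF,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    AnnotationTrack,
    VariantRecord,
    write_sex_table,
    write_vcf,
)

__all__ = [
    "MechanismBlock",
    "GeneratorConfig",
    "SyntheticGenome",
    "gen_hwe_variant",
    "apply_null_allele",
    "gen_collapsed_duplication",
    "gen_fixed_divergent_dup",
    "gen_band_region",
    "gen_genome",
    "default_config",
]

MECH_HWE = "hwe"
MECH_NULL = "null_allele"
MECH_DUP = "dup_collapse"
MECH_FIXED = "fixed_divergent_dup"
MECH_BAND = "band"

_BASES = ("A", "C", "G", "T")


@dataclass
class MechanismBlock:
    """A genomic interval (half-open, 0-based) carrying one error mechanism.

    ``params`` per mechanism: null_allele -> {'r': null-allele frequency,
    'maf': minor frequency among non-null alleles}; dup_collapse ->
    {'maf1', 'maf2'}: second-copy and original-copy minor frequencies;
    fixed_divergent_dup -> none; band -> {'hap_freq'} or {'composition':
    (n_minor_hom, n_het, n_major_hom)} plus optional 'n_filler'.
    ``track`` places the interval on the emitted segdup or repeat BED.
    """

    chrom: str
    start: int
    end: int
    mechanism: str
    n_variants: int
    params: dict = field(default_factory=dict)
    track: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"degenerate block interval {self.chrom}:{self.start}-{self.end}")


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic genome.

    Defaults mirror the cohort the analysis is designed around: 104
    individuals (56 males, 48 females), an 85% monomorphic fraction, and a
    total read depth per variant around 18,000 (the scale of the observed
    per-chromosome medians), drawn from a negative binomial and scaled by
    mechanism multipliers.  The folded MAF spectrum of polymorphic baseline
    variants is Beta(0.5, 2) scaled to (0, 0.5] — low-MAF-heavy, as
    sequencing panels are.
    """

    n_individuals: int = 104
    n_males: int = 56
    n_females: int = 48
    chrom_lengths: dict = field(default_factory=dict)
    chrom_variants: dict = field(default_factory=dict)
    monomorphic_fraction: float = 0.85
    maf_beta: tuple[float, float] = (0.5, 2.0)
    missing_rate: float = 0.002
    variable_missingness: float = 0.0  # if > 0: per-variant miss rate ~ U(0, value)
    error_with_missingness: float = 0.0  # het misclassification prob = value * miss rate
    depth_mean: float = 18_000.0
    depth_dispersion: float = 100.0
    dup_depth_multiplier: float = 2.0
    blocks: list[MechanismBlock] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, v in (
            ("monomorphic_fraction", self.monomorphic_fraction),
            ("missing_rate", self.missing_rate),
        ):
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_males + self.n_females != self.n_individuals:
            raise ValueError("n_males + n_females must equal n_individuals")
        for b in self.blocks:
            if b.chrom not in self.chrom_lengths:
                raise ValueError(f"block chromosome {b.chrom!r} not in chrom_lengths")
            if b.end > self.chrom_lengths[b.chrom]:
                raise ValueError(f"block {b.chrom}:{b.start}-{b.end} exceeds chromosome length")


def gen_hwe_variant(n: int, maf: float, rng: np.random.Generator) -> np.ndarray:
    """Genotype dosages of n individuals under HWE at the given minor
    allele frequency: two independent allele draws per individual, i.e.
    the (q^2, 2pq, p^2) trinomial."""
    if not 0 <= maf <= 0.5:
        raise ValueError("maf must be in [0, 0.5]")
    return rng.binomial(2, maf, size=n).astype(np.int8)


def apply_null_allele(
    n: int, maf: float, r: float, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    """Observed genotypes at a tri-allelic locus with a null allele.

    Alleles: A (freq maf*(1-r)), B (freq (1-maf)*(1-r)), null (freq r).
    A/null and B/null carriers are misclassified as homozygotes, null/null
    individuals yield no call; the returned depth factor is the fraction of
    allele copies that produce reads (1 when r = 0).
    """
    if not 0 <= r < 1:
        raise ValueError("null-allele frequency must be in [0, 1)")
    probs = [(1 - maf) * (1 - r), maf * (1 - r), r]  # B, A, null
    alleles = rng.choice(3, size=(n, 2), p=probs)
    n_null = (alleles == 2).sum(axis=1)
    dosage_a = (alleles == 1).sum(axis=1)
    obs = np.empty(n, dtype=np.int8)
    obs[n_null == 2] = MISSING
    carrier = n_null == 1
    obs[carrier] = np.where(dosage_a[carrier] == 1, 2, 0)  # A/null -> hom-A, B/null -> hom-B
    clean = n_null == 0
    obs[clean] = dosage_a[clean]
    depth_factor = float((2 - n_null).sum() / (2 * n))
    return obs, depth_factor


def gen_collapsed_duplication(
    n: int, maf1: float, maf2: float, rng: np.random.Generator
) -> np.ndarray:
    """Observed genotypes at a collapsed duplicated site.

    Each individual carries four allele copies (two per paralog, minor
    frequencies maf1 and maf2, independent); the caller sees a heterozygote
    whenever both alleles occur among the four copies, so double
    homozygotes of opposite type are typed heterozygous and heterozygosity
    is inflated.  Depth at such sites is doubled by the collapsed reads
    (applied by the genome assembler, not here).
    """
    minor = rng.binomial(2, maf1, size=n) + rng.binomial(2, maf2, size=n)
    obs = np.full(n, HET, dtype=np.int8)
    obs[minor == 0] = 0
    obs[minor == 4] = 2
    return obs


def gen_fixed_divergent_dup(n: int) -> np.ndarray:
    """The extreme duplication artifact: the two paralogs are fixed for
    different alleles, every individual is typed heterozygous (sample MAF
    exactly 0.5, maximal disequilibrium)."""
    return np.full(n, HET, dtype=np.int8)


def gen_band_region(
    n_variants: int,
    n: int,
    rng: np.random.Generator,
    hap_freq: float | None = None,
    composition: tuple[int, int, int] | None = None,
    n_filler: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Genotype matrix of a two-haplotype LD band plus monomorphic filler.

    Individuals are random pairs of two haplotypes that differ at every
    member variant, so all members share one genotypic composition and
    identical genotype vectors.  Either ``hap_freq`` (frequency of the
    minor haplotype) or an exact ``composition`` (n_minor_hom, n_het,
    n_major_hom) may be given.  Returns (members: n x n_variants,
    filler: n x n_filler all hom-ref).
    """
    if composition is not None:
        if sum(composition) != n:
            raise ValueError("composition must sum to the number of individuals")
        dosage = np.repeat(np.array([2, 1, 0], dtype=np.int8), composition)
        dosage = rng.permutation(dosage)
    else:
        if hap_freq is None:
            raise ValueError("need hap_freq or composition")
        dosage = rng.binomial(2, hap_freq, size=n).astype(np.int8)
    members = np.tile(dosage[:, None], (1, n_variants))
    filler = np.zeros((n, n_filler), dtype=np.int8)
    return members, filler


@dataclass
class SyntheticGenome:
    """In-memory synthetic dataset: records, sample sexes, truth table and
    annotation tracks, with writers for the on-disk layout."""

    samples: list[str]
    sex: dict[str, str]
    records: list[VariantRecord]
    truth: pd.DataFrame
    segdup: AnnotationTrack
    repeats: AnnotationTrack
    config: GeneratorConfig
    seed: int

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": outdir / "data.vcf",
            "sex": outdir / "sex.tsv",
            "segdup": outdir / "segdup.bed",
            "repeats": outdir / "repeats.bed",
            "truth": outdir / "truth.tsv",
            "config": outdir / "config.json",
        }
        write_vcf(self.records, self.samples, paths["vcf"], contigs=self.config.chrom_lengths)
        write_sex_table(self.sex, paths["sex"])
        for track, key in ((self.segdup, "segdup"), (self.repeats, "repeats")):
            with open(paths[key], "w") as fh:
                for chrom, start, end in track.intervals():
                    fh.write(f"{chrom}\t{start}\t{end}\n")
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        echo = dataclasses.asdict(self.config)
        echo["seed"] = self.seed
        with open(paths["config"], "w") as fh:
            json.dump(echo, fh, indent=2, default=str)
        return paths


def _unique_positions(rng: np.random.Generator, lo: int, hi: int, k: int) -> np.ndarray:
    """k distinct 1-based positions in (lo, hi] (lo, hi 0-based half-open)."""
    span = hi - lo
    if k > span:
        raise ValueError(f"cannot place {k} distinct positions in a span of {span}")
    pool = np.array([], dtype=np.int64)
    while len(pool) < k:
        draw = rng.integers(lo + 1, hi + 1, size=2 * (k - len(pool)) + 16)
        pool = np.unique(np.concatenate([pool, draw]))
    return rng.permutation(pool)[:k]


def _is_x(chrom: str) -> bool:
    return chrom in X_NAMES


def gen_genome(config: GeneratorConfig, seed: int) -> SyntheticGenome:
    """Assemble the full synthetic dataset.

    Baseline variants are placed uniformly per chromosome (a configurable
    fraction monomorphic, the rest HWE at Beta-distributed MAF); mechanism
    blocks place their variants inside their declared intervals, which are
    emitted on the corresponding BED track.  Non-PAR X variants make males
    hemizygous; X variants inside the hg19 PARs stay diploid.  Per-variant
    total read depth is negative-binomial around the configured mean times
    the mechanism multiplier and the called fraction.
    """
    rng = np.random.default_rng(seed)
    n = config.n_individuals
    samples = [f"S{i:04d}" for i in range(n)]
    sex = {
        s: ("male" if i < config.n_males else "female") for i, s in enumerate(samples)
    }
    male_mask = np.array([sex[s] == "male" for s in samples])

    segdup = AnnotationTrack("segdup")
    repeats = AnnotationTrack("repeats")
    site_rows: list[dict] = []  # staged per-variant state, sorted later

    def stage(chrom, pos, mechanism, dosage, maf, f_sign, region_id, depth_factor=1.0, hemizygous=False):
        site_rows.append(
            dict(
                chrom=chrom,
                pos=int(pos),
                mechanism=mechanism,
                dosage=dosage,
                maf=maf,
                expected_f_sign=f_sign,
                region_id=region_id,
                depth_factor=depth_factor,
                hemizygous=hemizygous,
            )
        )

    chrom_order = list(config.chrom_lengths)
    for chrom in chrom_order:
        length = config.chrom_lengths[chrom]
        n_base = int(config.chrom_variants.get(chrom, 0))
        if n_base:
            positions = _unique_positions(rng, 0, length, n_base)
            mono = rng.random(n_base) < config.monomorphic_fraction
            mafs = np.where(
                mono, 0.0, 0.5 * rng.beta(*config.maf_beta, size=n_base)
            )
            on_x = _is_x(chrom)
            for pos, maf in zip(positions, mafs):
                in_par = on_x and any(s <= pos - 1 < e for _, s, e in HG19_PAR)
                hemi = on_x and not in_par
                if maf == 0.0:
                    dosage = np.zeros(n, dtype=np.int8)
                elif hemi:
                    dosage = np.empty(n, dtype=np.int8)
                    dosage[male_mask] = rng.binomial(1, maf, size=male_mask.sum())
                    dosage[~male_mask] = rng.binomial(2, maf, size=(~male_mask).sum())
                else:
                    dosage = gen_hwe_variant(n, maf, rng)
                stage(chrom, pos, MECH_HWE, dosage, float(maf), 0, "", hemizygous=hemi)

    for bi, block in enumerate(config.blocks):
        region_id = f"{block.mechanism}_{bi}"
        if block.track == "segdup":
            segdup.add(block.chrom, block.start, block.end)
        elif block.track == "repeat":
            repeats.add(block.chrom, block.start, block.end)
        if block.mechanism == MECH_BAND:
            n_filler = int(block.params.get("n_filler", block.n_variants))
            members, filler = gen_band_region(
                block.n_variants,
                n,
                rng,
                hap_freq=block.params.get("hap_freq"),
                composition=block.params.get("composition"),
                n_filler=n_filler,
            )
            positions = _unique_positions(rng, block.start, block.end, block.n_variants + n_filler)
            member_pos = positions[: block.n_variants]
            for j, pos in enumerate(member_pos):
                stage(block.chrom, pos, MECH_BAND, members[:, j].copy(), math.nan, +1, region_id)
            for pos in positions[block.n_variants :]:
                stage(block.chrom, pos, MECH_HWE, np.zeros(n, dtype=np.int8), 0.0, 0, region_id)
            continue
        positions = _unique_positions(rng, block.start, block.end, block.n_variants)
        for pos in positions:
            if block.mechanism == MECH_NULL:
                maf = float(block.params.get("maf", 0.3))
                dosage, dfac = apply_null_allele(n, maf, float(block.params["r"]), rng)
                stage(block.chrom, pos, MECH_NULL, dosage, maf, +1, region_id, depth_factor=dfac)
            elif block.mechanism == MECH_DUP:
                maf1 = float(block.params.get("maf1", 0.3))
                maf2 = float(block.params.get("maf2", 0.3))
                dosage = gen_collapsed_duplication(n, maf1, maf2, rng)
                stage(
                    block.chrom, pos, MECH_DUP, dosage, maf1, -1, region_id,
                    depth_factor=config.dup_depth_multiplier,
                )
            elif block.mechanism == MECH_FIXED:
                stage(
                    block.chrom, pos, MECH_FIXED, gen_fixed_divergent_dup(n), 0.5, -1,
                    region_id, depth_factor=config.dup_depth_multiplier,
                )
            else:
                raise ValueError(f"unknown mechanism {block.mechanism!r}")

    site_rows.sort(key=lambda r: (chrom_order.index(r["chrom"]), r["pos"]))

    records: list[VariantRecord] = []
    truth_rows: list[dict] = []
    disp = config.depth_dispersion
    for i, row in enumerate(site_rows):
        dosage = row["dosage"]
        # baseline and coupled missingness
        if config.variable_missingness > 0:
            miss_rate = float(rng.uniform(0, config.variable_missingness))
        else:
            miss_rate = config.missing_rate
        miss = rng.random(n) < miss_rate
        if config.error_with_missingness > 0 and row["mechanism"] == MECH_HWE:
            flip = (dosage == 1) & (rng.random(n) < config.error_with_missingness * miss_rate)
            if flip.any():
                dosage = dosage.copy()
                dosage[flip] = 2 * rng.integers(0, 2, size=int(flip.sum())).astype(np.int8)
        codes = dosage.copy()
        if row["hemizygous"]:
            codes = codes.copy()
            codes[male_mask] = np.where(dosage[male_mask] > 0, HAP_ALT, HAP_REF)
        codes[miss | (dosage == MISSING)] = MISSING
        called_frac = float((codes != MISSING).mean())
        mean_depth = max(config.depth_mean * row["depth_factor"] * called_frac, 1.0)
        depth = int(rng.negative_binomial(disp, disp / (disp + mean_depth)))
        ref, alt = rng.choice(4, size=2, replace=False)
        records.append(
            VariantRecord(
                chrom=row["chrom"],
                pos=row["pos"],
                rsid=f"rs{i + 1:08d}",
                ref=_BASES[ref],
                alt=_BASES[alt],
                genotypes=codes,
                depth=depth,
            )
        )
        truth_rows.append(
            dict(
                chrom=row["chrom"],
                pos=row["pos"],
                rsid=f"rs{i + 1:08d}",
                mechanism=row["mechanism"],
                maf=row["maf"],
                expected_f_sign=row["expected_f_sign"],
                region_id=row["region_id"],
            )
        )
    truth = pd.DataFrame(truth_rows)
    return SyntheticGenome(samples, sex, records, truth, segdup, repeats, config, seed)


def default_config(scale: float = 1.0) -> GeneratorConfig:
    """The default synthetic study: four 50-Mb autosomes plus an X, ~50k
    baseline variants, and one block per error mechanism (two-haplotype
    band on chr1, null alleles inside a repeat region on chr2, collapsed
    duplications and fixed divergent sites inside segmental-duplication
    regions on chr3/chr4).  ``scale`` shrinks variant counts for quick
    runs; mechanism blocks keep at least 10 variants."""

    def s(k: int) -> int:
        return max(int(round(k * scale)), 10)

    return GeneratorConfig(
        chrom_lengths={
            "chr1": 50_000_000,
            "chr2": 50_000_000,
            "chr3": 50_000_000,
            "chr4": 50_000_000,
            "chrX": 155_270_560,
        },
        chrom_variants={
            "chr1": s(12_000),
            "chr2": s(12_000),
            "chr3": s(12_000),
            "chr4": s(9_000),
            "chrX": s(5_000),
        },
        blocks=[
            MechanismBlock(
                "chr1", 45_000_000, 45_500_000, MECH_BAND, s(329),
                params={"composition": (3, 4, 97)},
            ),
            MechanismBlock(
                "chr2", 10_000_000, 11_000_000, MECH_NULL, s(300),
                params={"r": 0.2, "maf": 0.3}, track="repeat",
            ),
            MechanismBlock(
                "chr3", 20_000_000, 21_000_000, MECH_DUP, s(300),
                params={"maf1": 0.3, "maf2": 0.3}, track="segdup",
            ),
            MechanismBlock(
                "chr4", 30_000_000, 30_200_000, MECH_FIXED, s(60), track="segdup",
            ),
        ],
    )
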