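"""Reading and writing the formats the scan touches.

VCF genotypes are read through cyvcf2; BED annotation tracks are held as
interval trees; sample-sex tables and per-variant results are plain TSV.
Only bi-allelic SNVs enter the analysis — multi-allelic and non-SNV records
are skipped and counted, never split.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
from cyvcf2 import VCF
from intervaltree import IntervalTree

from .hwe_core import GenotypeCounts, XGenotypeCounts

logger = logging.getLogger(__name__)

# per-sample genotype codes
HOM_REF = 0
HET = 1
HOM_ALT = 2
HAP_REF = 3
HAP_ALT = 4
MISSING = -1

_GT_STRINGS = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", HAP_REF: "0", HAP_ALT: "1", MISSING: "./."}

MALE = "male"
FEMALE = "female"


@dataclass
class VariantRecord:
    """One bi-allelic variant: site fields plus per-sample genotype codes.

    ``genotypes`` is an int8 array over samples using the module-level codes
    (diploid 0/1/2, haploid 3/4, missing -1); ``depth`` is the INFO DP —
    the total read depth summed over samples — when present.
    """

    chrom: str
    pos: int  # 1-based
    rsid: str | None
    ref: str
    alt: str
    genotypes: np.ndarray
    depth: int | None = None

    @property
    def n_samples(self) -> int:
        return len(self.genotypes)

    @property
    def n_missing(self) -> int:
        return int((self.genotypes == MISSING).sum())

    @property
    def missing_fraction(self) -> float:
        return self.n_missing / self.n_samples if self.n_samples else math.nan


@dataclass
class AnnotationTrack:
    """A named set of genomic intervals (half-open, 0-based), e.g. the
    segmental-duplication or simple-tandem-repeat annotation."""

    name: str
    trees: dict[str, IntervalTree] = field(default_factory=dict)

    def add(self, chrom: str, start: int, end: int) -> None:
        if start >= end:
            raise ValueError(f"degenerate interval {chrom}:{start}-{end}")
        self.trees.setdefault(chrom, IntervalTree()).addi(start, end)

    def __len__(self) -> int:
        return sum(len(t) for t in self.trees.values())

    def intervals(self) -> list[tuple[str, int, int]]:
        out = []
        for chrom in sorted(self.trees):
            out.extend((chrom, iv.begin, iv.end) for iv in sorted(self.trees[chrom]))
        return out


def in_track(track: AnnotationTrack, chrom: str, pos: int) -> bool:
    """Whether the 1-based variant position falls in any track interval.

    BED intervals are half-open and 0-based, so the variant base is pos-1:
    a variant at the first base of an interval is inside, one at the end
    coordinate is outside.
    """
    tree = track.trees.get(chrom)
    return bool(tree is not None and tree.overlaps(pos - 1))


def read_bed(path: str | Path, name: str | None = None) -> AnnotationTrack:
    """Read a BED3+ file into an annotation track.

    Lines with start >= end are rejected with a logged warning; ``track``,
    ``browser`` and ``#`` comment lines are ignored.
    """
    path = Path(path)
    track = AnnotationTrack(name or path.stem)
    n_bad = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                n_bad += 1
                continue
            track.add(chrom, start, end)
    if n_bad:
        logger.warning("%s: rejected %d BED lines with start >= end", path, n_bad)
    return track


def read_sex_table(path: str | Path) -> dict[str, str]:
    """Two-column TSV (sample id, M/F) -> {sample: 'male'|'female'}."""
    table: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sample, sex = line.split("\t")[:2]
            sex = sex.strip().lower()
            if sex in ("m", "male", "1"):
                table[sample] = MALE
            elif sex in ("f", "female", "2"):
                table[sample] = FEMALE
            else:
                raise ValueError(f"unrecognized sex {sex!r} for sample {sample!r}")
    return table


def write_sex_table(sex: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample, s in sex.items():
            fh.write(f"{sample}\t{'M' if s == MALE else 'F'}\n")


class VcfReader:
    """Iterate bi-allelic SNV records of a VCF as :class:`VariantRecord`.

    Multi-allelic and non-SNV records are skipped; ``counters`` reports how
    many, alongside parse failures.  Both ``/`` and ``|`` genotype
    separators are accepted and phasing is discarded; haploid calls map to
    the haploid codes.
    """

    def __init__(self, path: str | Path, region: str | None = None):
        self.path = str(path)
        self.region = region
        vcf = VCF(self.path)
        self.samples: list[str] = list(vcf.samples)
        vcf.close()
        self.counters = {"multiallelic_skipped": 0, "non_snv_skipped": 0, "malformed_skipped": 0}

    def __iter__(self) -> Iterator[VariantRecord]:
        vcf = VCF(self.path, gts012=False)
        try:
            it = vcf(self.region) if self.region else vcf
            for v in it:
                if len(v.ALT) != 1:
                    self.counters["multiallelic_skipped"] += 1
                    continue
                if len(v.REF) != 1 or len(v.ALT[0]) != 1:
                    self.counters["non_snv_skipped"] += 1
                    continue
                try:
                    codes = self._codes(v.genotypes)
                except Exception:
                    self.counters["malformed_skipped"] += 1
                    logger.warning("malformed record at %s:%d skipped", v.CHROM, v.POS)
                    continue
                depth = v.INFO.get("DP")
                yield VariantRecord(
                    chrom=v.CHROM,
                    pos=v.POS,
                    rsid=v.ID,
                    ref=v.REF,
                    alt=v.ALT[0],
                    genotypes=codes,
                    depth=int(depth) if depth is not None else None,
                )
        finally:
            vcf.close()

    @staticmethod
    def _codes(genotypes: list[list]) -> np.ndarray:
        codes = np.empty(len(genotypes), dtype=np.int8)
        for i, gt in enumerate(genotypes):
            alleles = [a for a in gt[:-1] if a is not None]  # last entry = phased flag
            if len(alleles) == 1:
                a = alleles[0]
                codes[i] = MISSING if a < 0 else (HAP_ALT if a == 1 else HAP_REF)
            elif len(alleles) == 2:
                a, b = alleles
                if a < 0 or b < 0:
                    codes[i] = MISSING
                else:
                    codes[i] = {0: HOM_REF, 1: HET, 2: HOM_ALT}[a + b]
            else:
                raise ValueError(f"unsupported ploidy {len(alleles)}")
        return codes


def read_vcf(path: str | Path, region: str | None = None) -> VcfReader:
    """Open a VCF for streaming; see :class:`VcfReader`."""
    if not Path(path).exists():
        raise FileNotFoundError(path)
    return VcfReader(path, region)


def genotype_counts(
    record: VariantRecord,
    sex: Mapping[str, str] | None = None,
    samples: list[str] | None = None,
    chrom_class: str = "autosome",
    diagnostics: dict[str, int] | None = None,
) -> GenotypeCounts | XGenotypeCounts:
    """Tally a record into minor-allele-oriented genotype counts.

    Autosomal class: diploid calls counted, haploid calls treated as
    missing.  X class: male haploid calls and male homozygous-diploid calls
    (the common convention for male X genotypes) tally as hemizygous; a
    heterozygous diploid male X call is set missing and recorded in
    ``diagnostics['male_x_het']``.
    """
    g = record.genotypes
    if chrom_class == "autosome":
        n_missing = int(((g == MISSING) | (g == HAP_REF) | (g == HAP_ALT)).sum())
        return GenotypeCounts.from_unoriented(
            int((g == HOM_REF).sum()), int((g == HET).sum()), int((g == HOM_ALT).sum()), n_missing
        )
    if chrom_class != "X":
        raise ValueError(f"unknown chromosome class {chrom_class!r}")
    if sex is None or samples is None:
        raise ValueError("X-chromosome counting requires a sex table and sample list")
    missing_sex = [s for s in samples if s not in sex]
    if missing_sex:
        raise ValueError(f"samples absent from sex table: {missing_sex[:5]}")
    m_ref = m_alt = f_hom_ref = f_het = f_hom_alt = n_missing = 0
    for code, sample in zip(g, samples):
        if code == MISSING:
            n_missing += 1
        elif sex[sample] == MALE:
            if code in (HAP_REF, HOM_REF):
                m_ref += 1
            elif code in (HAP_ALT, HOM_ALT):
                m_alt += 1
            else:  # heterozygous diploid male X call
                n_missing += 1
                if diagnostics is not None:
                    diagnostics["male_x_het"] = diagnostics.get("male_x_het", 0) + 1
        else:
            if code == HOM_REF:
                f_hom_ref += 1
            elif code == HET:
                f_het += 1
            elif code == HOM_ALT:
                f_hom_alt += 1
            else:  # haploid female call: no convention, treat as missing
                n_missing += 1
    return XGenotypeCounts.from_unoriented(m_ref, m_alt, f_hom_ref, f_het, f_hom_alt, n_missing)


def write_vcf(
    records: Iterable[VariantRecord],
    samples: list[str],
    path: str | Path,
    contigs: Mapping[str, int] | None = None,
) -> None:
    """Write records as an uncompressed VCF 4.2 with GT per sample and the
    total read depth in INFO DP."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=hwescan\n")
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth over all samples">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for rec in records:
            info = f"DP={rec.depth}" if rec.depth is not None else "."
            gts = "\t".join(_GT_STRINGS[int(c)] for c in rec.genotypes)
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t{rec.rsid or '.'}\t{rec.ref}\t{rec.alt}\t.\t.\t{info}\tGT\t{gts}\n"
            )


RESULT_COLUMNS = [
    "chrom",
    "pos",
    "rsid",
    "maf",
    "n_missing",
    "p_std",
    "p_mid",
    "f",
    "in_segdup",
    "in_repeat",
    "status",
    "miss_frac",
    "depth",
]


def write_results(rows: Iterable, path: str | Path) -> None:
    """Write per-variant scan results as TSV, one row per variant.

    p-values are written with full double precision (repr), since the
    extreme tail — transformed p-values of 10-30 and beyond — is exactly
    what the scan is looking at; monomorphic rows leave the p fields empty.
    """

    def fmt(x) -> str:
        if x is None:
            return ""
        if isinstance(x, float):
            return "" if math.isnan(x) else repr(x)
        if isinstance(x, (bool, np.bool_)):
            return "1" if x else "0"
        return str(x)

    with open(path, "w") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for r in rows:
            fh.write("\t".join(fmt(getattr(r, c)) for c in RESULT_COLUMNS) + "\n")
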