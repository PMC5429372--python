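"""The genome-scan analysis: variant filtering, per-variant exact testing
with PAR-aware test selection on the X, and the descriptive summaries used
to stratify disequilibrium by chromosome, region, missingness, read depth
and annotation membership."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import hwe_core
from .hwe_core import STATUS_MONOMORPHIC, STATUS_TESTED
from .variant_io import AnnotationTrack, VariantRecord, genotype_counts, in_track

__all__ = [
    "ScanConfig",
    "FilterReport",
    "VariantResult",
    "filter_variants",
    "run_scan",
    "results_frame",
    "bonferroni_threshold",
    "chromosome_summary",
    "region_summary",
    "missingness_bin_summary",
    "dp_decile_summary",
    "stratified_rates",
    "alpha_sweep",
]

# hg19 pseudo-autosomal regions of the X, half-open 0-based spans.
# Variants inside these diploid regions are tested with the autosomal test.
HG19_PAR = (("PAR1", 60000, 2_699_520), ("PAR2", 154_931_043, 155_260_560))

X_NAMES = {"X", "chrX", "x", "chrx", "23", "chr23"}


@dataclass
class ScanConfig:
    """Scan parameters.

    alpha: significance level for the summaries (0.001, the HapMap
    exclusion level, by default).  missing_threshold: variants with a
    missing-call fraction strictly above it are excluded (default 5%).
    use_mid: summarize on the mid p-value rather than the standard exact p.
    par_regions: half-open 0-based X intervals treated as diploid.
    """

    alpha: float = 0.001
    missing_threshold: float = 0.05
    use_mid: bool = True
    par_regions: tuple = HG19_PAR
    missingness_bin_width: float = 0.02
    alpha_grid: tuple = tuple(np.logspace(-2, -12, 21))

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 <= self.missing_threshold <= 1:
            raise ValueError("missing threshold must be in [0, 1]")

    def in_par(self, pos: int) -> bool:
        p0 = pos - 1
        return any(start <= p0 < end for _, start, end in self.par_regions)


@dataclass
class FilterReport:
    """Counts of variants dropped by each exclusion rule, applied in order:
    no RS identifier, duplicated identifier, shared base-pair position,
    missingness above threshold."""

    n_input: int = 0
    n_no_rsid: int = 0
    n_dup_rsid: int = 0
    n_dup_pos: int = 0
    n_high_missing: int = 0
    n_retained: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def filter_variants(
    records: Iterable[VariantRecord], config: ScanConfig | None = None
) -> tuple[list[VariantRecord], FilterReport]:
    """Apply the database exclusion rules.

    Drops records with no RS identifier; ALL records sharing a duplicated
    identifier; ALL records sharing an identical (chrom, pos); and records
    whose missing fraction strictly exceeds the threshold (exactly at the
    threshold is retained).  Each record is counted under the first rule
    that hits it.
    """
    config = config or ScanConfig()
    records = list(records)
    report = FilterReport(n_input=len(records))
    rsid_counts: dict[str, int] = {}
    pos_counts: dict[tuple[str, int], int] = {}
    for rec in records:
        if rec.rsid:
            rsid_counts[rec.rsid] = rsid_counts.get(rec.rsid, 0) + 1
        key = (rec.chrom, rec.pos)
        pos_counts[key] = pos_counts.get(key, 0) + 1
    kept = []
    for rec in records:
        if not rec.rsid:
            report.n_no_rsid += 1
        elif rsid_counts[rec.rsid] > 1:
            report.n_dup_rsid += 1
        elif pos_counts[(rec.chrom, rec.pos)] > 1:
            report.n_dup_pos += 1
        elif rec.missing_fraction > config.missing_threshold:
            report.n_high_missing += 1
        else:
            kept.append(rec)
    report.n_retained = len(kept)
    return kept, report


@dataclass(frozen=True)
class VariantResult:
    """Per-variant scan row: site identity, test outcome and annotation."""

    chrom: str
    pos: int
    rsid: str | None
    maf: float
    n_missing: int
    miss_frac: float
    depth: int | None
    p_std: float
    p_mid: float
    f: float
    status: str
    test: str  # 'autosomal' | 'x'
    in_segdup: bool = False
    in_repeat: bool = False


def _is_x(chrom: str) -> bool:
    return chrom in X_NAMES


def run_scan(
    records: Iterable[VariantRecord],
    samples: Sequence[str],
    sex: Mapping[str, str] | None = None,
    config: ScanConfig | None = None,
    segdup: AnnotationTrack | None = None,
    repeats: AnnotationTrack | None = None,
    diagnostics: dict[str, int] | None = None,
) -> list[VariantResult]:
    """Test every record and attach annotation membership.

    Autosomes get the autosomal exact test; X variants outside the
    pseudo-autosomal regions get the omnibus X test (which requires the sex
    table); X variants inside a PAR are diploid in both sexes and are
    tested autosomally.  Monomorphic variants are labelled, never tested.
    """
    config = config or ScanConfig()
    samples = list(samples)
    out = []
    for rec in records:
        x_like = _is_x(rec.chrom) and not config.in_par(rec.pos)
        if x_like:
            if sex is None:
                raise ValueError(f"X variant {rec.chrom}:{rec.pos} requires a sex table")
            counts = genotype_counts(rec, sex, samples, chrom_class="X", diagnostics=diagnostics)
            res = hwe_core.test_x(counts)
            kind = "x"
        else:
            counts = genotype_counts(rec, chrom_class="autosome")
            res = hwe_core.test_autosomal(counts)
            kind = "autosomal"
        out.append(
            VariantResult(
                chrom=rec.chrom,
                pos=rec.pos,
                rsid=rec.rsid,
                maf=res.maf,
                n_missing=rec.n_missing,
                miss_frac=rec.missing_fraction,
                depth=rec.depth,
                p_std=res.p_std,
                p_mid=res.p_mid,
                f=res.f,
                status=res.status,
                test=kind,
                in_segdup=in_track(segdup, rec.chrom, rec.pos) if segdup else False,
                in_repeat=in_track(repeats, rec.chrom, rec.pos) if repeats else False,
            )
        )
    return out


def results_frame(results: Iterable[VariantResult]) -> pd.DataFrame:
    """Scan results as a DataFrame (one row per variant)."""
    df = pd.DataFrame([r.__dict__ for r in results])
    if df.empty:
        df = pd.DataFrame(columns=list(VariantResult.__dataclass_fields__))
    return df


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Genome-wide significance line -log10(alpha / m) for m tests."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return -math.log10(alpha / m)


def _p_col(config: ScanConfig) -> str:
    return "p_mid" if config.use_mid else "p_std"


def _summary_row(df: pd.DataFrame, scope: str, config: ScanConfig) -> dict:
    """Table-style descriptive row for one scope of variants."""
    n = len(df)
    poly = df[df["status"] == STATUS_TESTED]
    n_poly = len(poly)
    row = {
        "scope": scope,
        "n_variants": n,
        "n_polymorphic": n_poly,
        "pct_monomorphic": 100.0 * (df["status"] == STATUS_MONOMORPHIC).sum() / n if n else math.nan,
        "pct_significant": math.nan,
        "pct_het_excess": math.nan,
        "median_f": math.nan,
        "median_dp": math.nan,
        "fold_enrichment": math.nan,
    }
    if n_poly:
        sig = poly[poly[_p_col(config)] < config.alpha]
        row["pct_significant"] = 100.0 * len(sig) / n_poly
        row["fold_enrichment"] = row["pct_significant"] / (100.0 * config.alpha)
        if len(sig):
            row["pct_het_excess"] = 100.0 * (sig["f"] < 0).sum() / len(sig)
        row["median_f"] = float(poly["f"].median())
        if poly["depth"].notna().any():
            row["median_dp"] = float(poly["depth"].median())
    return row


def chromosome_summary(
    results: Iterable[VariantResult] | pd.DataFrame, config: ScanConfig | None = None
) -> pd.DataFrame:
    """Per-chromosome descriptive statistics plus autosome-wide and
    genome-wide rows: variant count, % monomorphic, % significant among
    polymorphic at the configured alpha, % of significant due to
    heterozygote excess (f < 0), medians of f and read depth, and the
    fold-enrichment of the significant rate over alpha."""
    config = config or ScanConfig()
    df = results if isinstance(results, pd.DataFrame) else results_frame(results)
    rows = [_summary_row(sub, chrom, config) for chrom, sub in df.groupby("chrom", sort=True)]
    autosomal = df[~df["chrom"].isin(X_NAMES)]
    if len(autosomal):
        rows.append(_summary_row(autosomal, "autosomes", config))
    rows.append(_summary_row(df, "genome", config))
    return pd.DataFrame(rows)


def region_summary(
    results: Iterable[VariantResult] | pd.DataFrame,
    regions: Sequence[tuple[str, str, int, int]],
    config: ScanConfig | None = None,
) -> pd.DataFrame:
    """Descriptive rows for named regions (name, chrom, start, end in
    half-open 0-based coordinates) and their complements.  An empty region
    is flagged via n_variants = 0."""
    config = config or ScanConfig()
    df = results if isinstance(results, pd.DataFrame) else results_frame(results)
    rows = []
    for name, chrom, start, end in regions:
        inside = df[(df["chrom"] == chrom) & (df["pos"] - 1 >= start) & (df["pos"] - 1 < end)]
        outside = df.drop(inside.index)
        rows.append(_summary_row(inside, name, config))
        rows.append(_summary_row(outside, f"outside_{name}", config))
    return pd.DataFrame(rows)


def missingness_bin_summary(
    results: Iterable[VariantResult] | pd.DataFrame,
    config: ScanConfig | None = None,
    bin_width: float | None = None,
) -> pd.DataFrame:
    """% significant among polymorphic variants per missingness bin.

    Expects results scanned WITHOUT the missingness filter, so the bins
    above the exclusion threshold are populated.  Bins are half-open
    [k*w, (k+1)*w) on the missing-call fraction; empty bins are omitted.
    """
    config = config or ScanConfig()
    w = bin_width if bin_width is not None else config.missingness_bin_width
    df = results if isinstance(results, pd.DataFrame) else results_frame(results)
    poly = df[df["status"] == STATUS_TESTED].copy()
    poly["bin"] = (poly["miss_frac"] / w).astype(int)
    rows = []
    for b, sub in poly.groupby("bin", sort=True):
        n_sig = int((sub[_p_col(config)] < config.alpha).sum())
        rows.append(
            {
                "bin_low": b * w,
                "bin_high": (b + 1) * w,
                "n_polymorphic": len(sub),
                "pct_significant": 100.0 * n_sig / len(sub),
            }
        )
    return pd.DataFrame(rows)


def dp_decile_summary(
    results: Iterable[VariantResult] | pd.DataFrame, config: ScanConfig | None = None
) -> pd.DataFrame:
    """% significant per read-depth decile, split by sign of f.

    Deciles are over the polymorphic variants' total read depth; with fewer
    than 10 distinct depths coarser quantile groups are formed (warned).
    """
    config = config or ScanConfig()
    df = results if isinstance(results, pd.DataFrame) else results_frame(results)
    poly = df[(df["status"] == STATUS_TESTED) & df["depth"].notna()].copy()
    if poly.empty:
        return pd.DataFrame(
            columns=["decile", "n_polymorphic", "mean_depth", "pct_sig_het_excess", "pct_sig_het_deficiency"]
        )
    n_distinct = poly["depth"].nunique()
    if n_distinct < 10:
        warnings.warn(f"only {n_distinct} distinct depth values; using coarser quantile groups")
    poly["decile"] = pd.qcut(poly["depth"].rank(method="first"), q=min(10, n_distinct), labels=False)
    pcol = _p_col(config)
    rows = []
    for d, sub in poly.groupby("decile", sort=True):
        sig = sub[sub[pcol] < config.alpha]
        rows.append(
            {
                "decile": int(d),
                "n_polymorphic": len(sub),
                "mean_depth": float(sub["depth"].mean()),
                "pct_sig_het_excess": 100.0 * (sig["f"] < 0).sum() / len(sub),
                "pct_sig_het_deficiency": 100.0 * (sig["f"] > 0).sum() / len(sub),
            }
        )
    return pd.DataFrame(rows)


def stratified_rates(
    results: Iterable[VariantResult] | pd.DataFrame,
    track_col: str,
    config: ScanConfig | None = None,
) -> dict[str, float]:
    """Significant rate among polymorphic variants inside vs outside an
    annotation stratum (``track_col`` is 'in_segdup' or 'in_repeat'), and
    the inside/outside ratio (NaN when a stratum is empty)."""
    config = config or ScanConfig()
    df = results if isinstance(results, pd.DataFrame) else results_frame(results)
    poly = df[df["status"] == STATUS_TESTED]
    pcol = _p_col(config)
    out: dict[str, float] = {}
    for label, sub in (("inside", poly[poly[track_col]]), ("outside", poly[~poly[track_col]])):
        out[f"{label}_rate"] = (
            float((sub[pcol] < config.alpha).mean()) if len(sub) else math.nan
        )
        out[f"n_{label}"] = len(sub)
    r_in, r_out = out["inside_rate"], out["outside_rate"]
    out["ratio"] = r_in / r_out if (r_out and not math.isnan(r_in)) else math.nan
    return out


def alpha_sweep(
    results: Iterable[VariantResult] | pd.DataFrame,
    config: ScanConfig | None = None,
    alphas: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Share of significant variants lying inside the union of the
    annotation tracks, as a function of the significance threshold."""
    config = config or ScanConfig()
    alphas = list(alphas) if alphas is not None else list(config.alpha_grid)
    df = results if isinstance(results, pd.DataFrame) else results_frame(results)
    poly = df[df["status"] == STATUS_TESTED]
    pcol = _p_col(config)
    in_union = poly["in_segdup"] | poly["in_repeat"]
    rows = []
    for a in alphas:
        sig = poly[pcol] < a
        n_sig = int(sig.sum())
        rows.append(
            {
                "alpha": a,
                "n_significant": n_sig,
                "pct_inside_tracks": 100.0 * (sig & in_union).sum() / n_sig if n_sig else math.nan,
            }
        )
    return pd.DataFrame(rows)
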