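"""Filtering rules, PAR-aware test selection, and the summary statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import make_record
from hwescan import qc_pipeline as qp
from hwescan import variant_io as vio


def _genotypes(n, n_missing=0, het=0, hom_alt=0):
    g = np.zeros(n, dtype=np.int8)
    g[:hom_alt] = vio.HOM_ALT
    g[hom_alt : hom_alt + het] = vio.HET
    g[n - n_missing :] = vio.MISSING
    return g


class TestFilterVariants:
    def test_identical_positions_both_dropped(self):
        records = [
            make_record(pos=100, rsid="rs1"),
            make_record(pos=100, rsid="rs2"),
            make_record(pos=200, rsid="rs3"),
        ]
        kept, report = qp.filter_variants(records)
        assert [r.rsid for r in kept] == ["rs3"]
        assert report.n_dup_pos == 2

    def test_duplicated_identifiers_all_dropped(self):
        records = [
            make_record(pos=100, rsid="rsX"),
            make_record(pos=200, rsid="rsX"),
            make_record(pos=300, rsid="rs3"),
        ]
        kept, report = qp.filter_variants(records)
        assert [r.rsid for r in kept] == ["rs3"] and report.n_dup_rsid == 2

    def test_no_identifier_dropped(self):
        kept, report = qp.filter_variants([make_record(rsid=None)])
        assert not kept and report.n_no_rsid == 1

    def test_missingness_rule_is_strictly_greater_than(self):
        # 6/104 = 5.77% missing -> dropped; 5/104 = 4.81% -> retained;
        # exactly 5% -> retained
        records = [
            make_record(pos=1, rsid="rs1", genotypes=_genotypes(104, n_missing=6)),
            make_record(pos=2, rsid="rs2", genotypes=_genotypes(104, n_missing=5)),
            make_record(pos=3, rsid="rs3", genotypes=_genotypes(100, n_missing=5)),
        ]
        kept, report = qp.filter_variants(records)
        assert [r.rsid for r in kept] == ["rs2", "rs3"]
        assert report.n_high_missing == 1


class TestRunScan:
    def test_par_variants_get_the_autosomal_test(self, small_genome):
        sex = {"a": "male", "b": "female"}
        par1 = make_record(chrom="chrX", pos=100_000, rsid="rs1",
                           genotypes=np.array([vio.HET, vio.HET], dtype=np.int8))
        nonpar = make_record(chrom="chrX", pos=50_000_000, rsid="rs2",
                             genotypes=np.array([vio.HAP_ALT, vio.HET], dtype=np.int8))
        results = qp.run_scan([par1, nonpar], ["a", "b"], sex=sex)
        assert results[0].test == "autosomal" and results[1].test == "x"

    def test_x_without_sex_table_is_hard_error(self):
        rec = make_record(chrom="chrX", pos=50_000_000,
                          genotypes=np.array([vio.HET], dtype=np.int8))
        with pytest.raises(ValueError, match="sex table"):
            qp.run_scan([rec], ["a"])

    def test_monomorphic_labelled_polymorphic_tested(self):
        mono = make_record(pos=1, rsid="rs1", genotypes=_genotypes(50))
        poly = make_record(pos=2, rsid="rs2", genotypes=_genotypes(50, het=10, hom_alt=2))
        r_mono, r_poly = qp.run_scan([mono, poly], [f"s{i}" for i in range(50)])
        assert r_mono.status == "monomorphic" and math.isnan(r_mono.p_mid)
        assert r_poly.status == "tested" and 0 < r_poly.p_mid <= 1

    def test_scan_is_deterministic_to_the_byte(self, small_genome, tmp_path):
        out1, out2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        for out in (out1, out2):
            kept, _ = qp.filter_variants(small_genome.records)
            results = qp.run_scan(kept, small_genome.samples, sex=small_genome.sex,
                                  segdup=small_genome.segdup, repeats=small_genome.repeats)
            vio.write_results(results, out)
        assert out1.read_bytes() == out2.read_bytes()


class TestBonferroni:
    def test_genome_wide_line(self):
        # 12,133,408 polymorphic autosomal tests at alpha = 0.05
        assert round(qp.bonferroni_threshold(0.05, 12_133_408), 1) == 8.4

    def test_single_test_reduces_to_alpha(self):
        assert qp.bonferroni_threshold(0.05, 1) == pytest.approx(1.301, abs=5e-4)
        assert qp.bonferroni_threshold(1.0, 10) == pytest.approx(1.0)


def _result(chrom="chr1", pos=1, status="tested", p=0.5, f=0.01, depth=18_000,
            miss=0.0, segdup=False, repeat=False):
    return qp.VariantResult(chrom, pos, f"rs{chrom}_{pos}", 0.2, 0, miss, depth,
                           p, p, f, status, "autosomal", segdup, repeat)


def _fixture_results():
    """850 monomorphic + 150 polymorphic of which 15 significant (9 excess)."""
    rows = [_result(pos=i, status="monomorphic", p=math.nan, f=math.nan) for i in range(850)]
    rows += [_result(pos=1000 + i, p=1e-5, f=-0.5) for i in range(9)]
    rows += [_result(pos=2000 + i, p=1e-5, f=0.5) for i in range(6)]
    rows += [_result(pos=3000 + i, p=0.4, f=0.01) for i in range(135)]
    return rows


class TestSummaries:
    def test_chromosome_summary_arithmetic(self):
        df = qp.chromosome_summary(_fixture_results(), qp.ScanConfig(alpha=0.001))
        row = df[df["scope"] == "chr1"].iloc[0]
        assert row["n_variants"] == 1000
        assert row["pct_monomorphic"] == pytest.approx(85.0)
        assert row["pct_significant"] == pytest.approx(10.0)
        assert row["pct_het_excess"] == pytest.approx(60.0)
        # fold-enrichment is %sig over the chance expectation 100*alpha
        assert row["fold_enrichment"] == pytest.approx(row["pct_significant"] / 0.1)

    def test_fold_enrichment_matches_headline_rate(self):
        # 62 significant of 10,000 polymorphic at alpha=0.001: 0.62%, 6.2x chance
        rows = [_result(pos=i, p=1e-5, f=-0.1) for i in range(62)]
        rows += [_result(pos=100 + i, p=0.5) for i in range(9938)]
        row = qp.chromosome_summary(rows, qp.ScanConfig(alpha=0.001)).iloc[0]
        assert row["pct_significant"] == pytest.approx(0.62)
        assert row["fold_enrichment"] == pytest.approx(6.2)

    def test_all_monomorphic_scope_undefined(self):
        rows = [_result(pos=i, status="monomorphic", p=math.nan, f=math.nan) for i in range(10)]
        row = qp.chromosome_summary(rows).iloc[0]
        assert math.isnan(row["pct_significant"]) and math.isnan(row["median_f"])

    def test_region_summary_partitions_counts(self):
        rows = _fixture_results()
        df = qp.region_summary(rows, [("left", "chr1", 0, 1500)])
        inside = df[df["scope"] == "left"].iloc[0]
        outside = df[df["scope"] == "outside_left"].iloc[0]
        assert inside["n_variants"] + outside["n_variants"] == len(rows)
        assert inside["n_variants"] > 0 and outside["n_variants"] > 0

    def test_empty_region_flagged(self):
        df = qp.region_summary(_fixture_results(), [("void", "chr9", 0, 100)])
        assert df[df["scope"] == "void"].iloc[0]["n_variants"] == 0

    def test_planted_deficiency_region_enriched(self, small_scan, small_genome):
        _, df, _ = small_scan
        block = next(b for b in small_genome.config.blocks if b.mechanism == "dup_collapse")
        summary = qp.region_summary(df, [("dup", block.chrom, block.start, block.end)])
        inside = summary[summary["scope"] == "dup"].iloc[0]
        outside = summary[summary["scope"] == "outside_dup"].iloc[0]
        # other mechanism blocks elsewhere in the genome keep the outside
        # rate above the pure-HWE level; the planted region still dominates
        assert inside["pct_significant"] > 5 * outside["pct_significant"]


class TestMissingnessBins:
    def test_no_missingness_collapses_to_one_bin(self):
        df = qp.missingness_bin_summary([_result(pos=i) for i in range(20)])
        assert len(df) == 1 and df.iloc[0]["bin_low"] == 0.0

    def test_bins_partition_polymorphic_variants(self):
        rows = [_result(pos=i, miss=m) for i, m in enumerate([0.0, 0.01, 0.03, 0.21, 0.50])]
        df = qp.missingness_bin_summary(rows, bin_width=0.02)
        assert df["n_polymorphic"].sum() == len(rows)

    def test_error_missingness_coupling_gives_rising_then_falling_trend(self):
        from hwescan import synthetic_data as sd

        config = sd.GeneratorConfig(
            chrom_lengths={"chr1": 10_000_000},
            chrom_variants={"chr1": 4000},
            monomorphic_fraction=0.0,
            maf_beta=(2.0, 2.0),
            variable_missingness=0.95,
            error_with_missingness=0.8,
        )
        genome = sd.gen_genome(config, seed=3)
        results = qp.run_scan(genome.records, genome.samples, sex=genome.sex)
        df = qp.missingness_bin_summary(results, bin_width=0.10)
        rates = df.assign(b=(df["bin_low"] / 0.10).round().astype(int)).set_index("b")[
            "pct_significant"
        ]
        # misclassification scales with missingness: upper-mid bins beat the
        # clean bins, and once most calls are missing the shrinking sample
        # size erodes power and the rate falls back
        assert rates.loc[4] > rates.loc[0]
        assert rates.loc[3] > rates.loc[1]
        assert rates.loc[9] < rates.loc[5]


class TestDepthAndStrata:
    def test_constant_depth_collapses_with_warning(self):
        rows = [_result(pos=i, depth=100) for i in range(30)]
        with pytest.warns(UserWarning, match="distinct depth"):
            df = qp.dp_decile_summary(rows)
        assert len(df) == 1 and df.iloc[0]["n_polymorphic"] == 30

    def test_depth_deciles_partition_and_localize_mechanisms(self, small_scan):
        _, df, _ = small_scan
        dec = qp.dp_decile_summary(df)
        poly = df[(df["status"] == "tested") & df["depth"].notna()]
        assert dec["n_polymorphic"].sum() == len(poly)
        # doubled-depth duplication artifacts (f < 0) land in the top decile,
        # reduced-depth null alleles (f > 0) in the low deciles
        top, bottom = dec.iloc[-1], dec.iloc[:3]
        assert top["pct_sig_het_excess"] > dec.iloc[:-1]["pct_sig_het_excess"].max()
        assert bottom["pct_sig_het_deficiency"].max() > dec.iloc[5:]["pct_sig_het_deficiency"].max()

    def test_null_configuration_rates_match_inside_and_outside(self):
        rng = np.random.default_rng(0)
        rows = [
            _result(pos=i, p=rng.uniform(), segdup=bool(i % 2)) for i in range(4000)
        ]
        out = qp.stratified_rates(rows, "in_segdup", qp.ScanConfig(alpha=0.05))
        assert out["inside_rate"] == pytest.approx(out["outside_rate"], abs=0.03)

    def test_planted_artifacts_inflate_inside_rate(self, small_scan):
        _, df, _ = small_scan
        out = qp.stratified_rates(df, "in_segdup")
        assert out["ratio"] > 5

    def test_empty_stratum_gives_nan_ratio(self):
        rows = [_result(pos=i, segdup=False) for i in range(5)]
        assert math.isnan(qp.stratified_rates(rows, "in_segdup")["ratio"])

    def test_alpha_sweep_share_non_decreasing_with_planted_artifacts(self, small_scan):
        _, df, _ = small_scan
        sweep = qp.alpha_sweep(df).dropna(subset=["pct_inside_tracks"])
        shares = sweep.sort_values("alpha", ascending=False)["pct_inside_tracks"].to_numpy()
        # artifacts accumulate in the tail of the p distribution: the
        # inside-track share rises as alpha shrinks, up to finite-sample
        # jitter at the loose end of the grid
        assert (np.diff(shares) >= -2.0).all()
        assert shares[-1] > shares[0] + 20 and shares[-1] > 95
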