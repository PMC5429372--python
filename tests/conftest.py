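import numpy as np
import pytest

from hwescan import qc_pipeline, synthetic_data, variant_io


@pytest.fixture(scope="session")
def small_genome():
    """A scaled-down synthetic genome with every mechanism block."""
    config = synthetic_data.default_config(scale=0.05)
    return synthetic_data.gen_genome(config, seed=11)


@pytest.fixture(scope="session")
def small_scan(small_genome):
    """Filtered scan of the small genome, with truth merged in."""
    kept, report = qc_pipeline.filter_variants(small_genome.records)
    results = qc_pipeline.run_scan(
        kept,
        small_genome.samples,
        sex=small_genome.sex,
        segdup=small_genome.segdup,
        repeats=small_genome.repeats,
    )
    df = qc_pipeline.results_frame(results).merge(
        small_genome.truth[["chrom", "pos", "mechanism", "region_id"]], on=["chrom", "pos"]
    )
    return results, df, report


def make_record(chrom="chr1", pos=100, rsid="rs1", genotypes=None, depth=1000, n=10):
    """Hand-built VariantRecord for pipeline fixtures."""
    if genotypes is None:
        genotypes = np.zeros(n, dtype=np.int8)
    return variant_io.VariantRecord(
        chrom=chrom,
        pos=pos,
        rsid=rsid,
        ref="A",
        alt="C",
        genotypes=np.asarray(genotypes, dtype=np.int8),
        depth=depth,
    )
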