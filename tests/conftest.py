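import pytest

from peaklink import (
    AnalysisParameters,
    ChromSizes,
    GenomicInterval,
    SimulationConfig,
    TranscriptModel,
    simulate_study,
)


@pytest.fixture
def sizes():
    return ChromSizes({"chr1": 10_000_000, "chr2": 10_000_000})


@pytest.fixture
def toy_gene():
    """Plus-strand coding gene: tss 10_000, two exons, CDS [10_100, 12_300)."""
    return TranscriptModel(
        gene_symbol="TOY1",
        transcript_id="TX_TOY1",
        chrom="chr1",
        strand="+",
        exons=[
            GenomicInterval("chr1", 10_000, 10_200),
            GenomicInterval("chr1", 12_000, 12_500),
        ],
        cds_start=10_100,
        cds_end=12_300,
    )


@pytest.fixture(scope="session")
def small_config():
    """Down-scaled study: fast enough for per-test reuse, same structure."""
    return SimulationConfig(
        seed=7,
        n_chroms=2,
        chrom_length=3_000_000,
        n_genes=120,
        n_peaks_per_condition=400,
        shared_fraction=0.75,
        n_replicates=3,
        depth=60_000,
        peak_enrichment=5.0,
        n_dar=30,
        dar_log2fc=3.0,
        deg_count=60,
        deg_linked_fraction=0.8,
        cistrome_count=120,
        cistrome_overlap_fraction=0.5,
        peak_free_zone=900_000,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture
def default_params():
    return AnalysisParameters()
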