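import pandas as pd
import pytest


@pytest.fixture
def small_reads() -> pd.DataFrame:
    """Hand-built read table: 3 exonic reads (2 duplicates), 2 intronic."""
    return pd.DataFrame(
        {
            "sample_id": ["s1", "s1", "s1", "s1", "s2"],
            "gene_id": ["gA", "gA", "gA", "gB", "gA"],
            "chrom": ["chr1"] * 5,
            "position": [100, 100, 150, 300, 100],
            "strand": ["+"] * 5,
            "umi": ["ACGT", "ACGT", "ACGT", "TTTT", "ACGT"],
            "region_flag": ["exon", "exon", "exon", "intron", "intron"],
        }
    )


@pytest.fixture
def toy_counts() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "s1": [10, 20, 30, 0, 40],
            "s2": [20, 40, 60, 0, 80],
            "s3": [12, 18, 33, 1, 36],
        },
        index=[f"g{i}" for i in range(5)],
    )
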