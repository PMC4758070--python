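import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def static_counts():
    """Small single-condition count table: two genes, three variants."""
    return pd.DataFrame(
        {
            "sample_id": ["s1", "s1", "s1"],
            "variant_id": ["rs1", "rs2", "rs3"],
            "gene_id": ["gA", "gA", "gB"],
            "ref_count": [12, 30, 8],
            "alt_count": [28, 10, 9],
        }
    )


@pytest.fixture
def icd_counts():
    """Small paired-condition count table."""
    return pd.DataFrame(
        {
            "sample_id": ["s1", "s1", "s1"],
            "variant_id": ["rs1", "rs2", "rs3"],
            "gene_id": ["gA", "gA", "gB"],
            "ref_count_U": [20, 25, 30],
            "alt_count_U": [20, 25, 28],
            "ref_count_T": [35, 40, 31],
            "alt_count_T": [8, 12, 30],
        }
    )
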