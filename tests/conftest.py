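from pathlib import Path

import pandas as pd
import pytest

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def snp_table() -> pd.DataFrame:
    """Published SNP variant-calling confusion counts and metrics for a human
    benchmark sample at coverages 20-90x, under six quantization settings."""
    return pd.read_csv(DATA_DIR / "snp_counts.tsv", sep="\t")


@pytest.fixture(scope="session")
def indel_table() -> pd.DataFrame:
    """Published INDEL confusion counts and metrics for the same benchmark.

    Note: the printed precision column derives from query-side TP counts and
    is not recomputable from the truth-side TP/FP printed here; tests check
    recall from counts and F1 from the printed precision/recall pair.
    """
    return pd.read_csv(DATA_DIR / "indel_counts.tsv", sep="\t")


@pytest.fixture()
def two_record_fastq_text() -> str:
    return (
        "@read1 desc\n"
        "ACGTACGTAC\n"
        "+\n"
        "!+5?IIII~~\n"
        "@read2\n"
        "GGGGG\n"
        "+read2\n"
        ";;;;;\n"
    )
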