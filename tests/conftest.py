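import numpy as np
import pandas as pd
import pytest

from stemtrace import AbundanceMatrix, make_sample_meta


@pytest.fixture
def two_day_matrix():
    """3 proteins x 6 samples (days 0 and 3, three replicates each), no missing."""
    values = pd.DataFrame(
        {
            "d0_r1": [10.0, 5.0, 1.0],
            "d0_r2": [10.0, 5.0, 2.0],
            "d0_r3": [10.0, 5.0, 3.0],
            "d3_r1": [0.0, 5.0, 4.0],
            "d3_r2": [0.0, 5.0, 5.0],
            "d3_r3": [0.0, 5.0, 6.0],
        },
        index=pd.Index(["PA", "PB", "PC"], name="protein_id"),
    )
    missing = pd.DataFrame(False, index=values.index, columns=values.columns)
    peptides = pd.Series([4, 3, 5], index=values.index, name="unique_peptides")
    matrix = AbundanceMatrix(values, missing, peptides)
    meta = make_sample_meta(
        values.columns, [0, 0, 0, 3, 3, 3], [1, 2, 3, 1, 2, 3]
    )
    return matrix, meta


@pytest.fixture
def timecourse_meta():
    """Metadata for 5 days x 3 replicates with the standard sample naming."""
    days = [0, 3, 5, 7, 10]
    sample_ids = [f"d{d}_r{r}" for d in days for r in (1, 2, 3)]
    return make_sample_meta(
        sample_ids,
        [d for d in days for _ in range(3)],
        [r for _ in days for r in (1, 2, 3)],
    )
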