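"""Reading, writing and preprocessing of abundance matrices.

The preprocessing chain mirrors standard label-free quantitation practice:
keep master proteins supported by enough unique peptides, treat unobserved
entries as structural zeros, and fix each sample's scale by dividing by the
median of its nonzero intensities.

TSV dialect
-----------
The matrix file is tab-separated with a ``protein_id`` index column, an
optional ``unique_peptides`` column, and one column per sample.  Missing
entries are encoded as an empty cell, ``NA`` or ``NaN``.  The metadata file
has columns ``sample_id``, ``day``, ``replicate``, ``condition``.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix, validate_sample_meta

logger = logging.getLogger(__name__)

__all__ = [
    "read_matrix",
    "write_matrix",
    "filter_master_proteins",
    "replace_missing_with_zero",
    "median_normalize",
    "preprocess",
]

MISSING_TOKENS = ["", "NA", "NaN"]


def read_matrix(matrix_path, meta_path) -> tuple[AbundanceMatrix, pd.DataFrame]:
    """Parse a matrix TSV and its sample-metadata sidecar.

    Empty/NA cells become True entries of the missing mask (value NaN until
    zero replacement).  Every sample column must be annotated in the
    metadata; orphans raise with the offending sample ids.
    """
    df = pd.read_csv(
        Path(matrix_path),
        sep="\t",
        index_col=0,
        keep_default_na=False,
        na_values=MISSING_TOKENS,
    )
    if "unique_peptides" in df.columns:
        peptides = df.pop("unique_peptides")
        if peptides.isna().any():
            raise ValueError("unique_peptides column contains missing values")
        peptides = peptides.astype(int)
    else:
        peptides = pd.Series(0, index=df.index, name="unique_peptides")
    values = df.astype(float)
    missing = values.isna()
    observed = values.to_numpy()[~missing.to_numpy()]
    if observed.size and (observed < 0).any():
        raise ValueError("negative intensity encountered in matrix")
    meta = pd.read_csv(Path(meta_path), sep="\t", index_col="sample_id", dtype={"replicate": str})
    meta = validate_sample_meta(meta, values.columns)
    return AbundanceMatrix(values, missing, peptides), meta


def write_matrix(m: AbundanceMatrix, meta: pd.DataFrame, matrix_path, meta_path=None) -> None:
    """Write a matrix (and optionally its metadata) in the package TSV dialect.

    Entries that are still NaN (masked, pre-replacement) serialize as empty
    cells; after zero replacement the zeros are written as numbers, so a
    round trip preserves the values while the structural-zero mask is only
    recoverable for unreplaced matrices.
    """
    out = m.values.copy()
    out.insert(0, "unique_peptides", m.unique_peptides)
    out.rename_axis("protein_id").to_csv(matrix_path, sep="\t", na_rep="")
    if meta_path is not None:
        meta.rename_axis("sample_id").to_csv(meta_path, sep="\t")


def filter_master_proteins(m: AbundanceMatrix, min_unique_peptides: int = 3) -> AbundanceMatrix:
    """Keep proteins with at least ``min_unique_peptides`` unique peptides.

    The default of 3 encodes the master-protein convention of "more than two
    unique peptides".  Pass 0 to keep everything.
    """
    keep = m.unique_peptides >= min_unique_peptides
    if not keep.any():
        logger.warning("master-protein filter removed every protein")
    kept = keep[keep].index
    return AbundanceMatrix(
        m.values.loc[kept], m.missing.loc[kept], m.unique_peptides.loc[kept]
    )


def replace_missing_with_zero(m: AbundanceMatrix) -> AbundanceMatrix:
    """Set every masked entry to 0, preserving the mask.

    Downstream stages can still distinguish structural zeros via the mask.
    """
    values = m.values.copy()
    values[m.missing] = 0.0
    return AbundanceMatrix(values, m.missing.copy(), m.unique_peptides.copy())


def median_normalize(m: AbundanceMatrix) -> tuple[AbundanceMatrix, pd.Series]:
    """Divide each sample by the median of its nonzero observed entries.

    Zeros (and still-masked NaNs) are excluded from the median, so censoring
    depth does not distort the scale fix; afterwards every sample's nonzero
    median equals 1.  Returns the normalized matrix and the factors applied.
    """
    values = m.values
    factors = {}
    for sid in values.columns:
        col = values[sid]
        nz = col[(col > 0) & col.notna()]
        if nz.empty:
            raise ValueError(f"sample {sid!r} has no nonzero entries to normalize by")
        factors[sid] = float(np.median(nz.to_numpy()))
    factors_s = pd.Series(factors, name="scale_factor").reindex(values.columns)
    normalized = values.div(factors_s, axis=1)
    return (
        AbundanceMatrix(normalized, m.missing.copy(), m.unique_peptides.copy()),
        factors_s,
    )


def preprocess(
    m: AbundanceMatrix,
    min_unique_peptides: int = 3,
    normalize: bool = True,
) -> tuple[AbundanceMatrix, pd.Series]:
    """Full default chain: master-protein filter, zero replacement, normalization."""
    logger.info(
        "preprocess: filter(min_unique_peptides=%d) -> replace_missing -> %s",
        min_unique_peptides,
        "median_normalize" if normalize else "no normalization",
    )
    m = filter_master_proteins(m, min_unique_peptides)
    m = replace_missing_with_zero(m)
    if normalize:
        return median_normalize(m)
    return m, pd.Series(1.0, index=m.sample_ids, name="scale_factor")
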