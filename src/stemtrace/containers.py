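"""Core in-memory containers for label-free proteomics matrices.

The package follows the scanpy/anndata convention of thin dataclasses around
pandas objects: an :class:`AbundanceMatrix` holds a proteins x samples
intensity table together with a boolean missingness mask and per-protein
unique-peptide counts, and sample annotations travel as a plain
``pandas.DataFrame`` indexed by sample id (see :func:`validate_sample_meta`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["AbundanceMatrix", "validate_sample_meta", "make_sample_meta"]

#: columns every sample-metadata frame must carry
META_COLUMNS = ("day", "replicate", "condition")


@dataclass
class AbundanceMatrix:
    """Proteins x samples intensity matrix with missingness bookkeeping.

    Parameters
    ----------
    values
        Non-negative intensities, indexed by protein id (rows) and sample id
        (columns).  Entries flagged in ``missing`` may be NaN until
        :func:`stemtrace.preprocess.replace_missing_with_zero` has run; all
        other entries must be finite and >= 0.
    missing
        Boolean mask, same shape/labels as ``values``; True marks an entry
        that was not observed (left-censored in label-free quantitation).
    unique_peptides
        Per-protein count of unique (and razor) peptides supporting the
        quantification; used by the master-protein filter.
    """

    values: pd.DataFrame
    missing: pd.DataFrame
    unique_peptides: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.unique_peptides is None:
            self.unique_peptides = pd.Series(
                0, index=self.values.index, name="unique_peptides"
            )
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate protein ids: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if not (self.missing.index.equals(idx) and self.missing.columns.equals(cols)):
            raise ValueError("missing mask labels do not match values")
        if not self.unique_peptides.index.equals(idx):
            raise ValueError("unique_peptides index does not match protein ids")
        if (self.unique_peptides < 0).any():
            raise ValueError("unique_peptides must be >= 0")
        vals = self.values.to_numpy(dtype=float)
        mask = self.missing.to_numpy(dtype=bool)
        observed = vals[~mask]
        if observed.size and (~np.isfinite(observed)).any():
            raise ValueError("observed intensities must be finite")
        if observed.size and (observed < 0).any():
            raise ValueError("negative intensities are not allowed")

    # -- convenience -------------------------------------------------------
    @property
    def protein_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(
            self.values.copy(), self.missing.copy(), self.unique_peptides.copy()
        )


def validate_sample_meta(meta: pd.DataFrame, sample_ids) -> pd.DataFrame:
    """Check that ``meta`` annotates exactly the given samples.

    ``meta`` must be indexed by sample id and carry ``day``, ``replicate``
    and ``condition`` columns.  Every sample in ``sample_ids`` must have
    exactly one row; orphan samples are reported by name.
    """
    for col in META_COLUMNS:
        if col not in meta.columns:
            raise ValueError(f"sample metadata lacks required column {col!r}")
    if meta.index.has_duplicates:
        dups = meta.index[meta.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in metadata: {dups}")
    missing = [s for s in sample_ids if s not in meta.index]
    if missing:
        raise ValueError(f"samples absent from metadata: {missing}")
    return meta.loc[list(sample_ids)]


def make_sample_meta(sample_ids, days, replicates, condition="differentiation") -> pd.DataFrame:
    """Assemble a metadata frame from parallel per-sample vectors."""
    condition = (
        [condition] * len(sample_ids) if isinstance(condition, str) else list(condition)
    )
    meta = pd.DataFrame(
        {"day": list(days), "replicate": list(replicates), "condition": condition},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return meta
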