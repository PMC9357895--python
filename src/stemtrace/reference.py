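"""Correlation of a derived proteome against a reference, with influence analysis.

The headline quantity is the Pearson correlation between per-protein mean
abundance vectors of two datasets (e.g. induced cells vs primary cells under
the same culture condition).  Because a single highly discordant protein can
dominate that correlation, every shared protein is removed in turn and the
change in r recorded; the protein with the largest |delta r| is reported as
the top influencer, and the correlation without it is presented alongside
the full correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix, validate_sample_meta

__all__ = [
    "CorrelationReport",
    "mean_abundance_vector",
    "pearson",
    "influence_leave_one_out",
    "compare_conditions",
]


@dataclass
class CorrelationReport:
    """Full and leave-one-out correlations between two mean-abundance vectors."""

    shared_proteins: list
    r_full: float
    influence: pd.Series       # per-protein delta r = r(without) - r_full; NaN if undefined
    top_influencer: str
    r_without_top: float
    label: str = ""


def mean_abundance_vector(
    m: AbundanceMatrix,
    meta: pd.DataFrame,
    condition=None,
    day=None,
) -> pd.Series:
    """Per-protein mean over the samples matching the condition/day selector."""
    meta = validate_sample_meta(meta, m.sample_ids)
    mask = pd.Series(True, index=meta.index)
    if condition is not None:
        mask &= meta["condition"] == condition
    if day is not None:
        mask &= meta["day"] == day
    selected = meta.index[mask]
    if len(selected) == 0:
        raise ValueError(
            f"no samples match selector condition={condition!r}, day={day!r}"
        )
    return m.values[selected].mean(axis=1)


def pearson(x, y) -> float:
    """Product-moment correlation of two equal-length vectors (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be one-dimensional and equally long")
    if x.size < 3:
        raise ValueError("need at least 3 points for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the vectors")
    return float(np.corrcoef(x, y)[0, 1])


def influence_leave_one_out(x, y, ids=None, label: str = "") -> CorrelationReport:
    """Leave-one-protein-out influence on the Pearson correlation.

    For each protein i, recomputes r on the vectors with i removed and
    records ``delta_r_i = r_{-i} - r_full``.  The top influencer is the
    protein with the largest |delta r| (ties break toward the
    lexicographically smaller id); proteins whose removal leaves a
    zero-variance vector get NaN influence and are excluded from the argmax.
    """
    if isinstance(x, pd.Series) and ids is None:
        ids = list(x.index)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 points for leave-one-out influence")
    if ids is None:
        ids = [f"item{i}" for i in range(x.size)]
    ids = list(ids)
    r_full = pearson(x, y)
    deltas = np.full(x.size, np.nan)
    for i in range(x.size):
        xi = np.delete(x, i)
        yi = np.delete(y, i)
        if np.std(xi) == 0 or np.std(yi) == 0:
            continue
        deltas[i] = pearson(xi, yi) - r_full
    influence = pd.Series(deltas, index=pd.Index(ids, name="protein_id"), name="delta_r")
    defined = influence.dropna()
    if defined.empty:
        raise ValueError("influence undefined for every protein")
    # stable argmax with lexicographic tie-break
    best = defined.abs().sort_index().sort_values(ascending=False, kind="mergesort").index[0]
    r_without = r_full + float(influence[best])
    return CorrelationReport(
        shared_proteins=ids,
        r_full=r_full,
        influence=influence,
        top_influencer=str(best),
        r_without_top=r_without,
        label=label,
    )


def compare_conditions(
    derived: AbundanceMatrix,
    derived_meta: pd.DataFrame,
    reference: AbundanceMatrix,
    reference_meta: pd.DataFrame,
    conditions,
    timepoints,
    log: bool = False,
    exclude=None,
) -> list[CorrelationReport]:
    """One influence report per (condition, timepoint).

    For each pair, the derived mean vector over samples of that condition and
    day is correlated with the reference mean vector over samples of the same
    condition (the reference is typically collected at its own fixed day).
    The protein universe is the intersection of proteins with nonzero mean in
    both datasets; ``exclude`` removes named proteins up front (mirroring an
    a-priori exclusion such as vimentin).  ``log=True`` correlates
    log2(x + 1) means instead of raw means.
    """
    exclude = set(exclude or ())
    reports = []
    for cond in conditions:
        ref_vec = mean_abundance_vector(reference, reference_meta, condition=cond)
        for t in timepoints:
            der_vec = mean_abundance_vector(derived, derived_meta, condition=cond, day=t)
            shared = der_vec.index.intersection(ref_vec.index)
            shared = [
                p
                for p in shared
                if der_vec[p] > 0 and ref_vec[p] > 0 and p not in exclude
            ]
            if len(shared) < 3:
                raise ValueError(
                    f"fewer than 3 shared detected proteins for {cond} day {t}"
                )
            a = der_vec[shared]
            b = ref_vec[shared]
            if log:
                a = np.log2(a + 1.0)
                b = np.log2(b + 1.0)
            reports.append(
                influence_leave_one_out(a, b.to_numpy(), ids=shared, label=f"{cond}_day{t}")
            )
    return reports
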