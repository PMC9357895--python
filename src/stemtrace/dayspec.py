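"""Day-specific protein detection via a per-protein z-score statistic.

For protein *j* and day *d*, the statistic compares the day mean to the
protein's overall behaviour across every sample of the time course::

    Z_jd = (<p>_jd - <p>_all) / sigma_j

where ``<p>_jd`` is the mean normalized abundance of protein *j* over the
samples of day *d*, ``<p>_all`` its mean over all samples, and ``sigma_j``
its sample standard deviation (n-1 denominator) over all samples.  A protein
is *specific* to day *d* when ``Z_jd`` exceeds a threshold (default 1.5),
and its *multiplicity* is the number of days it is specific to.  The
threshold scan selects the smallest threshold at which the mean multiplicity
among specific proteins drops to ~1, balancing the number of proteins kept
against how day-exclusive they are.

Over-representation of the resulting protein sets in user-supplied
annotation collections (GMT-style term -> members) is tested with the
one-sided hypergeometric law and Benjamini-Hochberg correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .containers import AbundanceMatrix, validate_sample_meta
from .differential import benjamini_hochberg

__all__ = [
    "DaySpecificityResult",
    "ThresholdScan",
    "zscore_abundance",
    "day_specific_sets",
    "scan_threshold",
    "enrich",
    "read_gmt",
]

DEFAULT_THRESHOLD = 1.5
DEFAULT_GRID = np.round(np.arange(0.5, 3.0 + 1e-9, 0.1), 10)


@dataclass
class DaySpecificityResult:
    """Per-protein, per-day z-scores plus the thresholded summaries."""

    zscores: pd.DataFrame            # proteins x days
    day_means: pd.DataFrame          # proteins x days
    overall_mean: pd.Series          # per protein
    overall_sd: pd.Series            # per protein, n-1 denominator
    threshold: float | None = None
    specific_sets: dict | None = None
    multiplicity: pd.Series | None = None


@dataclass
class ThresholdScan:
    """Threshold grid with specific-protein counts and mean multiplicities."""

    table: pd.DataFrame  # columns: threshold, n_specific, mean_multiplicity
    selected: float
    tol: float
    attained: bool  # False when no grid value met the multiplicity criterion


def zscore_abundance(
    m: AbundanceMatrix, meta: pd.DataFrame, log: bool = False
) -> DaySpecificityResult:
    """Compute Z_jd for every protein and day.

    Operates on the (median-normalized) abundance scale by default; pass
    ``log=True`` to z-score log2(x+1) abundances instead.  Proteins with
    zero overall standard deviation get Z = 0 on every day.
    """
    meta = validate_sample_meta(meta, m.sample_ids)
    days = meta["day"]
    if days.nunique() < 2:
        raise ValueError("need at least two day groups for day specificity")
    values = m.values
    if values.isna().any().any():
        raise ValueError("matrix contains NaN; run replace_missing_with_zero first")
    if log:
        values = np.log2(values + 1.0)
    day_means = values.T.groupby(days).mean().T
    day_means = day_means[sorted(day_means.columns)]
    overall_mean = values.mean(axis=1)
    overall_sd = values.std(axis=1, ddof=1)
    z = day_means.sub(overall_mean, axis=0).div(overall_sd, axis=0)
    z = z.where(overall_sd > 0, 0.0)
    return DaySpecificityResult(
        zscores=z,
        day_means=day_means,
        overall_mean=overall_mean,
        overall_sd=overall_sd,
    )


def day_specific_sets(
    result: DaySpecificityResult, threshold: float = DEFAULT_THRESHOLD
) -> DaySpecificityResult:
    """Threshold the z-scores: protein j is in the day-d set iff Z_jd > threshold.

    Returns a copy of ``result`` with ``threshold``, ``specific_sets`` (day ->
    list of protein ids) and per-protein ``multiplicity`` filled in.  A
    protein may appear in several day sets.
    """
    exceeds = result.zscores > threshold
    sets = {day: list(result.zscores.index[exceeds[day]]) for day in exceeds.columns}
    multiplicity = exceeds.sum(axis=1).rename("multiplicity")
    return replace(
        result, threshold=threshold, specific_sets=sets, multiplicity=multiplicity
    )


def scan_threshold(
    result: DaySpecificityResult,
    grid=DEFAULT_GRID,
    tol: float = 0.05,
) -> ThresholdScan:
    """Scan thresholds and select the smallest with mean multiplicity <= 1 + tol.

    For each grid value, counts proteins specific to at least one day and the
    mean multiplicity among them.  The smallest threshold whose mean
    multiplicity is <= 1 + tol is selected (keeping the most proteins while
    day calls remain essentially exclusive).  If no threshold qualifies, the
    largest grid value is returned with a warning.
    """
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be non-empty and strictly increasing")
    rows = []
    for thr in grid:
        mult = (result.zscores > thr).sum(axis=1)
        spec = mult[mult >= 1]
        rows.append(
            {
                "threshold": float(thr),
                "n_specific": int(len(spec)),
                "mean_multiplicity": float(spec.mean()) if len(spec) else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    ok = table["mean_multiplicity"].le(1.0 + tol) & table["n_specific"].gt(0)
    if ok.any():
        selected = float(table.loc[ok.idxmax(), "threshold"])
        attained = True
    else:
        selected = float(grid[-1])
        attained = False
        warnings.warn(
            "no grid threshold reached mean multiplicity <= 1 + tol; "
            "falling back to the largest grid value",
            stacklevel=2,
        )
    return ThresholdScan(table=table, selected=selected, tol=tol, attained=attained)


def enrich(
    protein_set,
    annotations: dict,
    background,
    min_term_size: int = 1,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of ``protein_set`` in terms.

    ``annotations`` maps term name -> iterable of member ids.  Terms are
    intersected with the background; terms smaller than ``min_term_size``
    after intersection are skipped.  The p-value is the upper-tail
    probability of observing at least the realized overlap when drawing
    ``len(protein_set)`` proteins from the background without replacement;
    Benjamini-Hochberg adjustment is applied across the tested terms.
    """
    background = list(dict.fromkeys(background))
    if not background:
        raise ValueError("background is empty")
    bg = set(background)
    query = list(dict.fromkeys(protein_set))
    if not set(query) <= bg:
        extra = sorted(set(query) - bg)[:5]
        raise ValueError(f"protein set contains ids outside the background: {extra}")
    n_bg, n_set = len(bg), len(query)
    qset = set(query)
    rows = []
    for term, members in annotations.items():
        term_members = set(members) & bg
        if len(term_members) < max(min_term_size, 1):
            continue
        overlap = len(qset & term_members)
        p = float(hypergeom.sf(overlap - 1, n_bg, len(term_members), n_set))
        rows.append(
            {
                "term": term,
                "overlap": overlap,
                "set_size": n_set,
                "term_size": len(term_members),
                "background_size": n_bg,
                "p_value": min(p, 1.0),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["term", "overlap", "set_size", "term_size", "background_size", "p_value"],
    )
    if len(table):
        table["p_adjusted"] = benjamini_hochberg(table["p_value"].to_numpy())
        table = table.sort_values("p_value", kind="mergesort").reset_index(drop=True)
    else:
        table["p_adjusted"] = pd.Series(dtype=float)
    return table


def read_gmt(path) -> dict:
    """Parse a GMT file (term, description, tab-separated member ids)."""
    annotations: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            annotations[parts[0]] = set(p for p in parts[2:] if p)
    return annotations
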