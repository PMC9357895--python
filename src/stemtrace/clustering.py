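"""K-means clustering of combined-replicate temporal abundance profiles.

Each (protein, replicate) pair contributes one row: the protein's per-day
abundance in that replicate, normalized to unit sum (fraction-of-total over
the time course), so clusters group proteins by the *shape* of their
trajectory rather than absolute abundance.  Replicates are pooled into a
single row set before clustering; per-cluster replicate composition then
serves as a concordance diagnostic (exchangeable replicates should
contribute roughly equally to every cluster).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .containers import AbundanceMatrix, validate_sample_meta

logger = logging.getLogger(__name__)

__all__ = [
    "ProfileSet",
    "ClusterModel",
    "build_profiles",
    "kmeans_profiles",
    "replicate_composition",
    "peak_day_clusters",
    "top_shared_proteins",
]


@dataclass
class ProfileSet:
    """Unit-sum temporal profiles, one row per (protein, replicate)."""

    profiles: pd.DataFrame  # MultiIndex (protein_id, replicate) x day columns
    n_dropped: int          # all-zero raw profiles excluded

    @property
    def days(self) -> list:
        return list(self.profiles.columns)

    @property
    def replicates(self) -> list:
        return sorted(self.profiles.index.get_level_values("replicate").unique())


@dataclass
class ClusterModel:
    """Fitted k-means model over a :class:`ProfileSet`."""

    k: int
    assignment: pd.Series    # profile row -> cluster id (0..k-1)
    centroids: pd.DataFrame  # k x days
    inertia: float
    seed: int
    restarts: int


def build_profiles(
    m: AbundanceMatrix, meta: pd.DataFrame, norm: str = "sum"
) -> ProfileSet:
    """Assemble per-(protein, replicate) day profiles from a normalized matrix.

    When a (day, replicate) cell holds several samples their mean is used.
    Rows whose raw profile is all zero are dropped (their shape is
    undefined); the count is logged and recorded.  ``norm`` is ``"sum"``
    (divide by the row total, the default) or ``"max"``.
    """
    if norm not in ("sum", "max"):
        raise ValueError("norm must be 'sum' or 'max'")
    meta = validate_sample_meta(meta, m.sample_ids)
    if m.values.isna().any().any():
        raise ValueError("matrix contains NaN; run replace_missing_with_zero first")
    days = sorted(meta["day"].unique())
    replicates = sorted(meta["replicate"].unique())
    blocks = []
    for rep in replicates:
        rep_samples = meta.index[meta["replicate"] == rep]
        rep_days = meta.loc[rep_samples, "day"]
        present = set(rep_days)
        missing = [d for d in days if d not in present]
        if missing:
            raise ValueError(f"replicate {rep!r} has no samples for days {missing}")
        block = m.values[rep_samples].T.groupby(rep_days).mean().T
        block = block[days]
        block.index = pd.MultiIndex.from_product(
            [block.index, [rep]], names=["protein_id", "replicate"]
        )
        blocks.append(block)
    profiles = pd.concat(blocks)
    totals = profiles.sum(axis=1)
    zero_rows = totals == 0
    n_dropped = int(zero_rows.sum())
    if n_dropped:
        logger.info("build_profiles: dropped %d all-zero profiles", n_dropped)
    profiles = profiles[~zero_rows]
    if norm == "sum":
        profiles = profiles.div(profiles.sum(axis=1), axis=0)
    else:
        profiles = profiles.div(profiles.max(axis=1), axis=0)
    return ProfileSet(profiles=profiles, n_dropped=n_dropped)


def kmeans_profiles(
    p: ProfileSet, k: int = 20, seed: int = 0, restarts: int = 10
) -> ClusterModel:
    """Euclidean k-means on the profiles; best of ``restarts`` runs by inertia.

    Uses k-means++ seeding with a fixed random state, so results are
    deterministic given (seed, restarts).
    """
    n_rows = len(p.profiles)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n_rows:
        raise ValueError(f"k={k} exceeds the number of profile rows ({n_rows})")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=restarts,
        max_iter=300,
        random_state=seed,
    ).fit(p.profiles.to_numpy())
    assignment = pd.Series(km.labels_, index=p.profiles.index, name="cluster")
    centroids = pd.DataFrame(
        km.cluster_centers_, columns=p.profiles.columns,
        index=pd.RangeIndex(k, name="cluster"),
    )
    return ClusterModel(
        k=k,
        assignment=assignment,
        centroids=centroids,
        inertia=float(km.inertia_),
        seed=seed,
        restarts=restarts,
    )


def replicate_composition(model: ClusterModel, p: ProfileSet) -> pd.DataFrame:
    """Per-cluster fraction of member rows contributed by each replicate.

    Rows sum to 1 for non-empty clusters; empty clusters get a zero row (and
    a warning in the log).
    """
    reps = p.replicates
    counts = pd.crosstab(
        model.assignment,
        model.assignment.index.get_level_values("replicate"),
    ).reindex(index=range(model.k), columns=reps, fill_value=0)
    totals = counts.sum(axis=1)
    empty = totals == 0
    if empty.any():
        logger.warning(
            "replicate_composition: empty clusters %s", list(counts.index[empty])
        )
    comp = counts.div(totals.where(totals > 0, 1), axis=0)
    comp.index.name = "cluster"
    return comp


def peak_day_clusters(model: ClusterModel) -> dict:
    """Map each day to the clusters whose centroid peaks there.

    Ties in the centroid maximum break toward the earliest day (columns are
    kept in ascending day order).
    """
    centroid_vals = model.centroids.to_numpy()
    days = list(model.centroids.columns)
    peak_idx = centroid_vals.argmax(axis=1)  # argmax returns the first maximum
    mapping: dict = {d: [] for d in days}
    for cluster, idx in enumerate(peak_idx):
        mapping[days[idx]].append(cluster)
    return mapping


def top_shared_proteins(
    model: ClusterModel,
    p: ProfileSet,
    m: AbundanceMatrix,
    meta: pd.DataFrame,
    cluster: int,
    n: int = 10,
) -> pd.DataFrame:
    """Top-n shared proteins of a cluster, with per-day normalized expression.

    A protein is *shared* when every one of its profile rows (all replicates
    present in the profile set) is assigned to ``cluster``.  Shared proteins
    are ranked by mean abundance over all samples and truncated to ``n``;
    the returned per-day expression is each protein's day-mean divided by
    its maximum day-mean (so exactly one day attains 1).
    """
    meta = validate_sample_meta(meta, m.sample_ids)
    by_protein = model.assignment.groupby(level="protein_id")
    in_cluster = by_protein.apply(lambda s: bool((s == cluster).all()))
    shared = list(in_cluster.index[in_cluster])
    if len(shared) < n:
        logger.info(
            "top_shared_proteins: cluster %s has only %d shared proteins (< %d)",
            cluster, len(shared), n,
        )
    mean_abundance = m.values.loc[shared].mean(axis=1)
    top = mean_abundance.sort_values(ascending=False, kind="mergesort").head(n)
    day_means = m.values.loc[top.index].T.groupby(meta["day"]).mean().T
    day_means = day_means[sorted(day_means.columns)]
    normalized = day_means.div(day_means.max(axis=1), axis=0)
    normalized.insert(0, "mean_abundance", top)
    return normalized
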