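"""Synthetic label-free proteomics data with planted, recoverable ground truth.

Two generators cover the study designs the pipeline analyses:

* :func:`simulate_timecourse` — an LFQ-like intensity matrix over a
  differentiation time course (default days 0, 3, 5, 7, 10 with three
  replicates) with day-specific marker proteins planted as log2 mean shifts,
  left-censored missingness, per-sample scaling distortions and per-protein
  unique-peptide counts.
* :func:`simulate_reference_pair` — a pair of mean-abundance vectors with a
  chosen population correlation and optional discordant outlier proteins,
  emulating the comparison of a derived cell line against a primary-cell
  reference where a single protein (a vimentin analog) dominates the
  disagreement.

Every draw flows from one :class:`numpy.random.Generator` seeded from the
single integer in the config, so identical configs give bitwise-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .containers import AbundanceMatrix, make_sample_meta

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_timecourse",
    "simulate_reference_pair",
    "simulate_condition_pair",
    "write_truth",
]


@dataclass
class SimConfig:
    """Parameters of the time-course generator.

    Log-intensity units are log2 throughout; intensities are emitted on the
    raw (linear) scale.  ``missing_rate_at_median`` is the probability that
    an entry at the global median log2 intensity is censored;
    ``censoring_steepness`` is the logistic rate per log2 unit.
    """

    n_proteins: int = 2000
    days: tuple[int, ...] = (0, 3, 5, 7, 10)
    n_replicates: int = 3
    markers_per_day: int = 50
    marker_effect: float = 2.0
    base_log_mean: float = 20.0
    base_log_sd: float = 2.0
    noise_sd: float = 0.35
    missing_rate_at_median: float = 0.05
    censoring_steepness: float = 1.0
    sample_scale_sd: float = 0.25
    peptide_count_mean: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        days = tuple(self.days)
        object.__setattr__(self, "days", days)
        if self.n_proteins <= 0 or self.n_replicates <= 0 or len(days) == 0:
            raise ValueError("n_proteins, n_replicates and days must be non-empty/positive")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("days must be strictly increasing")
        if self.markers_per_day < 0:
            raise ValueError("markers_per_day must be >= 0")
        if self.markers_per_day * len(days) > self.n_proteins:
            raise ValueError("more planted markers than proteins")
        if not 0.0 <= self.missing_rate_at_median <= 1.0:
            raise ValueError("missing_rate_at_median must be in [0, 1]")
        if self.base_log_sd < 0 or self.noise_sd < 0 or self.sample_scale_sd < 0:
            raise ValueError("scale parameters must be >= 0")
        if self.censoring_steepness <= 0:
            raise ValueError("censoring_steepness must be > 0")
        if self.peptide_count_mean <= 0:
            raise ValueError("peptide_count_mean must be > 0")


@dataclass
class SimTruth:
    """Planted ground truth emitted alongside a simulated dataset."""

    marker_day: dict = field(default_factory=dict)
    archetype: dict = field(default_factory=dict)
    sample_scales: pd.Series | None = None
    outlier_proteins: set = field(default_factory=set)
    target_r: float | None = None
    #: pre-censoring, pre-scaling log2 abundances (time-course runs only)
    log2_true: pd.DataFrame | None = None


def _protein_ids(n: int) -> pd.Index:
    width = max(4, len(str(n)))
    return pd.Index([f"P{i:0{width}d}" for i in range(1, n + 1)], name="protein_id")


def simulate_timecourse(config: SimConfig) -> tuple[AbundanceMatrix, pd.DataFrame, SimTruth]:
    """Draw one LFQ-like differentiation time course.

    Returns the abundance matrix (missing entries as NaN, flagged in the
    mask), the sample metadata frame and the :class:`SimTruth` with marker
    assignments, archetype labels, sample scale factors and the
    pre-censoring log2 matrix.
    """
    rng = np.random.default_rng(config.seed)
    days = list(config.days)
    proteins = _protein_ids(config.n_proteins)
    sample_ids = [f"d{d}_r{r}" for d in days for r in range(1, config.n_replicates + 1)]
    sample_days = [d for d in days for _ in range(config.n_replicates)]
    sample_reps = [r for _ in days for r in range(1, config.n_replicates + 1)]

    # per-protein baseline and marker shifts
    base = rng.normal(config.base_log_mean, config.base_log_sd, size=config.n_proteins)
    order = rng.permutation(config.n_proteins)
    marker_day: dict[str, int] = {}
    archetype: dict[str, str] = {}
    pos = 0
    for d in days:
        for idx in order[pos : pos + config.markers_per_day]:
            marker_day[proteins[idx]] = d
        pos += config.markers_per_day
    for pid in proteins:
        archetype[pid] = (
            f"peak_day{marker_day[pid]}" if pid in marker_day else "flat"
        )

    shift = np.zeros((config.n_proteins, len(sample_ids)))
    day_arr = np.asarray(sample_days)
    for pid, d in marker_day.items():
        i = proteins.get_loc(pid)
        shift[i, day_arr == d] = config.marker_effect

    noise = rng.normal(0.0, config.noise_sd, size=shift.shape)
    log2_true = base[:, None] + shift + noise

    # left-censored missingness: logistic in true log2 intensity, anchored so
    # the censoring probability at the global median equals the configured rate
    if config.missing_rate_at_median > 0:
        med = np.median(log2_true)
        k = config.censoring_steepness
        x0 = med - np.log(1.0 / config.missing_rate_at_median - 1.0) / k
        p_miss = expit(-k * (log2_true - x0))
    else:
        p_miss = np.zeros_like(log2_true)
    missing = rng.random(size=log2_true.shape) < p_miss

    scales = np.exp2(rng.normal(0.0, config.sample_scale_sd, size=len(sample_ids)))
    values = np.exp2(log2_true) * scales[None, :]
    values[missing] = np.nan

    peptides = 1 + rng.poisson(config.peptide_count_mean, size=config.n_proteins)

    values_df = pd.DataFrame(values, index=proteins, columns=sample_ids)
    missing_df = pd.DataFrame(missing, index=proteins, columns=sample_ids)
    peptide_s = pd.Series(peptides, index=proteins, name="unique_peptides")
    matrix = AbundanceMatrix(values_df, missing_df, peptide_s)
    meta = make_sample_meta(sample_ids, sample_days, sample_reps)
    truth = SimTruth(
        marker_day=marker_day,
        archetype=archetype,
        sample_scales=pd.Series(scales, index=sample_ids, name="scale"),
        log2_true=pd.DataFrame(log2_true, index=proteins, columns=sample_ids),
    )
    return matrix, meta, truth


def simulate_reference_pair(
    n_proteins: int,
    target_r: float,
    n_outliers: int = 0,
    outlier_shift: float = 8.0,
    seed: int = 0,
    loc: float = 10.0,
    scale: float = 1.0,
) -> tuple[pd.Series, pd.Series, SimTruth]:
    """Draw two mean-abundance vectors with population correlation ``target_r``.

    Non-outlier entries come from a bivariate normal with the requested
    correlation, centred at ``loc`` (so both vectors are positive for any
    realistic size); each outlier protein receives a discordant shift of
    ``outlier_shift`` in the second vector only.
    """
    if n_proteins < 3:
        raise ValueError("n_proteins must be >= 3")
    if not -1.0 <= target_r <= 1.0:
        raise ValueError("target_r must be in [-1, 1]")
    if n_outliers >= n_proteins:
        raise ValueError("n_outliers must be < n_proteins")
    rng = np.random.default_rng(seed)
    proteins = _protein_ids(n_proteins)
    z1 = rng.normal(size=n_proteins)
    z2 = rng.normal(size=n_proteins)
    a = loc + scale * z1
    b = loc + scale * (target_r * z1 + np.sqrt(1.0 - target_r**2) * z2)
    outliers: set[str] = set()
    if n_outliers:
        idx = rng.choice(n_proteins, size=n_outliers, replace=False)
        b[idx] += outlier_shift
        outliers = {proteins[i] for i in idx}
    vec_a = pd.Series(a, index=proteins, name="derived")
    vec_b = pd.Series(b, index=proteins, name="reference")
    truth = SimTruth(outlier_proteins=outliers, target_r=target_r)
    return vec_a, vec_b, truth


def simulate_condition_pair(
    n_proteins: int = 2000,
    conditions: tuple[str, ...] = ("NM", "OM"),
    timepoints: tuple[int, ...] = (10, 17),
    reference_day: int = 14,
    n_replicates: int = 3,
    target_r: float = 0.6,
    n_outliers: int = 1,
    outlier_shift: float = 8.0,
    replicate_sd: float = 0.2,
    seed: int = 0,
) -> tuple[AbundanceMatrix, pd.DataFrame, AbundanceMatrix, pd.DataFrame, SimTruth]:
    """Build matched derived/reference endpoint matrices from correlated vectors.

    For every (condition, timepoint) pair one correlated vector pair is drawn
    with :func:`simulate_reference_pair`; replicate samples scatter around
    those vectors with sd ``replicate_sd``.  The same outlier proteins are
    reused across pairs, mimicking a single discordant protein in the
    reference comparison.
    """
    rng = np.random.default_rng(seed)
    proteins = _protein_ids(n_proteins)
    outlier_idx = rng.choice(n_proteins, size=n_outliers, replace=False)
    derived_cols: dict[str, np.ndarray] = {}
    derived_meta: list[tuple[str, int, int, str]] = []
    ref_cols: dict[str, np.ndarray] = {}
    ref_meta: list[tuple[str, int, int, str]] = []
    truth = SimTruth(outlier_proteins={proteins[i] for i in outlier_idx}, target_r=target_r)
    loc, scale = 10.0, 1.0
    for cond in conditions:
        # one latent reference proteome per condition; each derived timepoint
        # correlates with it at target_r
        z_ref = rng.normal(size=n_proteins)
        b = loc + scale * z_ref
        b[outlier_idx] += outlier_shift
        for t in timepoints:
            z_t = rng.normal(size=n_proteins)
            a = loc + scale * (target_r * z_ref + np.sqrt(1.0 - target_r**2) * z_t)
            for r in range(1, n_replicates + 1):
                sid = f"{cond}_d{t}_r{r}"
                derived_cols[sid] = np.clip(
                    a + rng.normal(0, replicate_sd, n_proteins), 0, None
                )
                derived_meta.append((sid, t, r, cond))
        for r in range(1, n_replicates + 1):
            sid = f"ref_{cond}_d{reference_day}_r{r}"
            ref_cols[sid] = np.clip(
                b + rng.normal(0, replicate_sd, n_proteins), 0, None
            )
            ref_meta.append((sid, reference_day, r, cond))

    def _assemble(cols, meta_rows):
        vals = pd.DataFrame(cols, index=proteins)
        mask = pd.DataFrame(False, index=proteins, columns=vals.columns)
        pep = pd.Series(3, index=proteins, name="unique_peptides")
        m = AbundanceMatrix(vals, mask, pep)
        ids, days_, reps, conds = zip(*meta_rows)
        return m, make_sample_meta(ids, days_, reps, list(conds))

    derived, dmeta = _assemble(derived_cols, derived_meta)
    reference, rmeta = _assemble(ref_cols, ref_meta)
    return derived, dmeta, reference, rmeta, truth


def write_truth(truth: SimTruth, out_dir) -> None:
    """Write the planted truth as plain TSV files (proteins and samples)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    ids = sorted(set(truth.marker_day) | set(truth.archetype) | truth.outlier_proteins)
    for pid in ids:
        rows.append(
            {
                "protein_id": pid,
                "marker_day": truth.marker_day.get(pid, ""),
                "archetype": truth.archetype.get(pid, ""),
                "outlier": pid in truth.outlier_proteins,
            }
        )
    pd.DataFrame(rows).to_csv(out / "truth_proteins.tsv", sep="\t", index=False)
    if truth.sample_scales is not None:
        truth.sample_scales.rename_axis("sample_id").to_csv(
            out / "truth_sample_scales.tsv", sep="\t"
        )
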