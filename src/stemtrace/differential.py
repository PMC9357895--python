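"""Empirical-Bayes moderated differential abundance on log2 intensities.

The two-group moderated t-statistic shrinks each protein's residual variance
``s_g^2`` (with ``d_g`` residual degrees of freedom) toward a prior variance
``s0^2`` carrying ``d0`` prior degrees of freedom::

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)
    t_g    = logFC_g / (s~_g * sqrt(1/n1 + 1/n2))

with p-values from the t distribution on ``d0 + d_g`` degrees of freedom.
The prior is estimated by moment matching on the log variances: under the
hierarchical model ``s_g^2 ~ s0^2 * F(d_g, d0)``, ``log s_g^2`` has known
mean and variance in terms of digamma/trigamma functions, which are inverted
to recover ``(d0, s0^2)``.  With ``d0 = 0`` the statistic reduces to the
ordinary pooled-variance two-sample t; as ``d0 -> inf`` every protein is
tested against the common variance ``s0^2``.

Benjamini-Hochberg step-up adjustment controls the FDR across proteins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import t as t_dist

from .containers import AbundanceMatrix, validate_sample_meta

__all__ = [
    "EBayesPrior",
    "DifferentialResult",
    "log_transform",
    "benjamini_hochberg",
    "fit_prior",
    "moderated_t_test",
    "volcano_table",
]


@dataclass
class EBayesPrior:
    """Prior degrees of freedom and variance of the hierarchical model."""

    d0: float  # may be math.inf
    s02: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValueError("d0 must be >= 0")
        if not self.s02 > 0:
            raise ValueError("s02 must be > 0")


@dataclass
class DifferentialResult:
    """Volcano-ready per-protein table plus the prior used."""

    table: pd.DataFrame  # log_fc, s2, s2_moderated, t, p_value, p_adjusted, significant
    prior: EBayesPrior
    df_residual: float
    group1: object
    group2: object
    p_cutoff: float
    lfc_cutoff: float


def log_transform(m: AbundanceMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """Entrywise log2(value + pseudocount); zeros map to log2(pseudocount)."""
    if not pseudocount > 0:
        raise ValueError("pseudocount must be > 0")
    if m.values.isna().any().any():
        raise ValueError("matrix contains NaN; run replace_missing_with_zero first")
    return np.log2(m.values + pseudocount)


def benjamini_hochberg(p) -> np.ndarray:
    """Step-up FDR adjustment; returns adjusted p-values in the input order."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def fit_prior(s2, d: float) -> EBayesPrior:
    """Estimate (d0, s0^2) by moment matching on log sample variances.

    ``s2`` are per-protein residual variances sharing ``d`` residual degrees
    of freedom.  Zero variances are excluded from the fit (they carry no
    spread information); if every variance is zero the fit is impossible.
    When the spread of ``log s2`` does not exceed what ``d`` alone implies,
    the prior is degenerate (``d0 = inf``) and all moderated variances
    collapse to ``s0^2``.
    """
    s2 = np.asarray(s2, dtype=float)
    if d < 1:
        raise ValueError("residual degrees of freedom must be >= 1")
    positive = s2[s2 > 0]
    if positive.size == 0:
        raise ValueError("all residual variances are zero; cannot fit a prior")
    if positive.size < 10:
        raise ValueError("need >= 10 positive variances to fit the prior")
    z = np.log(positive)
    e = z - digamma(d / 2.0) + math.log(d / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(polygamma(1, d / 2.0))
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s02 = math.exp(e_mean + float(digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s02 = math.exp(e_mean)
    return EBayesPrior(d0=d0, s02=s02)


def moderated_t_test(
    log_matrix: pd.DataFrame,
    meta: pd.DataFrame,
    group1,
    group2,
    prior="fit",
    p_cutoff: float = 0.05,
    lfc_cutoff: float = 1.0,
) -> DifferentialResult:
    """Two-group moderated t-test between the samples of two day labels.

    ``log_matrix`` is a proteins x samples frame of log2 abundances.
    ``prior`` may be ``"fit"`` (estimate from the data), an
    :class:`EBayesPrior`, or ``None`` / ``EBayesPrior(0, ...)`` for the
    ordinary pooled t-test.  The log fold change is group2 - group1.
    """
    meta = validate_sample_meta(meta, log_matrix.columns)
    cols1 = log_matrix.columns[(meta["day"] == group1).to_numpy()]
    cols2 = log_matrix.columns[(meta["day"] == group2).to_numpy()]
    n1, n2 = len(cols1), len(cols2)
    if n1 < 2 or n2 < 2:
        raise ValueError(
            f"both groups need >= 2 samples (day {group1}: {n1}, day {group2}: {n2})"
        )
    x1 = log_matrix[cols1].to_numpy()
    x2 = log_matrix[cols2].to_numpy()
    mean1, mean2 = x1.mean(axis=1), x2.mean(axis=1)
    log_fc = mean2 - mean1
    d = float(n1 + n2 - 2)
    ss = ((x1 - mean1[:, None]) ** 2).sum(axis=1) + ((x2 - mean2[:, None]) ** 2).sum(axis=1)
    s2 = ss / d

    if prior == "fit":
        prior_obj = fit_prior(s2, d)
    elif prior is None:
        prior_obj = EBayesPrior(0.0, 1.0)
    elif isinstance(prior, EBayesPrior):
        prior_obj = prior
    else:
        raise TypeError("prior must be 'fit', None, or an EBayesPrior")

    d0, s02 = prior_obj.d0, prior_obj.s02
    if math.isinf(d0):
        s2_mod = np.full_like(s2, s02)
        df_total = math.inf
    else:
        s2_mod = (d0 * s02 + d * s2) / (d0 + d)
        df_total = d0 + d

    se = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
    t = np.zeros_like(log_fc)
    nz = se > 0
    t[nz] = log_fc[nz] / se[nz]
    degenerate = ~nz & (log_fc != 0)  # zero variance but nonzero difference
    t[degenerate] = np.sign(log_fc[degenerate]) * np.inf
    if math.isinf(df_total):
        from scipy.stats import norm

        p = 2.0 * norm.sf(np.abs(t))
    else:
        p = 2.0 * t_dist.sf(np.abs(t), df_total)
    p = np.clip(p, 0.0, 1.0)
    p_adj = benjamini_hochberg(p)
    significant = (p_adj < p_cutoff) & (np.abs(log_fc) > lfc_cutoff)

    table = pd.DataFrame(
        {
            "log_fc": log_fc,
            "s2": s2,
            "s2_moderated": s2_mod,
            "t": t,
            "p_value": p,
            "p_adjusted": p_adj,
            "significant": significant,
        },
        index=log_matrix.index,
    )
    return DifferentialResult(
        table=table,
        prior=prior_obj,
        df_residual=d,
        group1=group1,
        group2=group2,
        p_cutoff=p_cutoff,
        lfc_cutoff=lfc_cutoff,
    )


def volcano_table(
    result: DifferentialResult,
    p_cutoff: float | None = None,
    lfc_cutoff: float | None = None,
) -> pd.DataFrame:
    """Per-protein volcano coordinates and significance class.

    Classes (strict inequalities at both cutoffs): ``significant`` when both
    the adjusted p and |logFC| criteria hold, ``p_only`` / ``lfc_only`` when
    one does, ``ns`` otherwise.
    """
    p_cutoff = result.p_cutoff if p_cutoff is None else p_cutoff
    lfc_cutoff = result.lfc_cutoff if lfc_cutoff is None else lfc_cutoff
    tab = result.table
    with np.errstate(divide="ignore"):
        neg_log_p = -np.log10(tab["p_adjusted"].to_numpy())
    pass_p = tab["p_adjusted"].to_numpy() < p_cutoff
    pass_fc = np.abs(tab["log_fc"].to_numpy()) > lfc_cutoff
    cls = np.where(
        pass_p & pass_fc,
        "significant",
        np.where(pass_p, "p_only", np.where(pass_fc, "lfc_only", "ns")),
    )
    return pd.DataFrame(
        {
            "log_fc": tab["log_fc"],
            "neg_log10_p_adjusted": neg_log_p,
            "class": cls,
        },
        index=tab.index,
    )
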