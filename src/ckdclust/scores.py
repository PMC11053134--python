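"""Cluster-specific polygenic scores (cPGS) and their characterization.

A cluster's score is the inner product of its variant weights (a row of
the H matrix) with individual dosages; scores are standardized within
each cluster over the pooled cohort.  Distribution shape is checked with
the Anderson-Darling composite-normality test, group differences with
the Mann-Whitney test, and multi-cluster risk overlap with top-decile
membership counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "compute_cpgs",
    "standardize_cpgs",
    "ad_normality",
    "mw_test",
    "decile_membership",
    "DecileSummary",
]


def compute_cpgs(
    dosages: pd.DataFrame,
    weights: pd.DataFrame,
    effect_alleles: pd.Series | None = None,
    panel_alleles: pd.Series | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Raw cluster scores: score[i, k] = sum_v w[k, v] * dosage[i, v].

    ``weights`` is clusters x variants (rows of H).  Missing dosages are
    replaced by the cohort mean dosage of the variant; weighted variants
    absent from the panel are dropped and counted in the returned log.
    If both allele series are given, dosages are flipped (2 - d) where
    the panel's counted allele differs from the weight's effect allele.

    Raises
    ------
    ValueError
        If a cluster has no supported (positive-weight) variant in the
        panel.
    """
    weights = weights.astype(float)
    overlap = [v for v in weights.columns if v in dosages.columns]
    dropped = [v for v in weights.columns if v not in dosages.columns]
    for cluster, row in weights.iterrows():
        support = row[row > 0].index
        if not any(v in dosages.columns for v in support):
            raise ValueError(
                f"cluster {cluster!r}: no weighted variant overlaps the panel"
            )
    D = dosages[overlap].to_numpy(dtype=float)
    if effect_alleles is not None and panel_alleles is not None:
        flip = np.array(
            [effect_alleles.get(v) != panel_alleles.get(v) for v in overlap]
        )
        D = np.where(flip[None, :], 2.0 - D, D)
    col_mean = np.nanmean(D, axis=0)
    D = np.where(np.isnan(D), col_mean, D)
    raw = D @ weights[overlap].to_numpy().T
    table = pd.DataFrame(raw, index=dosages.index, columns=weights.index)
    return table, {"dropped_variants": len(dropped), "used_variants": len(overlap)}


def standardize_cpgs(
    raw: pd.DataFrame, cohort: pd.Index | list | None = None
) -> pd.DataFrame:
    """Z-score each cluster's raw scores on the pooled cohort (ddof=1).

    ``cohort`` optionally names the standardization subset; the returned
    table still covers every individual, transformed with the cohort's
    mean and SD so group comparisons share one z axis.
    """
    ref = raw.loc[cohort] if cohort is not None else raw
    mean = ref.mean(axis=0)
    sd = ref.std(axis=0, ddof=1)
    degenerate = sd[sd == 0].index.tolist()
    if degenerate:
        raise ValueError(f"constant raw scores for cluster(s) {degenerate}")
    return (raw - mean) / sd


def ad_normality(z: np.ndarray | pd.Series) -> tuple[float, float]:
    """Anderson-Darling composite normality test (mean, SD estimated).

    Returns the small-sample adjusted statistic A*^2 and its p-value via
    Stephens' approximation.  Requires n >= 8 and non-zero variance.
    """
    x = np.asarray(z, dtype=float)
    x = x[~np.isnan(x)]
    n = x.size
    if n < 8:
        raise ValueError(f"Anderson-Darling needs n >= 8, got {n}")
    if np.std(x, ddof=1) == 0:
        raise ValueError("degenerate sample: zero variance")
    w = np.sort((x - x.mean()) / np.std(x, ddof=1))
    i = np.arange(1, n + 1)
    a2 = float(
        -n
        - np.sum((2 * i - 1) * (stats.norm.logcdf(w) + stats.norm.logsf(w[::-1]))) / n
    )
    a2_star = a2 * (1.0 + 0.75 / n + 2.25 / n**2)
    if a2_star >= 0.6:
        p = np.exp(1.2937 - 5.709 * a2_star + 0.0186 * a2_star**2)
    elif a2_star > 0.34:
        p = np.exp(0.9177 - 4.279 * a2_star - 1.38 * a2_star**2)
    elif a2_star > 0.2:
        p = 1.0 - np.exp(-8.318 + 42.796 * a2_star - 59.938 * a2_star**2)
    else:
        p = 1.0 - np.exp(-13.436 + 101.14 * a2_star - 223.73 * a2_star**2)
    return a2_star, float(np.clip(p, 0.0, 1.0))


def mw_test(scores_a, scores_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test between two score distributions.

    Exact enumeration when n_a * n_b <= 400 and there are no ties,
    otherwise the normal approximation with tie and continuity
    corrections.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size * b.size <= 400 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class DecileSummary:
    """Cohort-level summary of top-decile cluster membership."""

    counts: pd.Series  # per-individual number of clusters in top decile
    fraction_at_least_one: float
    count_distribution: dict  # count -> fraction of cohort
    thresholds: pd.Series  # per-cluster 90th-percentile cutoffs


def decile_membership(z: pd.DataFrame) -> DecileSummary:
    """How many clusters place each individual in their top decile.

    The per-cluster threshold is the 90th percentile (linear
    interpolation) of that cluster's z-scores; an individual is "at high
    risk" for a cluster when its score reaches the threshold.
    """
    if z.shape[0] < 10:
        raise ValueError("decile membership needs at least 10 individuals")
    thresholds = z.quantile(0.9, axis=0)
    flags = z.ge(thresholds, axis=1)
    counts = flags.sum(axis=1)
    dist = (counts.value_counts(normalize=True).sort_index()).to_dict()
    return DecileSummary(
        counts=counts,
        fraction_at_least_one=float((counts >= 1).mean()),
        count_distribution=dist,
        thresholds=thresholds,
    )
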