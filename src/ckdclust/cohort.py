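"""Validation-cohort preparation: relatedness, PCA, ancestry groups.

The pooled cohort is the kinship-pruned set of genotyped individuals;
group sub-cohorts are disjoint subsets of it, assigned by a
probabilistic classifier trained on labelled reference coordinates and
thresholded at a membership-probability floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "kinship_matrix",
    "kinship_filter",
    "GenotypePCA",
    "pca",
    "AncestryClassifier",
    "assign_groups",
    "KINSHIP_2ND_DEGREE",
]

#: KING kinship bound separating 2nd-degree relatives from more distant
#: pairs (2^(-7/2)); pairs above it are pruned.
KINSHIP_2ND_DEGREE = 0.0884


def kinship_matrix(dosages: pd.DataFrame) -> pd.DataFrame:
    """Pairwise KING-robust between-family kinship estimates.

    phi(i,j) = (N_Aa,Aa - 2 * N_AA,aa) / (N_Aa(i) + N_Aa(j)), with
    heterozygote counts restricted to variants non-missing in both
    members of the pair.  Symmetric by construction; the diagonal is set
    to 0.5.
    """
    G = dosages.to_numpy(dtype=float)
    valid = ~np.isnan(G)
    Gz = np.where(valid, G, -1.0)
    het = (Gz == 1.0).astype(float)
    hom0 = (Gz == 0.0).astype(float)
    hom2 = (Gz == 2.0).astype(float)
    v = valid.astype(float)

    n_het_both = het @ het.T
    n_opp = hom0 @ hom2.T + hom2 @ hom0.T
    # het count of i over variants valid in j (and vice versa)
    het_i = het @ v.T
    denom = het_i + het_i.T
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (n_het_both - 2.0 * n_opp) / denom
    phi[denom == 0] = 0.0
    np.fill_diagonal(phi, 0.5)
    return pd.DataFrame(phi, index=dosages.index, columns=dosages.index)


def kinship_filter(
    dosages: pd.DataFrame,
    degree_threshold: float = KINSHIP_2ND_DEGREE,
) -> tuple[list[str], dict]:
    """Greedily prune individuals until no pair exceeds the threshold.

    Pairs with phi > ``degree_threshold`` are resolved by repeatedly
    dropping the individual involved in the most flagged pairs
    (ties broken by dropping the lexicographically later id).
    Individuals with all-missing genotypes are excluded up front.

    Returns the retained ids and a log with the dropped ids.
    """
    if dosages.shape[0] < 2:
        raise ValueError("kinship filtering needs at least 2 individuals")
    all_missing = dosages.isna().all(axis=1)
    log: dict = {"all_missing": list(dosages.index[all_missing]), "related_dropped": []}
    work = dosages.loc[~all_missing]

    phi = kinship_matrix(work).to_numpy()
    np.fill_diagonal(phi, 0.0)
    ids = list(work.index)
    flagged = phi > degree_threshold
    active = np.ones(len(ids), dtype=bool)
    while True:
        counts = (flagged & active[None, :] & active[:, None]).sum(axis=1)
        counts[~active] = 0
        worst = counts.max()
        if worst == 0:
            break
        cand = np.flatnonzero(counts == worst)
        drop = max(cand, key=lambda i: ids[i])  # lexicographically later id
        active[drop] = False
        log["related_dropped"].append(ids[drop])
    return [i for i, a in zip(ids, active) if a], log


class GenotypePCA(TransformerMixin, BaseEstimator):
    """PCA of a dosage matrix with the usual GWAS normalization.

    Variants with minor allele frequency below ``maf_min`` are dropped,
    missing dosages mean-imputed, and each variant centered at 2p and
    scaled by sqrt(2p(1-p)).  Coordinates are the top ``n_pcs`` left
    singular vectors (orthonormal columns); each PC's sign is fixed so
    its largest-magnitude variant loading is positive.
    """

    def __init__(self, n_pcs: int = 10, maf_min: float = 0.05):
        self.n_pcs = n_pcs
        self.maf_min = maf_min

    def fit(self, X: pd.DataFrame, y=None):
        self.fit_transform(X)
        return self

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
        G = X.to_numpy(dtype=float)
        p = np.nanmean(G, axis=0) / 2.0
        maf = np.minimum(p, 1.0 - p)
        keep = maf >= self.maf_min
        if keep.sum() < self.n_pcs:
            raise ValueError(
                f"only {int(keep.sum())} variants pass MAF >= {self.maf_min}; "
                f"need at least n_pcs={self.n_pcs}"
            )
        Gk = G[:, keep]
        pk = p[keep]
        col_mean = np.nanmean(Gk, axis=0)
        Gk = np.where(np.isnan(Gk), col_mean, Gk)
        Z = (Gk - 2.0 * pk) / np.sqrt(2.0 * pk * (1.0 - pk))
        U, S, Vt = np.linalg.svd(Z, full_matrices=False)
        U, Vt = U[:, : self.n_pcs], Vt[: self.n_pcs]
        flip = np.sign(Vt[np.arange(Vt.shape[0]), np.abs(Vt).argmax(axis=1)])
        flip[flip == 0] = 1.0
        U = U * flip
        self.components_ = Vt * flip[:, None]
        self.singular_values_ = S[: self.n_pcs]
        self.kept_variants_ = list(np.asarray(X.columns)[keep])
        self.allele_freq_ = pd.Series(pk, index=self.kept_variants_)
        coords = pd.DataFrame(
            U, index=X.index, columns=[f"PC{i + 1}" for i in range(self.n_pcs)]
        )
        self.coordinates_ = coords
        return coords


def pca(dosages: pd.DataFrame, maf_min: float = 0.05, n_pcs: int = 10) -> pd.DataFrame:
    """Thin wrapper over :class:`GenotypePCA`; returns the coordinates."""
    return GenotypePCA(n_pcs=n_pcs, maf_min=maf_min).fit_transform(dosages)


class AncestryClassifier(BaseEstimator):
    """Probabilistic group assignment from PC coordinates.

    Any classifier exposing calibrated ``predict_proba`` can be plugged
    in; the default is a random forest.  Individuals whose maximum class
    probability is <= ``prob_floor`` are flagged as mixed and excluded
    from group-specific analyses (they remain in the pooled cohort).
    """

    def __init__(
        self,
        prob_floor: float = 0.5,
        classifier=None,
        random_state: int | None = 0,
    ):
        self.prob_floor = prob_floor
        self.classifier = classifier
        self.random_state = random_state

    def fit(self, reference_pcs, reference_labels):
        ref = np.asarray(reference_pcs, dtype=float)
        labels = np.asarray(reference_labels)
        if len(np.unique(labels)) < 2:
            raise ValueError("reference must contain at least 2 group labels")
        self.n_features_in_ = ref.shape[1]
        self.estimator_ = self.classifier or RandomForestClassifier(
            n_estimators=200, random_state=self.random_state
        )
        self.estimator_.fit(ref, labels)
        self.classes_ = self.estimator_.classes_
        return self

    def predict_proba(self, pcs):
        pcs = np.asarray(pcs, dtype=float)
        if pcs.shape[1] != self.n_features_in_:
            raise ValueError(
                f"query has {pcs.shape[1]} coordinates, reference had "
                f"{self.n_features_in_}"
            )
        return self.estimator_.predict_proba(pcs)

    def assign(self, pcs: pd.DataFrame) -> pd.DataFrame:
        proba = self.predict_proba(pcs)
        best = proba.argmax(axis=1)
        prob = proba[np.arange(len(best)), best]
        index = pcs.index if isinstance(pcs, pd.DataFrame) else range(len(best))
        return pd.DataFrame(
            {
                "group_label": self.classes_[best],
                "group_prob": prob,
                "included_in_group_analysis": prob > self.prob_floor,
            },
            index=index,
        )


def assign_groups(
    pcs: pd.DataFrame,
    reference_pcs,
    reference_labels,
    prob_floor: float = 0.5,
    classifier=None,
    trim_quantiles: tuple[float, float] | None = None,
    random_state: int | None = 0,
) -> pd.DataFrame:
    """Assign each individual to a genetic group with a probability.

    ``trim_quantiles`` optionally excludes, within each assigned group,
    individuals whose assignment probability falls outside the given
    quantile band; disabled by default.
    """
    clf = AncestryClassifier(
        prob_floor=prob_floor, classifier=classifier, random_state=random_state
    )
    clf.fit(reference_pcs, reference_labels)
    table = clf.assign(pcs)
    if trim_quantiles is not None:
        lo_q, hi_q = trim_quantiles
        for label, sub in table.groupby("group_label"):
            lo = sub["group_prob"].quantile(lo_q)
            hi = sub["group_prob"].quantile(hi_q)
            out = sub.index[(sub["group_prob"] < lo) | (sub["group_prob"] > hi)]
            table.loc[out, "included_in_group_analysis"] = False
    return table
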