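"""PheWAS harness: regress every phenotype on each cluster score.

Quantitative phenotypes are fitted by ordinary least squares with both
the outcome and the score z-scored (standardized beta); binary Phecode
phenotypes by logistic regression with the score z-scored, reported as
an odds ratio per 1 SD of cPGS.  All models adjust for sex, age and the
genetic principal components supplied in the covariate table, and
significance is controlled by a Bonferroni threshold over all
(cluster, trait) tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "PhenotypeSet",
    "PhewasResult",
    "map_phecodes",
    "compute_alpha",
    "run_phewas",
    "validate_top_traits",
    "results_to_frame",
]


@dataclass
class PhenotypeSet:
    """Phenotypes and covariates, indexed by individual id.

    ``binary`` uses 1 = case (>= 2 qualifying code events), 0 = control,
    NaN = excluded (exactly one event).
    """

    quantitative: pd.DataFrame
    binary: pd.DataFrame
    covariates: pd.DataFrame


@dataclass
class PhewasResult:
    cluster_id: str
    trait: str
    trait_type: str  # "quantitative" | "binary"
    estimate: float  # standardized beta, or OR per 1 SD of cPGS
    ci95: tuple[float, float]
    p: float
    n: int
    n_cases: int | None
    significant: bool
    converged: bool = True


def map_phecodes(
    code_events: pd.DataFrame,
    code_map: pd.DataFrame,
    individuals: pd.Index | list,
) -> tuple[pd.DataFrame, dict]:
    """Build case/control/excluded Phecode columns from ICD code events.

    ``code_events`` is long-format (individual_id, code); ``code_map``
    maps icd_code -> phecode.  Per Phecode: >= 2 mapped events = case
    (1), exactly 1 = excluded (NaN), 0 = control (0).  Unmapped codes
    are logged, not fatal.
    """
    mapping = dict(zip(code_map["icd_code"], code_map["phecode"]))
    unmapped = sorted(set(code_events["code"]) - set(mapping))
    mapped = code_events[code_events["code"].isin(mapping)].copy()
    mapped["phecode"] = mapped["code"].map(mapping)
    counts = (
        mapped.groupby(["individual_id", "phecode"]).size().unstack(fill_value=0)
    )
    counts = counts.reindex(index=individuals, fill_value=0)
    binary = pd.DataFrame(
        np.where(counts >= 2, 1.0, np.where(counts == 1, np.nan, 0.0)),
        index=counts.index,
        columns=counts.columns,
    )
    return binary, {"unmapped_codes": unmapped}


def compute_alpha(
    K: int, n_quant: int, n_binary: int, family_alpha: float = 0.05
) -> float:
    """Bonferroni alpha over all K * (n_quant + n_binary) tests."""
    if K < 0 or n_quant < 0 or n_binary < 0:
        raise ValueError("counts must be non-negative")
    denom = K * (n_quant + n_binary)
    if denom == 0:
        raise ValueError("cannot divide family alpha by zero tests")
    return family_alpha / denom


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def run_phewas(
    cpgs: pd.DataFrame,
    phenos: PhenotypeSet,
    min_n: int = 100,
    min_cases: int = 20,
    alpha: float | None = None,
) -> list[PhewasResult]:
    """Fit outcome ~ cPGS + covariates for every (cluster, trait) pair.

    Traits observed in fewer than ``min_n`` individuals are skipped;
    binary traits additionally require ``min_cases`` cases (logistic
    fits with a handful of cases are meaningless).  If ``alpha`` is None
    it is recomputed from the numbers of analyzable traits via
    :func:`compute_alpha`.
    """
    quant_traits = [
        t for t in phenos.quantitative.columns
        if phenos.quantitative[t].notna().sum() >= min_n
    ]
    bin_traits = []
    for t in phenos.binary.columns:
        col = phenos.binary[t].dropna()
        if len(col) >= min_n and (col == 1).sum() >= min_cases and (col == 0).sum() >= 1:
            bin_traits.append(t)
    if alpha is None:
        alpha = compute_alpha(cpgs.shape[1], len(quant_traits), len(bin_traits))

    cov = phenos.covariates
    results: list[PhewasResult] = []
    for cluster in cpgs.columns:
        score = cpgs[cluster]
        for trait in quant_traits:
            results.append(
                _fit_linear(cluster, trait, phenos.quantitative[trait], score, cov, alpha)
            )
        for trait in bin_traits:
            results.append(
                _fit_logistic(cluster, trait, phenos.binary[trait], score, cov, alpha)
            )
    return results


def _design(y: pd.Series, score: pd.Series, cov: pd.DataFrame):
    df = pd.concat({"y": y, "cpgs": score}, axis=1).join(cov, how="inner").dropna()
    X = sm.add_constant(df.drop(columns="y"), has_constant="add")
    return df["y"].to_numpy(dtype=float), X, len(df)


def _fit_linear(cluster, trait, y, score, cov, alpha) -> PhewasResult:
    yv, X, n = _design(y, score, cov)
    yz = _zscore(yv)
    X = X.copy()
    X["cpgs"] = _zscore(X["cpgs"].to_numpy())
    fit = sm.OLS(yz, X).fit()
    beta = float(fit.params["cpgs"])
    lo, hi = map(float, fit.conf_int().loc["cpgs"])
    p = float(fit.pvalues["cpgs"])
    return PhewasResult(
        cluster_id=str(cluster), trait=str(trait), trait_type="quantitative",
        estimate=beta, ci95=(lo, hi), p=p, n=n, n_cases=None,
        significant=bool(p < alpha),
    )


def _fit_logistic(cluster, trait, y, score, cov, alpha) -> PhewasResult:
    yv, X, n = _design(y, score, cov)
    X = X.copy()
    X["cpgs"] = _zscore(X["cpgs"].to_numpy())
    n_cases = int((yv == 1).sum())
    converged = True
    try:
        fit = sm.Logit(yv, X).fit(disp=0, maxiter=200)
        converged = bool(fit.mle_retvals.get("converged", True))
        beta = float(fit.params["cpgs"])
        lo, hi = map(float, fit.conf_int().loc["cpgs"])
        p = float(fit.pvalues["cpgs"])
    except Exception:
        converged, beta, lo, hi, p = False, np.nan, np.nan, np.nan, np.nan
    return PhewasResult(
        cluster_id=str(cluster), trait=str(trait), trait_type="binary",
        estimate=float(np.exp(beta)), ci95=(float(np.exp(lo)), float(np.exp(hi))),
        p=p, n=n, n_cases=n_cases,
        significant=bool(p < alpha) if np.isfinite(p) else False,
        converged=converged,
    )


def results_to_frame(results: list[PhewasResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{
            "cluster_id": r.cluster_id,
            "trait": r.trait,
            "trait_type": r.trait_type,
            "estimate": r.estimate,
            "ci_low": r.ci95[0],
            "ci_high": r.ci95[1],
            "p": r.p,
            "n": r.n,
            "n_cases": r.n_cases,
            "significant": r.significant,
            "converged": r.converged,
        }
        for r in results]
    )


def validate_top_traits(
    results: list[PhewasResult],
    top_traits: dict[str, list[tuple[str, str]]],
    synonym_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Check each cluster's top traits against its PheWAS results.

    ``top_traits`` maps cluster id -> ordered [(trait name, direction)]
    with direction "+" or "-".  A top trait is validated iff its matched
    PheWAS result is Bonferroni-significant and the effect sign agrees
    with the trait's cluster direction (for binary traits the sign of
    log OR).  Trait names are matched through ``synonym_map`` when
    given, else identically; unmatched traits are flagged, not fatal.
    """
    synonym_map = synonym_map or {}
    by_key = {(r.cluster_id, r.trait): r for r in results}
    rows = []
    for cluster, traits in top_traits.items():
        for rank, (trait, direction) in enumerate(traits, start=1):
            name = synonym_map.get(trait, trait)
            r = by_key.get((str(cluster), name))
            if r is None:
                rows.append(
                    dict(cluster_id=cluster, trait=trait, rank=rank,
                         matched=False, validated=False, estimate=np.nan, p=np.nan)
                )
                continue
            signed = (
                r.estimate if r.trait_type == "quantitative" else np.log(r.estimate)
            )
            sign_ok = signed > 0 if direction == "+" else signed < 0
            rows.append(
                dict(
                    cluster_id=cluster, trait=trait, rank=rank, matched=True,
                    validated=bool(r.significant and sign_ok),
                    estimate=r.estimate, p=r.p,
                )
            )
    return pd.DataFrame(rows)
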