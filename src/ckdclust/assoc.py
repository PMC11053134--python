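"""Build the non-negative trait x variant association matrix.

The clustering input is a matrix of standardized GWAS effect sizes
(beta = B/SE, a z-score) linking kidney-function lead variants — through
their LD proxies — to secondary traits harvested from published GWAS
summary records.  Records pass through a fixed sequence of filters
(gender-specific studies, small studies, kidney-function traits
themselves, non-significant associations, sparsely associated traits)
before each trait is split into a "+" and a "-" feature row so that the
matrix is non-negative and direction-resolved.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "VariantRecord",
    "ProxyLink",
    "TraitAssociation",
    "AssociationMatrix",
    "FilterLog",
    "DEFAULT_EXCLUDED_TRAIT_PATTERNS",
    "filter_associations",
    "standardize_effects",
    "align_to_lead",
    "build_matrix",
]

#: Kidney-function traits are excluded because the variants were selected
#: for them in the first place; matching is case-insensitive substring.
DEFAULT_EXCLUDED_TRAIT_PATTERNS = (
    "glomerular filtration rate",
    "chronic kidney disease",
)

_VALID_ALLELES = frozenset("ACGT")


class FilterError(ValueError):
    """Raised when filtering leaves no usable associations."""


@dataclass(frozen=True)
class VariantRecord:
    """A kidney-function lead variant with aligned alleles."""

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    kidney_decreasing_allele: str

    def __post_init__(self) -> None:
        if self.effect_allele not in _VALID_ALLELES or self.other_allele not in _VALID_ALLELES:
            raise ValueError(f"{self.rsid}: alleles must be one of A/C/G/T")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.rsid}: effect and other allele are identical")
        if self.kidney_decreasing_allele not in (self.effect_allele, self.other_allele):
            raise ValueError(
                f"{self.rsid}: kidney-decreasing allele must be one of the two alleles"
            )


@dataclass(frozen=True)
class ProxyLink:
    """An LD link between a lead variant and one of its proxies."""

    lead_rsid: str
    proxy_rsid: str
    r2: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2 <= 1.0:
            raise ValueError(f"r2 must lie in [0, 1], got {self.r2}")


@dataclass
class TraitAssociation:
    """One proxy-variant -> trait GWAS summary record.

    ``beta_std`` (B/SE) is filled in by :func:`standardize_effects`;
    ``lead_rsid`` by :func:`align_to_lead`.  ``decoy_rule`` is used by the
    synthetic generator to label records planted to violate a filter.
    """

    proxy_rsid: str
    trait: str
    B: float
    SE: float
    p: float
    n: int
    gender_specific: bool = False
    study_id: str = ""
    effect_allele: str | None = None
    beta_std: float | None = None
    lead_rsid: str | None = None
    decoy_rule: str | None = None

    def __post_init__(self) -> None:
        if self.SE <= 0:
            raise ValueError(f"{self.proxy_rsid}/{self.trait}: SE must be > 0")
        if not 0.0 < self.p <= 1.0:
            raise ValueError(f"{self.proxy_rsid}/{self.trait}: p must lie in (0, 1]")


@dataclass
class FilterLog:
    """Per-rule removal counts accumulated by :func:`filter_associations`."""

    gender_specific: int = 0
    small_n: int = 0
    excluded_trait: int = 0
    p_threshold: int = 0
    few_variants: int = 0
    kept: int = 0
    skipped_align: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "gender_specific": self.gender_specific,
            "small_n": self.small_n,
            "excluded_trait": self.excluded_trait,
            "p_threshold": self.p_threshold,
            "few_variants": self.few_variants,
            "kept": self.kept,
        }


@dataclass
class AssociationMatrix:
    """Non-negative matrix of |beta| values, trait-features x variants.

    Each trait contributes up to two feature rows: ``(trait, '+')`` holds
    the magnitudes of its positive standardized effects and
    ``(trait, '-')`` those of its negative ones; all-zero rows are
    dropped, so the matrix is strictly non-negative with at most two rows
    per trait.
    """

    values: np.ndarray
    feature_labels: list[tuple[str, str]]
    variant_labels: list[str]
    provenance: FilterLog | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.min(initial=0.0) < 0:
            raise ValueError("association matrix must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_tuples(self.feature_labels, names=["trait", "direction"])
        return pd.DataFrame(self.values, index=idx, columns=self.variant_labels)


def filter_associations(
    records: list[TraitAssociation],
    excluded_trait_patterns: tuple[str, ...] = DEFAULT_EXCLUDED_TRAIT_PATTERNS,
    p_threshold: float = 1e-6,
    min_n: int = 100,
    min_variants_per_trait: int = 5,
) -> tuple[list[TraitAssociation], FilterLog]:
    """Apply the record-level quality filters in a fixed order.

    Rules are applied sequentially — gender-specific studies, sample size
    below ``min_n``, excluded (kidney-function) trait names,
    non-significant p-values, and finally traits left with fewer than
    ``min_variants_per_trait`` distinct variants — so that the per-rule
    removal counts in the returned :class:`FilterLog` are reproducible.

    Raises
    ------
    FilterError
        If the input was non-empty but nothing survives.
    """
    if p_threshold <= 0 or min_n <= 0 or min_variants_per_trait <= 0:
        raise ValueError("filter thresholds must be positive")
    log = FilterLog()
    patterns = [re.compile(re.escape(pat), re.IGNORECASE) for pat in excluded_trait_patterns]

    survivors = []
    for rec in records:
        if rec.gender_specific:
            log.gender_specific += 1
        elif rec.n < min_n:
            log.small_n += 1
        elif any(pat.search(rec.trait) for pat in patterns):
            log.excluded_trait += 1
        elif rec.p >= p_threshold:
            log.p_threshold += 1
        else:
            survivors.append(rec)

    counts: dict[str, set] = {}
    for rec in survivors:
        counts.setdefault(rec.trait, set()).add(rec.proxy_rsid)
    kept = []
    for rec in survivors:
        if len(counts[rec.trait]) < min_variants_per_trait:
            log.few_variants += 1
        else:
            kept.append(rec)

    log.kept = len(kept)
    if records and not kept:
        raise FilterError("no data after filtering: every association was removed")
    return kept, log


def standardize_effects(records: list[TraitAssociation]) -> list[TraitAssociation]:
    """Return copies with the standardized effect beta = B/SE filled in."""
    out = []
    for rec in records:
        if rec.SE <= 0:  # defensive; the dataclass already rejects this
            raise ValueError(f"record {rec.proxy_rsid}/{rec.trait}: SE <= 0")
        out.append(replace(rec, beta_std=rec.B / rec.SE))
    return out


def align_to_lead(
    records: list[TraitAssociation],
    proxies: list[ProxyLink],
    variants: list[VariantRecord],
    r2_min: float = 0.6,
    log: FilterLog | None = None,
) -> list[TraitAssociation]:
    """Attribute proxy-level associations to their lead variants.

    Proxy links with r2 below ``r2_min`` are dropped.  The effect sign is
    flipped when the record's effect allele is not the lead's
    kidney-function-decreasing allele, so positive beta always means
    "more of the trait on the kidney-function-decreasing allele".  When
    several proxies of one lead hit the same trait, the record with the
    largest |beta| is kept (ties: smaller p, then lexicographic proxy
    rsid).

    Records must already be standardized (``beta_std`` set).
    """
    if log is None:
        log = FilterLog()
    lead_by_rsid = {v.rsid: v for v in variants}
    lead_of_proxy: dict[str, tuple[str, float]] = {}
    for link in proxies:
        if link.r2 < r2_min:
            continue
        prev = lead_of_proxy.get(link.proxy_rsid)
        if prev is None or link.r2 > prev[1]:
            lead_of_proxy[link.proxy_rsid] = (link.lead_rsid, link.r2)

    aligned: dict[tuple[str, str], TraitAssociation] = {}
    for rec in records:
        if rec.beta_std is None:
            raise ValueError("records must be standardized before alignment")
        hit = lead_of_proxy.get(rec.proxy_rsid)
        if hit is None:
            log.skipped_align.append((rec.proxy_rsid, rec.trait, "no proxy link"))
            continue
        lead_rsid = hit[0]
        lead = lead_by_rsid.get(lead_rsid)
        if lead is None:
            log.skipped_align.append((rec.proxy_rsid, rec.trait, "unknown lead"))
            continue
        beta = rec.beta_std
        if rec.effect_allele is not None:
            if rec.effect_allele == lead.kidney_decreasing_allele:
                pass
            elif rec.effect_allele in (lead.effect_allele, lead.other_allele):
                beta = -beta
            else:
                log.skipped_align.append((rec.proxy_rsid, rec.trait, "allele mismatch"))
                continue
        cand = replace(rec, beta_std=beta, lead_rsid=lead_rsid)
        key = (lead_rsid, rec.trait)
        prev = aligned.get(key)
        if prev is None or _align_rank(cand) < _align_rank(prev):
            aligned[key] = cand
    return list(aligned.values())


def _align_rank(rec: TraitAssociation) -> tuple:
    # best record first: largest |beta|, then smallest p, then rsid
    return (-abs(rec.beta_std), rec.p, rec.proxy_rsid)


def build_matrix(
    aligned_records: list[TraitAssociation],
    provenance: FilterLog | None = None,
) -> AssociationMatrix:
    """Arrange lead-aligned records as a non-negative feature matrix.

    For each trait a "+" row holds |beta| where beta > 0 and a "-" row
    holds |beta| where beta < 0; all-zero rows are dropped.
    """
    for rec in aligned_records:
        if rec.lead_rsid is None or rec.beta_std is None:
            raise ValueError("records must be filtered, standardized and lead-aligned")
    traits = sorted({rec.trait for rec in aligned_records})
    leads = sorted({rec.lead_rsid for rec in aligned_records})
    col = {rsid: j for j, rsid in enumerate(leads)}

    rows: list[np.ndarray] = []
    labels: list[tuple[str, str]] = []
    by_trait: dict[str, list[TraitAssociation]] = {}
    for rec in aligned_records:
        by_trait.setdefault(rec.trait, []).append(rec)
    for trait in traits:
        plus = np.zeros(len(leads))
        minus = np.zeros(len(leads))
        for rec in by_trait[trait]:
            if rec.beta_std > 0:
                plus[col[rec.lead_rsid]] = abs(rec.beta_std)
            elif rec.beta_std < 0:
                minus[col[rec.lead_rsid]] = abs(rec.beta_std)
        if plus.any():
            rows.append(plus)
            labels.append((trait, "+"))
        if minus.any():
            rows.append(minus)
            labels.append((trait, "-"))
    values = np.vstack(rows) if rows else np.empty((0, len(leads)))
    return AssociationMatrix(values, labels, leads, provenance)


def beta_to_p(beta: float | np.ndarray) -> float | np.ndarray:
    """Two-sided normal-tail p-value of a standardized effect.

    Floored at 1e-300 so extreme z-scores keep a representable, strictly
    positive p.
    """
    from scipy.stats import norm

    p = 2.0 * norm.sf(np.abs(beta))
    return np.maximum(p, 1e-300) if isinstance(p, np.ndarray) else max(p, 1e-300)
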