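"""Synthetic pipeline inputs with planted ground truth.

Every input the pipeline consumes — lead variants, proxy links, GWAS
summary records, genotype dosages, phenotypes with ICD code events, gene
sets — can be generated here with known cluster structure, so each
downstream stage is testable end to end without external downloads.

The planted structure is block-diagonal: every trait and every variant
has one dominant cluster, plus a uniform cross-loading of 5% of the
within-block mean so the factorization has to cope with soft overlap.
Ground-truth matrices are rescaled so planted standardized effects are
genome-wide significant (the GWAS record generator emulates a catalog
that only contains significant associations).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .assoc import ProxyLink, TraitAssociation, VariantRecord, beta_to_p

__all__ = [
    "GroundTruth",
    "GenotypeData",
    "PhenotypeData",
    "generate_truth",
    "generate_association_records",
    "generate_genotypes",
    "generate_phenotypes",
    "toy_phecode_map",
    "variants_for_truth",
    "identity_proxies",
    "write_dataset",
]

#: Cross-loading fraction of the within-block mean (soft cluster overlap).
CROSS_LOADING = 0.05

#: Planted minimum standardized effect; chosen so every product entry of
#: the dense (sparsity=0) truth clears the default 1e-6 significance
#: filter (|beta| >= 4.89) with margin.
BETA_FLOOR = 6.0

#: Default per-SD effect of a cluster score on its matched phenotype.
PHENO_EFFECT = 0.3


@dataclass
class GroundTruth:
    """Planted factorization and phenotype effects for one simulation."""

    W_true: np.ndarray  # traits x K, non-negative
    H_true: np.ndarray  # K x variants, non-negative
    K_true: int
    effect_sign: np.ndarray  # per-trait +1/-1
    pheno_effects: np.ndarray  # K x (2K): quantitative then binary targets
    seed: int
    trait_labels: list[str] = field(default_factory=list)
    variant_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.K_true < 1:
            raise ValueError("K_true must be >= 1")
        if self.W_true.min() < 0 or self.H_true.min() < 0:
            raise ValueError("ground-truth factors must be non-negative")

    @property
    def n_traits(self) -> int:
        return self.W_true.shape[0]

    @property
    def n_variants(self) -> int:
        return self.H_true.shape[1]

    @property
    def dominant_trait_cluster(self) -> np.ndarray:
        return self.W_true.argmax(axis=1)

    @property
    def dominant_variant_cluster(self) -> np.ndarray:
        return self.H_true.argmax(axis=0)

    def signal(self) -> np.ndarray:
        """The noiseless standardized-effect matrix W_true @ H_true."""
        return self.W_true @ self.H_true


def _block_matrix(
    rng: np.random.Generator, n_rows: int, K: int, sparsity: float, transpose: bool
) -> np.ndarray:
    """Rows (or columns if ``transpose``) with one dominant cluster each."""
    dom = np.concatenate([np.arange(K), rng.integers(0, K, size=n_rows - K)])
    rng.shuffle(dom)
    dom_vals = rng.uniform(1.0, 2.0, size=n_rows)
    cross = CROSS_LOADING * dom_vals.mean()
    M = np.full((n_rows, K), cross)
    M[np.arange(n_rows), dom] = dom_vals

    n_zero = int(round(sparsity * M.size))
    eligible = np.flatnonzero(np.ones((n_rows, K)).ravel())
    dominant_flat = np.arange(n_rows) * K + dom
    eligible = np.setdiff1d(eligible, dominant_flat)
    if n_zero > eligible.size:
        raise ValueError(
            f"sparsity {sparsity} too high for K={K}: cannot zero dominant entries"
        )
    if n_zero:
        zero_idx = rng.choice(eligible, size=n_zero, replace=False)
        M.ravel()[zero_idx] = 0.0
    return M.T if transpose else M


def generate_truth(
    K: int,
    n_traits: int,
    n_variants: int,
    sparsity: float = 0.0,
    seed: int = 0,
    neg_trait_fraction: float = 0.5,
) -> GroundTruth:
    """Draw a planted block-structured factorization W_true, H_true.

    Parameters
    ----------
    K : number of planted clusters (>= 1).
    n_traits, n_variants : matrix dimensions; each must be >= K so that
        every cluster receives at least one dominant trait and variant.
    sparsity : fraction of entries in each factor set exactly to zero
        (never a dominant entry, so the block structure survives).
    neg_trait_fraction : expected fraction of traits whose planted GWAS
        effect direction is negative.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if n_traits < K or n_variants < K:
        raise ValueError("need n_traits >= K and n_variants >= K")
    if not 0.0 <= sparsity < 1.0:
        raise ValueError("sparsity must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    W = _block_matrix(rng, n_traits, K, sparsity, transpose=False)
    H = _block_matrix(rng, n_variants, K, sparsity, transpose=True)

    # Rescale so the smallest entry of the dense product clears the
    # genome-wide significance floor; computed on the zero-free pattern so
    # the scale does not depend on which entries the sparsity mask hit.
    dense_min = _dense_product_min(W, H)
    scale = np.sqrt(BETA_FLOOR / dense_min)
    W *= scale
    H *= scale

    sign = np.where(rng.random(n_traits) < neg_trait_fraction, -1.0, 1.0)
    effects = np.zeros((K, 2 * K))
    effects[np.arange(K), np.arange(K)] = PHENO_EFFECT
    effects[np.arange(K), K + np.arange(K)] = PHENO_EFFECT
    return GroundTruth(
        W_true=W,
        H_true=H,
        K_true=K,
        effect_sign=sign,
        pheno_effects=effects,
        seed=seed,
        trait_labels=[f"Synthetic trait {t:03d}" for t in range(n_traits)],
        variant_labels=[f"rs{1000 + v}" for v in range(n_variants)],
    )


def _dense_product_min(W: np.ndarray, H: np.ndarray) -> float:
    Wd = np.where(W > 0, W, CROSS_LOADING * W.max(axis=1).mean())
    Hd = np.where(H > 0, H, CROSS_LOADING * H.max(axis=0).mean())
    return float((Wd @ Hd).min())


def generate_association_records(
    truth: GroundTruth,
    noise_sd: float = 0.1,
    n_decoys: int = 0,
    seed: int = 0,
    significance_threshold: float = 1e-6,
    se_range: tuple[float, float] = (0.02, 0.1),
) -> list[TraitAssociation]:
    """Emit GWAS-catalog-style records for the planted signal plus decoys.

    For each nonzero entry of W_true @ H_true a record is drawn with
    realized beta = sign(trait) * signal + Normal(0, noise_sd), then
    converted to (B, SE, p, n) with B = beta * SE and p from the
    two-sided normal tail.  Mirroring a catalog of significant hits,
    records whose realized p does not clear ``significance_threshold``
    are not emitted (pass 1.0 to emit everything).

    ``n_decoys`` extra records are planted, each violating exactly one
    quality filter; their ``decoy_rule`` attribute names the rule so
    tests can assert that the filter removes exactly the decoys.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    signal = truth.signal()
    records: list[TraitAssociation] = []
    for t in range(truth.n_traits):
        for v in range(truth.n_variants):
            if signal[t, v] == 0:
                continue
            beta = truth.effect_sign[t] * signal[t, v] + rng.normal(0.0, noise_sd)
            p = float(beta_to_p(beta))
            if p >= significance_threshold:
                continue
            se = rng.uniform(*se_range)
            records.append(
                TraitAssociation(
                    proxy_rsid=truth.variant_labels[v],
                    trait=truth.trait_labels[t],
                    B=beta * se,
                    SE=se,
                    p=p,
                    n=int(rng.integers(10_000, 500_000)),
                    gender_specific=False,
                    study_id=f"SYNSTUDY{t:03d}",
                    effect_allele="A",
                )
            )
    records.extend(_decoys(truth, rng, n_decoys, se_range))
    return records


def _decoys(
    truth: GroundTruth,
    rng: np.random.Generator,
    n_decoys: int,
    se_range: tuple[float, float],
) -> list[TraitAssociation]:
    rules = ["small_n", "gender_specific", "excluded_trait", "p_threshold", "few_variants"]
    out = []
    strong_beta = float(truth.signal().max())
    for i in range(n_decoys):
        rule = rules[i % len(rules)]
        se = rng.uniform(*se_range)
        beta = strong_beta
        kw: dict = dict(
            proxy_rsid=truth.variant_labels[int(rng.integers(truth.n_variants))],
            trait=truth.trait_labels[int(rng.integers(truth.n_traits))],
            n=int(rng.integers(10_000, 500_000)),
            gender_specific=False,
            study_id=f"DECOY{i:03d}",
            effect_allele="A",
        )
        if rule == "small_n":
            kw["n"] = int(rng.integers(10, 100))
        elif rule == "gender_specific":
            kw["gender_specific"] = True
        elif rule == "excluded_trait":
            kw["trait"] = "Estimated glomerular filtration rate"
        elif rule == "p_threshold":
            beta = float(rng.uniform(0.5, 2.0))
        elif rule == "few_variants":
            kw["trait"] = f"Sparse decoy trait {i:03d}"
        out.append(
            TraitAssociation(
                B=beta * se, SE=se, p=float(beta_to_p(beta)), decoy_rule=rule, **kw
            )
        )
    return out


@dataclass
class GenotypeData:
    """Dosage matrix (individuals x variants, values 0/1/2) with groups."""

    dosages: pd.DataFrame
    group_labels: pd.Series
    freqs: pd.DataFrame  # group x variant allele frequencies


def generate_genotypes(
    n_individuals: int,
    n_variants: int,
    groups: list[tuple[str, float, tuple[float, float]]] | None = None,
    seed: int = 0,
) -> GenotypeData:
    """Hardy-Weinberg dosages with group-specific allele frequencies.

    ``groups`` is a list of (label, cohort fraction, (maf_lo, maf_hi));
    fractions must sum to 1 and frequency ranges lie within (0, 0.5].
    """
    if groups is None:
        groups = [("POP1", 1.0, (0.05, 0.5))]
    fracs = np.array([g[1] for g in groups], dtype=float)
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError(f"group fractions must sum to 1, got {fracs.sum()}")
    for _, _, (lo, hi) in groups:
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf ranges must lie within (0, 0.5]")
    rng = np.random.default_rng(seed)
    counts = np.diff(np.round(np.cumsum(np.concatenate([[0.0], fracs])) * n_individuals)).astype(int)

    variant_ids = [f"rs{1000 + v}" for v in range(n_variants)]
    blocks, labels, freq_rows = [], [], []
    for (label, _, (lo, hi)), cnt in zip(groups, counts):
        p = rng.uniform(lo, hi, size=n_variants)
        blocks.append(rng.binomial(2, p, size=(cnt, n_variants)))
        labels.extend([label] * cnt)
        freq_rows.append(p)
    dosages = np.vstack(blocks).astype(float)
    ids = pd.Index([f"IND{i:06d}" for i in range(n_individuals)], name="individual_id")
    return GenotypeData(
        dosages=pd.DataFrame(dosages, index=ids, columns=variant_ids),
        group_labels=pd.Series(labels, index=ids, name="group"),
        freqs=pd.DataFrame(freq_rows, index=[g[0] for g in groups], columns=variant_ids),
    )


def toy_phecode_map(n_codes: int = 64) -> pd.DataFrame:
    """A 1:1 synthetic ICD -> Phecode map (stand-in for versioned maps)."""
    return pd.DataFrame(
        {
            "icd_code": [f"SYN{j:03d}" for j in range(n_codes)],
            "phecode": [f"PC{j:03d}" for j in range(n_codes)],
        }
    )


@dataclass
class PhenotypeData:
    """Simulated phenotypes: labs, ICD code events, covariates, truth."""

    quantitative: pd.DataFrame  # individuals x quantitative phenotypes
    code_events: pd.DataFrame  # long: individual_id, code (one row/event)
    covariates: pd.DataFrame  # sex, age
    binary_truth: pd.DataFrame  # individuals x binary phenotypes (0/1)
    phecode_map: pd.DataFrame


def generate_phenotypes(
    dosages: pd.DataFrame,
    truth: GroundTruth,
    h2: float = 0.3,
    prevalence: float = 0.1,
    seed: int = 0,
    single_code_fraction: float = 0.02,
) -> PhenotypeData:
    """Phenotypes driven by the planted cluster scores.

    Quantitative phenotype j is a linear combination of the z-scored raw
    cluster scores (weights ``truth.pheno_effects[:, j]``) plus Gaussian
    noise scaled so the genetic score explains fraction ``h2`` of the
    variance.  Binary phenotypes threshold the analogous liability at the
    requested prevalence; cases receive two ICD code events (so they meet
    the two-code Phecode rule) and a ``single_code_fraction`` of
    non-cases receive exactly one event to exercise the exclusion rule.
    """
    if not 0.0 < h2 < 1.0:
        raise ValueError("h2 must lie in (0, 1)")
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie in (0, 1)")
    if dosages.shape[1] != truth.n_variants:
        raise ValueError("dosage panel width must match the ground truth")
    rng = np.random.default_rng(seed)
    n = dosages.shape[0]
    K = truth.K_true

    raw = dosages.to_numpy() @ truth.H_true.T  # n x K raw cluster scores
    sd = raw.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    z = (raw - raw.mean(axis=0)) / sd

    def genetic_component(j: int) -> np.ndarray:
        g = z @ truth.pheno_effects[:, j]
        var_g = g.var(ddof=1)
        if var_g == 0:
            return rng.normal(0.0, 1.0, size=n)
        noise_sd = np.sqrt(var_g * (1.0 - h2) / h2)
        return g + rng.normal(0.0, noise_sd, size=n)

    quant = pd.DataFrame(
        {f"quant_c{k}": genetic_component(k) for k in range(K)}, index=dosages.index
    )

    phecode_map = toy_phecode_map(max(K, 1))
    events: list[tuple[str, str]] = []
    binary_truth = {}
    for k in range(K):
        liability = genetic_component(K + k)
        thresh = np.quantile(liability, 1.0 - prevalence)
        case = liability > thresh
        binary_truth[f"PC{k:03d}"] = case.astype(int)
        icd = f"SYN{k:03d}"
        for ind, is_case in zip(dosages.index, case):
            if is_case:
                n_ev = 2 + int(rng.random() < 0.3)
                events.extend([(ind, icd)] * n_ev)
            elif rng.random() < single_code_fraction:
                events.append((ind, icd))

    covariates = pd.DataFrame(
        {
            "sex": rng.integers(0, 2, size=n),
            "age": rng.uniform(20.0, 80.0, size=n).round(1),
        },
        index=dosages.index,
    )
    return PhenotypeData(
        quantitative=quant,
        code_events=pd.DataFrame(events, columns=["individual_id", "code"]),
        covariates=covariates,
        binary_truth=pd.DataFrame(binary_truth, index=dosages.index),
        phecode_map=phecode_map,
    )


def variants_for_truth(truth: GroundTruth) -> list[VariantRecord]:
    """Lead-variant records for the synthetic panel (A/G, A decreasing)."""
    return [
        VariantRecord(
            rsid=rsid,
            chrom="1",
            pos=10_000 + 100 * v,
            effect_allele="A",
            other_allele="G",
            kidney_decreasing_allele="A",
        )
        for v, rsid in enumerate(truth.variant_labels)
    ]


def identity_proxies(truth: GroundTruth) -> list[ProxyLink]:
    """Each lead variant acting as its own proxy (r2 = 1)."""
    return [ProxyLink(rsid, rsid, 1.0) for rsid in truth.variant_labels]


def write_dataset(
    out_dir: str | Path,
    truth: GroundTruth,
    records: list[TraitAssociation],
    genotypes: GenotypeData,
    phenotypes: PhenotypeData,
) -> None:
    """Write the full synthetic dataset in the pipeline's file formats."""
    from . import io as ckio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ckio.write_variants(out / "variants.tsv", variants_for_truth(truth))
    ckio.write_proxies(out / "proxies.tsv", identity_proxies(truth))
    ckio.write_associations(out / "associations.tsv", records)
    ckio.write_dosages(out / "dosages.tsv", genotypes.dosages)
    ckio.write_vcf(out / "genotypes.vcf", genotypes.dosages)
    genotypes.group_labels.to_frame().to_csv(out / "groups.csv")
    phenotypes.quantitative.to_csv(out / "phenotypes.csv", index_label="individual_id")
    phenotypes.code_events.to_csv(out / "code_events.csv", index=False)
    phenotypes.covariates.to_csv(out / "covariates.csv", index_label="individual_id")
    phenotypes.phecode_map.to_csv(out / "phecode_map.csv", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(
            {
                "K_true": truth.K_true,
                "seed": truth.seed,
                "W_true": truth.W_true.tolist(),
                "H_true": truth.H_true.tolist(),
                "effect_sign": truth.effect_sign.tolist(),
                "pheno_effects": truth.pheno_effects.tolist(),
                "trait_labels": truth.trait_labels,
                "variant_labels": truth.variant_labels,
            },
            fh,
        )
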