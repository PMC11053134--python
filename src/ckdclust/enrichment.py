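"""Gene-set enrichment of cluster variant weights.

Per-cluster gene scores are the maximum H weight over a gene's variants
(closest-gene assignment is an input map, not a computation).  Two tests
are offered against user-supplied GMT gene sets: a preranked GSEA with
the classic weighted Kolmogorov-Smirnov running-sum statistic and a
gene-label permutation null, and a hypergeometric overrepresentation
test of the top-weighted genes.  q-values are Benjamini-Hochberg within
each result list; the gene universe is the set of mapped genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetResult",
    "gene_ranks",
    "enrichment_score",
    "gsea_prerank",
    "ora_hypergeometric",
    "top_fraction_genes",
]


@dataclass
class GeneSetResult:
    name: str
    statistic: float  # ES for GSEA, fold-enrichment for ORA
    nes: float | None
    p: float
    q: float
    size: int
    overlap: int | None = None


def gene_ranks(
    H: pd.DataFrame, variant_gene_map: dict[str, str] | pd.Series
) -> tuple[dict[str, pd.Series], dict]:
    """Per-cluster gene scores: max variant weight per gene.

    ``H`` is clusters x variants; ``variant_gene_map`` maps variant id
    to its (single, closest) gene.  Variants without a gene are logged.
    """
    if isinstance(variant_gene_map, pd.Series):
        variant_gene_map = variant_gene_map.to_dict()
    if not variant_gene_map:
        raise ValueError("variant -> gene map is empty")
    unmapped = [v for v in H.columns if v not in variant_gene_map]
    mapped_cols = [v for v in H.columns if v in variant_gene_map]
    genes = pd.Series({v: variant_gene_map[v] for v in mapped_cols})
    ranks = {}
    for cluster, row in H.iterrows():
        ranks[str(cluster)] = row[mapped_cols].groupby(genes).max().sort_values(
            ascending=False
        )
    return ranks, {"unmapped_variants": unmapped}


def enrichment_score(
    ranked_genes: list[str],
    scores: np.ndarray,
    gene_set: set[str],
    weight: float = 1.0,
) -> float:
    """Weighted KS enrichment score on a descending-ranked gene list.

    Hits advance the running sum by |score|^weight (normalized over the
    set's hits), misses retreat by 1/(N - |set|); the ES is the running
    sum value of largest magnitude.
    """
    N = len(ranked_genes)
    hit = np.array([g in gene_set for g in ranked_genes])
    n_hit = int(hit.sum())
    if n_hit == 0 or n_hit == N:
        raise ValueError("gene set must be a proper non-empty subset of the list")
    w = np.abs(np.asarray(scores, dtype=float)) ** weight
    hit_sum = w[hit].sum()
    steps = np.where(hit, w / hit_sum if hit_sum > 0 else 1.0 / n_hit, -1.0 / (N - n_hit))
    if hit_sum == 0:  # all-zero scores inside the set: uniform hit steps
        steps = np.where(hit, 1.0 / n_hit, -1.0 / (N - n_hit))
    running = np.cumsum(steps)
    return float(running[np.abs(running).argmax()])


def gsea_prerank(
    ranks: pd.Series,
    gene_sets: dict[str, list[str]],
    n_perm: int = 1000,
    seed: int | None = None,
    weight: float = 1.0,
    min_size: int = 3,
    max_size: int = 500,
) -> tuple[list[GeneSetResult], dict]:
    """Preranked GSEA over a dict of gene sets.

    Sets are filtered to genes present in ``ranks`` and skipped when the
    filtered size falls outside [min_size, max_size] or equals the whole
    universe.  The null permutes gene labels (equivalently, redraws the
    set at random); NES divides the ES by the mean |null ES| of the same
    sign; p is the two-sided empirical tail with the +1 correction.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    ranks = ranks.sort_values(ascending=False)
    genes = list(ranks.index)
    scores = ranks.to_numpy(dtype=float)
    N = len(genes)
    rng = np.random.default_rng(seed)

    skipped = {}
    rows = []
    for name, members in gene_sets.items():
        inset = set(members) & set(genes)
        size = len(inset)
        if size < min_size or size > max_size:
            skipped[name] = f"size {size} outside [{min_size}, {max_size}]"
            continue
        if size == N:
            skipped[name] = "set equals the whole universe"
            continue
        es = enrichment_score(genes, scores, inset, weight)
        null = np.empty(n_perm)
        for i in range(n_perm):
            perm = set(rng.choice(N, size=size, replace=False))
            hit_set = {genes[j] for j in perm}
            null[i] = enrichment_score(genes, scores, hit_set, weight)
        same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
        denom = np.abs(same_sign).mean() if same_sign.size else np.abs(null).mean()
        nes = es / denom if denom > 0 else 0.0
        p = (1.0 + np.sum(np.abs(null) >= abs(es))) / (1.0 + n_perm)
        rows.append((name, es, nes, p, size))

    qs = multipletests([r[3] for r in rows], method="fdr_bh")[1] if rows else []
    results = [
        GeneSetResult(name=name, statistic=es, nes=nes, p=p, q=float(q), size=size)
        for (name, es, nes, p, size), q in zip(rows, qs)
    ]
    return results, {"skipped": skipped}


def top_fraction_genes(
    H_row: pd.Series, variant_gene_map: dict[str, str] | pd.Series, top_frac: float = 0.25
) -> set[str]:
    """Genes annotated to the top-weighted fraction of a cluster's variants."""
    if isinstance(variant_gene_map, pd.Series):
        variant_gene_map = variant_gene_map.to_dict()
    ordered = H_row.sort_values(ascending=False)
    n_top = max(1, int(np.ceil(top_frac * len(ordered))))
    return {
        variant_gene_map[v] for v in ordered.index[:n_top] if v in variant_gene_map
    }


def ora_hypergeometric(
    top_genes: set[str],
    universe: set[str],
    gene_sets: dict[str, list[str]],
) -> list[GeneSetResult]:
    """Hypergeometric overrepresentation of top genes in each set.

    With universe size N, set size K, draw size n and overlap k the
    p-value is P(X >= k); fold enrichment is (k/n) / (K/N).
    """
    if not universe:
        raise ValueError("gene universe is empty")
    if not set(top_genes) <= set(universe):
        raise ValueError("top_genes must be a subset of the universe")
    N = len(universe)
    n = len(top_genes)
    rows = []
    for name, members in gene_sets.items():
        inset = set(members) & universe
        K = len(inset)
        if K == 0:
            continue
        k = len(top_genes & inset)
        p = float(hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N) if n > 0 else np.nan
        rows.append((name, fold, p, K, k))
    qs = multipletests([r[2] for r in rows], method="fdr_bh")[1] if rows else []
    return [
        GeneSetResult(name=name, statistic=fold, nes=None, p=p, q=float(q),
                      size=K, overlap=k)
        for (name, fold, p, K, k), q in zip(rows, qs)
    ]
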