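"""End-to-end glue: synthetic records -> matrix -> clustering -> scores.

These helpers chain the module-level operations in the order the
analysis runs, and provide the Hungarian-matching recovery metrics used
to evaluate planted-cluster simulations.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

from . import assoc, synthetic
from .assoc import AssociationMatrix
from .nmf import RankScan, rank_scan

__all__ = [
    "matrix_from_truth",
    "variant_assignment_accuracy",
    "discover",
]


def matrix_from_truth(
    truth: synthetic.GroundTruth,
    noise_sd: float = 0.1,
    n_decoys: int = 0,
    seed: int = 0,
) -> tuple[AssociationMatrix, assoc.FilterLog]:
    """Run the full record path: generate, filter, standardize, align, build."""
    records = synthetic.generate_association_records(
        truth, noise_sd=noise_sd, n_decoys=n_decoys, seed=seed
    )
    kept, log = assoc.filter_associations(records)
    kept = assoc.standardize_effects(kept)
    aligned = assoc.align_to_lead(
        kept,
        synthetic.identity_proxies(truth),
        synthetic.variants_for_truth(truth),
        log=log,
    )
    return assoc.build_matrix(aligned, provenance=log), log


def variant_assignment_accuracy(
    H: np.ndarray,
    truth: synthetic.GroundTruth,
    variant_labels: list[str] | None = None,
) -> float:
    """Hungarian-matched accuracy of argmax variant cluster assignment.

    Estimated clusters are matched to planted clusters by maximizing the
    confusion-matrix trace over permutations; accuracy is the matched
    fraction of variants.  ``variant_labels`` maps the columns of H back
    to ground-truth variants (needed when the matrix dropped or
    reordered variants); defaults to identity order.
    """
    true_all = truth.dominant_variant_cluster
    if variant_labels is not None:
        pos = {rsid: v for v, rsid in enumerate(truth.variant_labels)}
        idx = [pos[lab] for lab in variant_labels]
        true_lab = true_all[idx]
    else:
        true_lab = true_all[: H.shape[1]]
    est_lab = np.asarray(H).argmax(axis=0)
    K_est, K_true = np.asarray(H).shape[0], truth.K_true
    conf = np.zeros((K_est, K_true))
    for e, t in zip(est_lab, true_lab):
        conf[e, t] += 1
    rows, cols = linear_sum_assignment(-conf)
    return float(conf[rows, cols].sum() / len(est_lab))


def discover(
    X,
    k_range: tuple[int, int] = (2, 20),
    n_restarts: int = 30,
    max_iter: int = 10_000,
    conv_window: int = 80,
    seed: int | None = None,
) -> RankScan:
    """Rank-scan the association matrix; alias with pipeline defaults."""
    return rank_scan(
        X,
        k_range=k_range,
        n_restarts=n_restarts,
        max_iter=max_iter,
        conv_window=conv_window,
        seed=seed,
    )
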