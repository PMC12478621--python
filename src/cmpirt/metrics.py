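"""Evaluation criteria for simulation studies.

* CER (correct estimation rate): the fraction of unconstrained
  discrimination entries whose exact zero/nonzero status matches the truth.
  The zero test is exact — rotated solutions, which cannot produce exact
  zeros, legitimately score poorly on it.
* Gram off-diagonal metrics: bias/RMSE of the off-diagonal entries of
  Lambda Phi Lambda', a rotation-invariant measure of item-pair association.
* bias/RMSE of intercepts and log-dispersions across trials.

Trait labels and signs are arbitrary, so the truth is aligned to each
estimate by greedy absolute-congruence column matching before CER scoring
(which leaves the estimate's constrained positions where they are).
"""

from __future__ import annotations

import numpy as np

from cmpirt.em import ConstraintMask
from cmpirt.rotation import align_columns

__all__ = ["cer", "gram_offdiag_metrics", "bias_rmse"]


def cer(A_hat, A_true, mask: ConstraintMask, align: bool = True) -> float:
    """Correct estimation rate over unconstrained discrimination entries.

    CER = (1 / (M L - c)) * sum over free (j, l) of
          1{ 1(A_hat_jl != 0) = 1(A_true_jl != 0) },
    with c the number of identification constraints.  ``align`` permutes and
    sign-flips the *truth's* columns toward the estimate first.
    """
    A_hat = np.asarray(A_hat, dtype=float)
    A_true = np.asarray(A_true, dtype=float)
    if A_hat.shape != A_true.shape:
        raise ValueError("shape mismatch between estimate and truth")
    if align:
        A_true, _, _ = align_columns(A_true, A_hat)
    free = mask.free()
    agree = (A_hat[free] != 0.0) == (A_true[free] != 0.0)
    return float(agree.mean())


def gram_offdiag_metrics(A_hat, phi_hat, A_true, phi_true):
    """Bias and RMSE of the upper off-diagonal of Lambda Phi Lambda'."""
    G_hat = np.asarray(A_hat) @ np.asarray(phi_hat) @ np.asarray(A_hat).T
    G_true = np.asarray(A_true) @ np.asarray(phi_true) @ np.asarray(A_true).T
    iu = np.triu_indices_from(G_hat, k=1)
    diff = G_hat[iu] - G_true[iu]
    return float(diff.mean()), float(np.sqrt((diff**2).mean()))


def bias_rmse(estimates, truth):
    """Per-item bias and RMSE over trials, with condition-level summaries.

    ``estimates``: (n_trials, M) array of per-trial estimates of one
    parameter family; ``truth``: (M,) true values.  Returns a dict with
    per-item vectors and scalar summaries (mean over items, between-item
    standard deviation).
    """
    est = np.atleast_2d(np.asarray(estimates, dtype=float))
    truth = np.asarray(truth, dtype=float)
    diff = est - truth[None, :]
    item_bias = diff.mean(axis=0)
    item_rmse = np.sqrt((diff**2).mean(axis=0))
    return {
        "item_bias": item_bias,
        "item_rmse": item_rmse,
        "bias": float(item_bias.mean()),
        "bias_sd": float(item_bias.std(ddof=0)),
        "rmse": float(item_rmse.mean()),
        "rmse_sd": float(item_rmse.std(ddof=0)),
    }
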