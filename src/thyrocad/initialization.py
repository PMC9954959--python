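"""Fuzzy c-means initialization of the rule base.

The rule structure is cluster-based: fuzzy c-means (FCM) is run on the
scaled training inputs with one cluster per rule, cluster centers become
premise centers, and premise spreads are the membership-weighted standard
deviations around each center.  Consequents are then set by a single global
least-squares solve (the same solve the hybrid trainer uses), so the
starting model is already consequent-optimal for its premises.

FCM follows the classic alternating scheme: with fuzzifier ``m`` it
minimizes  J = sum_{k,i} u_ki^m ||x_k - c_i||^2  subject to rows of U
summing to one, iterating the closed-form center and membership updates
until the objective decrease falls below ``tol``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fis_core import SIGMA_FLOOR, AnfisModel, decode, parameter_count
from .trainers import solve_consequents_ls

__all__ = ["FcmResult", "fcm", "init_model_from_fcm"]


@dataclass(frozen=True)
class FcmResult:
    """Fuzzy partition of the training inputs.

    ``centers`` is (n_clusters, n_features); ``memberships`` is the fuzzy
    partition matrix U, (n_samples, n_clusters) with rows summing to one;
    ``objective_trace`` records J after every iteration (non-increasing).
    """

    centers: np.ndarray
    memberships: np.ndarray
    objective_trace: np.ndarray


def fcm(
    data: np.ndarray,
    n_clusters: int,
    fuzzifier: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 200,
    seed: int = 0,
) -> FcmResult:
    """Bezdek fuzzy c-means on ``data`` (n_samples, n_features)."""
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValueError("data must be a 2-D array")
    n, _ = X.shape
    if not 1 <= n_clusters <= n:
        raise ValueError(f"need 1 <= n_clusters <= n_samples, got {n_clusters}")
    if not fuzzifier > 1:
        raise ValueError("fuzzifier must exceed 1")

    rng = np.random.default_rng(seed)
    U = rng.uniform(size=(n, n_clusters))
    U /= U.sum(axis=1, keepdims=True)

    trace: list[float] = []
    prev = np.inf
    for _ in range(max_iter):
        Um = U**fuzzifier
        centers = (Um.T @ X) / Um.sum(axis=0)[:, None]
        # squared distances; zeros jittered so the membership update is defined
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        d2 = np.maximum(d2, 1e-12)
        obj = float(np.sum(Um * d2))
        exp = 1.0 / (fuzzifier - 1.0)
        inv = d2 ** (-exp)
        U = inv / inv.sum(axis=1, keepdims=True)
        trace.append(obj)
        if prev - obj < tol:
            break
        prev = obj

    return FcmResult(
        centers=centers, memberships=U, objective_trace=np.array(trace)
    )


def init_model_from_fcm(
    result: FcmResult,
    data: np.ndarray,
    targets: np.ndarray,
    input_scaling: tuple[tuple[float, float], ...],
    fuzzifier: float = 2.0,
) -> AnfisModel:
    """Build the initial ANFIS model from an FCM partition.

    Premise centers are the cluster centers; sigma_ij is the weighted
    standard deviation  sqrt( sum_k u_ki^m (x_kj - c_ij)^2 / sum_k u_ki^m ),
    clamped below by SIGMA_FLOOR (a cluster collapsed onto a single point
    would otherwise produce a zero spread).  Consequents come from the
    exact least-squares solve, so no other consequent choice has lower
    training RMSE for these premises.
    """
    X = np.asarray(data, dtype=float)
    y = np.asarray(targets, dtype=float)
    centers = result.centers
    n_rules, n_inputs = centers.shape
    if X.shape[1] != n_inputs:
        raise ValueError("data and cluster centers disagree on dimension")

    Um = result.memberships**fuzzifier                    # (N, R)
    dev2 = (X[:, None, :] - centers[None, :, :]) ** 2     # (N, R, n)
    sigmas = np.sqrt(
        np.einsum("nr,nrj->rj", Um, dev2) / Um.sum(axis=0)[:, None]
    )
    sigmas = np.maximum(sigmas, SIGMA_FLOOR)

    values = np.zeros(parameter_count(n_inputs, n_rules))
    n_premise = 2 * n_inputs * n_rules
    values[:n_premise] = np.stack([centers, sigmas], axis=2).ravel()
    model = decode(values, n_inputs, n_rules, input_scaling)
    return solve_consequents_ls(model, X, y)
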