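"""Evaluation protocol: data splitting, confusion metrics, aggregation.

The study design evaluates each trainer under four splitting schemes —
70/30 and 80/20 stratified holdouts plus 5- and 10-fold cross-validation —
and reports accuracy, sensitivity and specificity as percentages, with the
malignant class as positive:

    AC = (TP + TN) / (TP + TN + FP + FN) * 100
    SN = TP / (TP + FN) * 100
    SP = TN / (TN + FP) * 100

K-fold metrics are computed by default from confusion counts pooled over
the test folds (a flag switches to averaging per-fold percentages).
Splitting is stratified by default: with a 28.6% benign prevalence an
unstratified small test set can end up with almost no benign nodules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from . import trainers as _trainers
from .fis_core import AnfisModel, apply_scaling, classify, fit_scaling
from .initialization import fcm, init_model_from_fcm
from .synthetic_nodules import NoduleTable

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "SplitPlan",
    "metrics",
    "make_splits",
    "confusion_from_pairs",
    "fit_anfis",
    "evaluate_trainer",
    "aggregate_mean",
    "round2",
    "TRAINERS",
]

SCHEMES = ("holdout_70_30", "holdout_80_20", "kfold_5", "kfold_10")

TRAINERS = {
    "ga": (_trainers.train_ga, _trainers.GaConfig),
    "bp": (_trainers.train_bp, _trainers.BpConfig),
    "hybrid": (_trainers.train_hybrid, _trainers.BpConfig),
}


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn,
            self.fp + other.fp, self.fn + other.fn,
        )


@dataclass(frozen=True)
class MetricSet:
    """Accuracy / sensitivity / specificity as percentages in [0, 100]."""

    accuracy: float
    sensitivity: float
    specificity: float


@dataclass(frozen=True)
class SplitPlan:
    scheme: str
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}, got {self.scheme!r}")


def round2(x: float) -> float:
    """Round to 2 decimals with ties away from zero (half-up), as in the
    report tables."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"),
                                                  rounding=ROUND_HALF_UP))


def metrics(c: ConfusionCounts) -> MetricSet:
    """Confusion counts to percentage metrics.

    An undefined ratio (no actual positives for SN, no actual negatives
    for SP) is reported as NaN with a warning rather than silently zeroed.
    """
    if c.total == 0:
        raise ValueError("metrics of an empty confusion table are undefined")
    ac = (c.tp + c.tn) / c.total * 100.0
    if c.tp + c.fn == 0:
        warnings.warn("no positive samples: sensitivity undefined", stacklevel=2)
        sn = float("nan")
    else:
        sn = c.tp / (c.tp + c.fn) * 100.0
    if c.tn + c.fp == 0:
        warnings.warn("no negative samples: specificity undefined", stacklevel=2)
        sp = float("nan")
    else:
        sp = c.tn / (c.tn + c.fp) * 100.0
    return MetricSet(accuracy=ac, sensitivity=sn, specificity=sp)


def confusion_from_pairs(labels: np.ndarray, predictions: np.ndarray) -> ConfusionCounts:
    """Count a confusion table from 0/1 label and prediction vectors."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predictions, dtype=int)
    if y.shape != p.shape:
        raise ValueError("labels and predictions disagree on shape")
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & (p == 1))),
        tn=int(np.sum((y == 0) & (p == 0))),
        fp=int(np.sum((y == 0) & (p == 1))),
        fn=int(np.sum((y == 1) & (p == 0))),
    )


# ---------------------------------------------------------------------------
# splitting


def _stratified_allocation(
    class_indices: list[np.ndarray], k: int
) -> list[list[np.ndarray]]:
    """Allocate each class's (already shuffled) indices over k folds.

    Every fold receives floor(n_c / k) samples of class c plus at most one
    extra; extras go to the currently least-loaded fold, which keeps
    overall fold sizes within one of each other.
    """
    per_fold: list[list[np.ndarray]] = [[] for _ in range(k)]
    totals = np.zeros(k, dtype=int)
    for idx in class_indices:
        q, r = divmod(idx.size, k)
        counts = np.full(k, q)
        order = np.lexsort((np.arange(k), totals))  # least loaded, lowest index
        counts[order[:r]] += 1
        pos = 0
        for fold in range(k):
            per_fold[fold].append(idx[pos : pos + counts[fold]])
            pos += counts[fold]
        totals += counts
    return per_fold


def make_splits(
    table: NoduleTable, plan: SplitPlan
) -> list[tuple[np.ndarray, np.ndarray]]:
    """(train_indices, test_indices) pairs for the plan.

    Holdout schemes return one pair with the test size rounded down
    (e.g. 398 samples at 70/30 give a 119-sample test set); k-fold schemes
    return K disjoint pairs covering every index.  Deterministic per seed.
    """
    n = table.n
    rng = np.random.default_rng(plan.seed)
    y = table.labels
    if plan.stratified:
        groups = [np.flatnonzero(y == cls) for cls in sorted(np.unique(y))]
        if plan.scheme.startswith("kfold"):
            k = int(plan.scheme.split("_")[1])
            short = [g.size for g in groups if g.size < k]
            if short:
                raise ValueError(
                    f"a class has fewer samples than the {k} folds"
                )
    else:
        groups = [np.arange(n)]
    groups = [rng.permutation(g) for g in groups]

    if plan.scheme.startswith("holdout"):
        frac = {"holdout_70_30": 0.30, "holdout_80_20": 0.20}[plan.scheme]
        n_test = int(np.floor(frac * n))
        want = np.array([frac * g.size for g in groups])
        take = np.floor(want).astype(int)
        # largest remainders top up to the exact global test size
        for j in np.argsort(-(want - take), kind="stable")[: n_test - take.sum()]:
            take[j] += 1
        test = np.concatenate([g[:t] for g, t in zip(groups, take)])
        train = np.concatenate([g[t:] for g, t in zip(groups, take)])
        return [(np.sort(train), np.sort(test))]

    k = int(plan.scheme.split("_")[1])
    per_fold = _stratified_allocation(groups, k)
    folds = [np.sort(np.concatenate(parts)) for parts in per_fold]
    out = []
    for i in range(k):
        test = folds[i]
        train = np.sort(np.concatenate([folds[j] for j in range(k) if j != i]))
        out.append((train, test))
    return out


# ---------------------------------------------------------------------------
# training pipeline


def fit_anfis(
    X_raw: np.ndarray,
    y: np.ndarray,
    trainer="ga",
    trainer_cfg=None,
    n_rules: int = 10,
    seed: int = 0,
):
    """Scale, cluster-initialize and train one ANFIS model.

    ``trainer`` is one of the registered names ("ga", "bp", "hybrid") or
    any callable with the trainer signature
    ``(data, targets, template_model, cfg) -> TrainResult``.

    Training inputs are min–max scaled to [0, 1]; fuzzy c-means with one
    cluster per rule places the initial premises and the least-squares
    solve sets the initial consequents; the chosen trainer then optimizes
    the full parameter vector.  Returns the TrainResult; the model inside
    carries the training scaling for reuse on test data.
    """
    if callable(trainer):
        train_fn = trainer
    elif trainer in TRAINERS:
        train_fn, cfg_cls = TRAINERS[trainer]
        if trainer_cfg is None:
            trainer_cfg = (cfg_cls(seed=seed) if cfg_cls is _trainers.GaConfig
                           else cfg_cls())
    else:
        raise ValueError(f"unknown trainer {trainer!r}; choose from {sorted(TRAINERS)}")
    X_raw = np.asarray(X_raw, dtype=float)
    y = np.asarray(y, dtype=float)
    scaling = fit_scaling(X_raw)
    Xs = apply_scaling(scaling, X_raw)
    part = fcm(Xs, n_clusters=n_rules, seed=seed)
    template = init_model_from_fcm(part, Xs, y, scaling)
    return train_fn(Xs, y, template, trainer_cfg)


def predict(model: AnfisModel, X_raw: np.ndarray) -> np.ndarray:
    """0/1 class predictions for raw-code inputs."""
    return classify(model, apply_scaling(model.input_scaling, X_raw))


def evaluate_trainer(
    table: NoduleTable,
    plan: SplitPlan,
    trainer="ga",
    trainer_cfg=None,
    n_rules: int = 10,
    pool_folds: bool = True,
) -> MetricSet:
    """Train under the plan and score the held-out data.

    Holdout: train on the train split, metrics on the test split.  K-fold:
    by default one confusion table pooled over all test folds; with
    ``pool_folds=False`` the per-fold percentage metrics are averaged
    instead.  Per-fold seeds derive deterministically from the plan seed.
    """
    X, y = table.X, table.labels
    splits = make_splits(table, plan)
    counts: list[ConfusionCounts] = []
    for i, (tr, te) in enumerate(splits):
        fold_seed = (plan.seed * 1009 + i) % (2**31)
        result = fit_anfis(X[tr], y[tr], trainer, trainer_cfg,
                           n_rules=n_rules, seed=fold_seed)
        counts.append(confusion_from_pairs(y[te], predict(result.model, X[te])))
    if len(counts) == 1 or pool_folds:
        pooled = counts[0]
        for c in counts[1:]:
            pooled = pooled + c
        return metrics(pooled)
    return aggregate_mean([metrics(c) for c in counts])


def aggregate_mean(metric_rows: list[MetricSet]) -> MetricSet:
    """Arithmetic mean of each metric across rows, to 2 decimals half-up.

    This is the overall-performance aggregation: one row per
    (sign-set, splitting-scheme) experiment, averaged into a single
    AC/SN/SP summary per trainer.
    """
    if not metric_rows:
        raise ValueError("cannot aggregate zero metric rows")
    return MetricSet(
        accuracy=round2(float(np.mean([m.accuracy for m in metric_rows]))),
        sensitivity=round2(float(np.mean([m.sensitivity for m in metric_rows]))),
        specificity=round2(float(np.mean([m.specificity for m in metric_rows]))),
    )
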