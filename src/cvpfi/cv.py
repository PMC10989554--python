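"""Fold planning and pooled out-of-fold prediction.

Fold counts follow sample-size rules tuned for small-data regression:
leave-one-out below 30 samples, 10-fold up to 100, 5-fold from 100 on.
Out-of-fold predictions are pooled back into one full-length vector and
scored once ("integrated" scoring), rather than averaging per-fold scores —
with few samples a per-fold r^2 on a handful of points is meaningless, while
the pooled vector always scores m points.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

__all__ = ["FoldPlan", "choose_fold_count", "make_fold_plan", "pooled_cv_predict"]


@dataclass
class FoldPlan:
    """A partition of {0..m-1} into disjoint validation blocks.

    Each fold is a (train_indices, validation_indices) pair; the train block
    is the complement of its validation block.
    """

    folds: list[tuple[np.ndarray, np.ndarray]]
    n_splits: int
    seed: int

    @property
    def m(self) -> int:
        return sum(len(v) for _, v in self.folds)

    def __iter__(self):
        return iter(self.folds)

    def validation_blocks(self) -> list[list[int]]:
        return [list(map(int, v)) for _, v in self.folds]


def choose_fold_count(m: int, override: int | None = None) -> int:
    """Fold count by sample size: LOO for m < 30, 10-fold for m < 100, else 5.

    An explicit ``override`` wins (validated against m in make_fold_plan).
    """
    if m < 4:
        raise ValueError(f"need at least 4 samples (got {m})")
    if override is not None:
        return int(override)
    if m < 30:
        return m
    if m < 100:
        return 10
    return 5


def make_fold_plan(m: int, n_splits: int, seed: int) -> FoldPlan:
    """Shuffle indices with ``seed`` and split into ``n_splits`` blocks.

    Blocks have size floor(m/N) or ceil(m/N). Deterministic given
    (m, n_splits, seed).
    """
    if n_splits < 2 or n_splits > m:
        raise ValueError(f"fold count must satisfy 2 <= N <= m (got N={n_splits}, m={m})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(m)
    folds = []
    for block in np.array_split(order, n_splits):
        val = np.sort(block)
        train = np.setdiff1d(np.arange(m), val, assume_unique=True)
        folds.append((train, val))
    return FoldPlan(folds=folds, n_splits=n_splits, seed=seed)


def _clone_estimator(estimator):
    if hasattr(estimator, "clone"):
        return estimator.clone()
    try:
        from sklearn.base import clone

        return clone(estimator)
    except Exception:
        return copy.deepcopy(estimator)


def pooled_cv_predict(estimator, X, y, plan: FoldPlan, return_models: bool = False):
    """Out-of-fold predictions reassembled in original row order.

    For each fold a fresh copy of ``estimator`` is fitted on the train block
    and predicts the validation block; every row receives exactly one
    prediction. With ``return_models=True`` the per-fold fitted estimators
    are returned as well (in fold order) for reuse on corrupted blocks.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    m = X.shape[0]
    if y.shape[0] != m or plan.m != m:
        raise ValueError("X, y and the fold plan disagree on the sample count")

    pooled = np.full(m, np.nan)
    models = []
    for k, (train, val) in enumerate(plan):
        model = _clone_estimator(estimator)
        try:
            model.fit(X[train], y[train])
            pred = np.asarray(model.predict(X[val]), dtype=float).ravel()
        except Exception as exc:
            raise RuntimeError(f"estimator failed on fold {k}") from exc
        if pred.shape[0] != len(val) or not np.isfinite(pred).all():
            name = getattr(estimator, "name", type(estimator).__name__)
            raise ValueError(f"estimator '{name}' returned invalid predictions on fold {k}")
        pooled[val] = pred
        models.append(model)
    assert not np.isnan(pooled).any()
    if return_models:
        return pooled, models
    return pooled
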