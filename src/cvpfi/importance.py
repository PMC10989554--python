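"""Permutation feature importance: conventional (PFI) and cross-validated (CVPFI).

Both methods measure how much a model's validation score drops when one
feature's values are decoupled from the rest of its row:

* PFI fits once on a train split and, per feature and repetition, shuffles
  that feature's validation column in place. With few samples the single
  split makes the estimate unstable, and a strongly correlated partner
  feature can stand in for the shuffled one, deflating its importance.

* CVPFI scores pooled out-of-fold CV predictions instead of a single split,
  and replaces the target column of each validation block with a
  without-replacement draw from the full original column (shuffling is
  impossible under leave-one-out, where validation blocks have one row).
  Each companion feature whose chance-correlation-gated absolute correlation
  with the target is rho > 0 is likewise replaced with probability rho, so
  correlated features share their corruption events and their importance is
  not drained away by mutual substitution.

Importance of feature i is the reference score minus the mean of the J
corrupted scores (r^2 for regression, accuracy for classification).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, r2_score

from .correlation import GatedCorrelationMatrix, gate_correlations
from .cv import FoldPlan, choose_fold_count, make_fold_plan, pooled_cv_predict

__all__ = [
    "ImportanceResults",
    "CVPFI",
    "PFI",
    "cvpfi",
    "pfi",
    "score",
    "corrupt_validation_block",
]


def score(y_true, y_pred, task: str = "regression") -> float:
    """Model score: coefficient of determination r^2 or exact-match accuracy."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or y_true.size < 2:
        raise ValueError("y_true and y_pred must be equal-length vectors of size >= 2")
    if task == "regression":
        y_true = y_true.astype(float)
        y_pred = y_pred.astype(float)
        if not (np.isfinite(y_true).all() and np.isfinite(y_pred).all()):
            raise ValueError("regression responses must be finite")
        if np.var(y_true) == 0.0:
            raise ValueError("r^2 is undefined for a constant y_true")
        return float(r2_score(y_true, y_pred))
    if task == "classification":
        return float(accuracy_score(y_true, y_pred))
    raise ValueError(f"unknown task '{task}'")


def _row_mean(scores: np.ndarray) -> np.ndarray:
    # arithmetic mean per row, exact when all J entries coincide — a feature
    # whose corruption never changed the score must report exactly zero
    mean = scores.mean(axis=1)
    same = np.all(scores == scores[:, :1], axis=1)
    return np.where(same, scores[:, 0], mean)


def corrupt_validation_block(
    X_original,
    validation_indices,
    target_feature: int,
    gated_row,
    rng,
    joint_rows: bool = False,
):
    """Corrupted copy of the validation rows of ``X_original``.

    The target column of the block is replaced by values sampled from the
    FULL original column at row positions drawn without replacement. Every
    other feature q with co-sampling probability gated_row[q] > 0 is
    replaced the same way with that probability (one Bernoulli draw per
    companion). With ``joint_rows=True`` companions reuse the target's row
    draw, which preserves the empirical target-companion association inside
    the corrupted block; by default the draws are independent.

    Rows outside the validation block are never touched (the caller only
    receives the block).
    """
    if rng is None:
        raise ValueError("an explicitly seeded rng is required for reproducibility")
    X_original = np.asarray(X_original, dtype=float)
    val = np.asarray(validation_indices, dtype=int)
    if val.size == 0:
        raise ValueError("validation block is empty")
    m, p = X_original.shape
    gated_row = np.asarray(gated_row, dtype=float)

    block = X_original[val].copy()
    rows_target = rng.choice(m, size=val.size, replace=False)
    block[:, target_feature] = X_original[rows_target, target_feature]
    for q in range(p):
        if q == target_feature or gated_row[q] <= 0.0:
            continue
        if rng.random() < gated_row[q]:
            rows_q = rows_target if joint_rows else rng.choice(m, size=val.size, replace=False)
            block[:, q] = X_original[rows_q, q]
    return block


@dataclass
class ImportanceResults:
    """Feature importances with their audit trail.

    The defining identity holds exactly:
    ``importances == reference_score - corrupted_scores.mean(axis=1)``.
    Negative importances are reported as-is — corrupting a feature can
    accidentally improve the score.
    """

    importances: np.ndarray
    reference_score: float
    corrupted_scores: np.ndarray  # p x J
    J: int
    method: str  # "cvpfi" | "pfi"
    seed: int
    feature_names: list[str]
    task: str = "regression"
    estimator_name: str = ""
    alpha: float | None = None
    gated_correlations: GatedCorrelationMatrix | None = None
    fold_plan: FoldPlan | None = None
    pooled_predictions: np.ndarray | None = None
    extra: dict = field(default_factory=dict)

    @property
    def p(self) -> int:
        return len(self.importances)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.feature_names,
                "importance": self.importances,
                "reference_score": self.reference_score,
                "J": self.J,
                "method": self.method,
                "seed": self.seed,
            }
        )

    def rank(self) -> pd.DataFrame:
        """Features sorted by descending importance, ties broken by index."""
        frame = self.to_frame()[["feature", "importance"]]
        order = np.lexsort((np.arange(self.p), -self.importances))
        return frame.iloc[order].reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path=None):
        """Full audit record including the per-repetition corrupted scores."""
        payload = {
            "method": self.method,
            "estimator": self.estimator_name,
            "task": self.task,
            "seed": self.seed,
            "J": self.J,
            "alpha": self.alpha,
            "reference_score": self.reference_score,
            "feature_names": self.feature_names,
            "importances": self.importances.tolist(),
            "corrupted_scores": self.corrupted_scores.tolist(),
        }
        if path is None:
            return json.dumps(payload, indent=2)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def summary(self) -> str:
        lines = [
            f"{'CVPFI' if self.method == 'cvpfi' else 'PFI'} results"
            + (f" ({self.estimator_name})" if self.estimator_name else ""),
            f"  reference score: {self.reference_score: .4f}"
            f"   J={self.J}  seed={self.seed}"
            + (f"  alpha={self.alpha}" if self.alpha is not None else ""),
            f"  {'feature':<20}{'importance':>12}{'sd over J':>12}",
        ]
        sd = self.corrupted_scores.std(axis=1)
        for name, imp, s in zip(self.feature_names, self.importances, sd):
            lines.append(f"  {name:<20}{imp:>12.4f}{s:>12.4f}")
        return "\n".join(lines)

    def plot(self, ax=None, roles=None):
        """Bar chart of importances, coloured by ground-truth role if given."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(max(6, self.p * 0.5), 4))
        palette = {
            "relevant-linear": "tab:blue",
            "relevant-nonlinear": "tab:blue",
            "irrelevant": "black",
            "correlated-block": "tab:red",
            "quantised": "tab:green",
        }
        colors = (
            [palette.get(r, "tab:gray") for r in roles]
            if roles is not None
            else "tab:blue"
        )
        ax.bar(range(self.p), self.importances, color=colors)
        ax.set_xticks(range(self.p))
        ax.set_xticklabels(self.feature_names, rotation=90)
        ax.set_ylabel(f"{self.method.upper()} importance")
        ax.set_title(self.estimator_name or self.method)
        return ax


def _as_matrix(X, y, feature_names):
    if isinstance(X, pd.DataFrame):
        feature_names = feature_names or list(map(str, X.columns))
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
    if feature_names is None:
        feature_names = [f"x{i + 1}" for i in range(X.shape[1])]
    y = np.asarray(y).ravel()
    if X.ndim != 2 or y.shape[0] != X.shape[0]:
        raise ValueError("X must be 2-D with one response value per row")
    return X, y, list(feature_names)


def _child_rng(seed: int, tag: int, i: int, j: int) -> np.random.Generator:
    # Independent stream per (feature, repetition): adding features or
    # repetitions never perturbs draws for earlier ones.
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(tag, i, j)))


class CVPFI:
    """Cross-validated permutation feature importance model.

    Parameters
    ----------
    X, y : array-like or DataFrame / Series
        Feature matrix (m x p) and response vector.
    estimator : object with fit/predict
        Refitted per CV fold; internals are never inspected. If it exposes
        ``select_hyperparameters(X, y)``, that is invoked once on the full
        data before the CV loop.
    task : "regression" (r^2 scoring) or "classification" (accuracy).
    alpha : coverage of the chance-correlation gate interval.
    n_folds : optional override of the sample-size fold rule.
    joint_rows : companions reuse the target's resampling rows (default off).
    """

    def __init__(
        self,
        X,
        y,
        estimator,
        task: str = "regression",
        alpha: float = 0.999,
        n_folds: int | None = None,
        joint_rows: bool = False,
        feature_names=None,
    ):
        self.X, self.y, self.feature_names = _as_matrix(X, y, feature_names)
        if self.X.shape[0] < 4:
            raise ValueError("need at least 4 samples")
        self.estimator = estimator
        self.task = task
        self.alpha = alpha
        self.n_folds = n_folds
        self.joint_rows = joint_rows

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, response, estimator, **kwargs):
        """Build from a table holding both features and the response column."""
        y = frame[response]
        X = frame.drop(columns=[response])
        return cls(X, y, estimator, **kwargs)

    def fit(self, J: int = 5, seed: int = 0) -> ImportanceResults:
        """Run the full CVPFI procedure and return the results object."""
        if J < 1:
            raise ValueError("J must be >= 1")
        X, y = self.X, self.y
        m, p = X.shape

        # Step 1-2: gated co-sampling probabilities from the FULL dataset.
        gated = gate_correlations(X, self.alpha, feature_names=self.feature_names)

        # Step 3: one shared fold plan; one fitted estimator per fold.
        n_folds = choose_fold_count(m, self.n_folds)
        plan = make_fold_plan(m, n_folds, seed)
        if hasattr(self.estimator, "select_hyperparameters"):
            self.estimator.select_hyperparameters(X, y)
        pooled_ref, models = pooled_cv_predict(self.estimator, X, y, plan, return_models=True)

        # Step 4: pooled reference score.
        reference = score(y, pooled_ref, self.task)

        # Steps 3-3 and 5: corrupted pooled scores per (feature, repetition).
        corrupted = np.empty((p, J))
        for i in range(p):
            row = gated.row(i)
            for j in range(J):
                rng = _child_rng(seed, 1, i, j)
                pooled_cor = np.empty(m)
                for k, (train, val) in enumerate(plan):
                    block = corrupt_validation_block(
                        X, val, i, row, rng, joint_rows=self.joint_rows
                    )
                    try:
                        pred = np.asarray(models[k].predict(block), dtype=float).ravel()
                    except Exception as exc:
                        raise RuntimeError(
                            f"estimator failed on fold {k}, feature {i}, repetition {j}"
                        ) from exc
                    if not np.isfinite(pred).all():
                        name = getattr(self.estimator, "name", type(self.estimator).__name__)
                        raise ValueError(
                            f"estimator '{name}' returned non-finite predictions "
                            f"(fold {k}, feature {i}, repetition {j})"
                        )
                    pooled_cor[val] = pred
                corrupted[i, j] = score(y, pooled_cor, self.task)

        # Step 6: importance identity.
        importances = reference - _row_mean(corrupted)
        return ImportanceResults(
            importances=importances,
            reference_score=reference,
            corrupted_scores=corrupted,
            J=J,
            method="cvpfi",
            seed=seed,
            feature_names=self.feature_names,
            task=self.task,
            estimator_name=getattr(self.estimator, "name", type(self.estimator).__name__),
            alpha=self.alpha,
            gated_correlations=gated,
            fold_plan=plan,
            pooled_predictions=pooled_ref,
        )


class PFI:
    """Conventional permutation feature importance on one train/validation split.

    The split is drawn with the fit seed; by default 25% of rows form the
    validation set. A single-row validation set makes shuffling a no-op and
    all importances exactly 0 (the failure mode that motivates CVPFI); a
    warning is emitted.
    """

    def __init__(
        self,
        X,
        y,
        estimator,
        task: str = "regression",
        validation_fraction: float = 0.25,
        feature_names=None,
    ):
        self.X, self.y, self.feature_names = _as_matrix(X, y, feature_names)
        self.estimator = estimator
        self.task = task
        if not 0.0 < validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")
        self.validation_fraction = validation_fraction

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, response, estimator, **kwargs):
        y = frame[response]
        X = frame.drop(columns=[response])
        return cls(X, y, estimator, **kwargs)

    def split_indices(self, seed: int) -> tuple[np.ndarray, np.ndarray]:
        m = self.X.shape[0]
        n_val = max(1, int(round(self.validation_fraction * m)))
        rng = np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(7,)))
        order = rng.permutation(m)
        return np.sort(order[n_val:]), np.sort(order[:n_val])

    def fit(self, J: int = 5, seed: int = 0) -> ImportanceResults:
        if J < 1:
            raise ValueError("J must be >= 1")
        train, val = self.split_indices(seed)
        res = _pfi_core(
            self.estimator,
            self.X[train],
            self.y[train],
            self.X[val],
            self.y[val],
            J=J,
            seed=seed,
            task=self.task,
            feature_names=self.feature_names,
        )
        res.extra["train_indices"] = train.tolist()
        res.extra["validation_indices"] = val.tolist()
        return res


def _pfi_core(estimator, X_train, y_train, X_val, y_val, J, seed, task, feature_names):
    X_train = np.asarray(X_train, dtype=float)
    X_val = np.asarray(X_val, dtype=float)
    y_train = np.asarray(y_train).ravel()
    y_val = np.asarray(y_val).ravel()
    p = X_val.shape[1]

    if X_val.shape[0] == 1:
        warnings.warn(
            "single-row validation set: a column permutation is a no-op and "
            "all PFI values are 0; use CVPFI instead",
            stacklevel=3,
        )
        corrupted = np.zeros((p, J))
        return ImportanceResults(
            importances=np.zeros(p),
            reference_score=0.0,
            corrupted_scores=corrupted,
            J=J,
            method="pfi",
            seed=seed,
            feature_names=list(feature_names),
            task=task,
            estimator_name=getattr(estimator, "name", type(estimator).__name__),
        )

    if hasattr(estimator, "select_hyperparameters"):
        estimator.select_hyperparameters(X_train, y_train)
    try:
        estimator.fit(X_train, y_train)
        ref_pred = np.asarray(estimator.predict(X_val), dtype=float).ravel()
    except Exception as exc:
        raise RuntimeError("estimator failed on the training split") from exc
    if not np.isfinite(ref_pred).all():
        name = getattr(estimator, "name", type(estimator).__name__)
        raise ValueError(f"estimator '{name}' returned non-finite predictions")
    reference = score(y_val, ref_pred, task)

    corrupted = np.empty((p, J))
    for i in range(p):
        for j in range(J):
            rng = _child_rng(seed, 2, i, j)
            block = X_val.copy()
            block[:, i] = rng.permutation(block[:, i])
            pred = np.asarray(estimator.predict(block), dtype=float).ravel()
            if not np.isfinite(pred).all():
                name = getattr(estimator, "name", type(estimator).__name__)
                raise ValueError(
                    f"estimator '{name}' returned non-finite predictions "
                    f"(feature {i}, repetition {j})"
                )
            corrupted[i, j] = score(y_val, pred, task)

    importances = reference - _row_mean(corrupted)
    return ImportanceResults(
        importances=importances,
        reference_score=reference,
        corrupted_scores=corrupted,
        J=J,
        method="pfi",
        seed=seed,
        feature_names=list(feature_names),
        task=task,
        estimator_name=getattr(estimator, "name", type(estimator).__name__),
    )


def cvpfi(
    estimator,
    X,
    y,
    J: int = 5,
    alpha: float = 0.999,
    seed: int = 0,
    fold_override: int | None = None,
    **kwargs,
) -> ImportanceResults:
    """Functional one-call CVPFI; see the CVPFI class for details."""
    model = CVPFI(X, y, estimator, alpha=alpha, n_folds=fold_override, **kwargs)
    return model.fit(J=J, seed=seed)


def pfi(estimator, X_train, y_train, X_val, y_val, J: int = 5, seed: int = 0,
        task: str = "regression", feature_names=None) -> ImportanceResults:
    """Conventional PFI on an explicit train/validation split."""
    X_val = np.asarray(X_val, dtype=float)
    if feature_names is None:
        feature_names = [f"x{i + 1}" for i in range(X_val.shape[1])]
    return _pfi_core(estimator, X_train, y_train, X_val, y_val, J, seed, task, feature_names)
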