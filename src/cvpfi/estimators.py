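"""Ready-made regression estimators for the importance machinery.

Any object with ``fit(X, y)`` and ``predict(X)`` works with the importance
routines; this module ships three families commonly used in QSPR work:

* ``pls`` — partial least squares, latent-variable count chosen by inner CV;
* ``svr`` — support-vector regression with a Gaussian kernel, (C, gamma,
  epsilon) chosen by inner grid-search CV;
* ``gpr`` — Gaussian-process regression with the kernel
  K(x_i, x_j) = theta0 * exp(-theta1/2 * ||x_i - x_j||^2) + theta2
  (plus a white-noise term), hyperparameters set by marginal-likelihood
  maximisation.

All families autoscale features inside ``fit`` using train-row statistics
only. Hyperparameter selection is exposed separately via
``select_hyperparameters`` so a caller running repeated CV can tune once on
the full data and then refit cheaply per fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np
from sklearn.base import clone as sk_clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

__all__ = [
    "EstimatorContract",
    "EstimatorConfig",
    "SuiteEstimator",
    "build_estimator",
    "gaussian_rbf_kernel",
]


@runtime_checkable
class EstimatorContract(Protocol):
    """Anything with fit/predict; the importance code never looks inside."""

    def fit(self, X, y): ...

    def predict(self, X): ...


@dataclass
class EstimatorConfig:
    """Configuration for one estimator family.

    ``hyperparameter_grid`` of None selects the family default; ``gpr`` uses
    marginal-likelihood optimisation instead of a grid.
    """

    family: str = "pls"
    hyperparameter_grid: dict | None = None
    inner_cv_folds: int = 5
    autoscale: bool = True

    def __post_init__(self):
        if self.family not in ("pls", "svr", "gpr"):
            raise ValueError(f"unknown estimator family '{self.family}'")
        if self.inner_cv_folds < 2:
            raise ValueError("inner_cv_folds must be >= 2")
        if self.hyperparameter_grid is not None and any(
            len(v) == 0 for v in self.hyperparameter_grid.values()
        ):
            raise ValueError("hyperparameter grid values must be non-empty")


def gaussian_rbf_kernel(theta0: float = 1.0, theta1: float = 1.0, theta2: float = 1.0):
    """Gaussian-process kernel theta0 * exp(-theta1/2 * ||xi - xj||^2) + theta2.

    Mapped onto scikit-learn primitives via RBF length scale l = 1/sqrt(theta1)
    (theta1 = 0 gives an infinite length scale, i.e. a constant kernel
    theta0 + theta2).
    """
    length = np.inf if theta1 == 0 else 1.0 / np.sqrt(theta1)
    return ConstantKernel(theta0) * RBF(length_scale=length) + ConstantKernel(theta2)


_SVR_GRID = {
    "svr__C": [0.1, 1.0, 10.0, 100.0],
    "svr__gamma": [0.01, 0.1, 1.0, "scale"],
    "svr__epsilon": [0.01, 0.1, 1.0],
}


class SuiteEstimator:
    """Wraps an sklearn pipeline behind the fit/predict contract.

    ``fit`` always starts from an unfitted clone, so refitting fully resets
    state and nothing leaks across CV folds. SVR additionally standardises
    the response internally (predictions are returned on the original scale).
    """

    def __init__(self, config: EstimatorConfig):
        self.config = config
        self.name = config.family
        self._base = self._build_base(config)
        self._model = None
        self._y_loc = 0.0
        self._y_scale = 1.0

    @staticmethod
    def _build_base(config: EstimatorConfig):
        steps = []
        if config.autoscale:
            steps.append(("scale", StandardScaler()))
        if config.family == "pls":
            steps.append(("pls", PLSRegression(n_components=2, scale=False)))
        elif config.family == "svr":
            steps.append(("svr", SVR(kernel="rbf")))
        else:
            kernel = gaussian_rbf_kernel(1.0, 1.0, 1.0) + WhiteKernel(1e-2)
            steps.append(
                (
                    "gpr",
                    GaussianProcessRegressor(
                        kernel=kernel,
                        normalize_y=True,
                        n_restarts_optimizer=2,
                        random_state=0,
                    ),
                )
            )
        return Pipeline(steps)

    # -- hyperparameter selection -------------------------------------------------
    def select_hyperparameters(self, X, y) -> None:
        """Pick hyperparameters by inner CV on (X, y) and fix them on the base.

        GPR tunes itself through marginal likelihood at fit time, so this is
        a no-op for that family.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if self.config.family == "gpr":
            return
        n_splits = min(self.config.inner_cv_folds, X.shape[0])
        inner = KFold(n_splits=n_splits, shuffle=True, random_state=0)
        grid = self.config.hyperparameter_grid
        if self.config.family == "pls":
            max_comp = min(X.shape[1], X.shape[0] - X.shape[0] // n_splits - 1, 10)
            max_comp = max(max_comp, 1)
            grid = grid or {"pls__n_components": list(range(1, max_comp + 1))}
        else:
            grid = grid or _SVR_GRID
        search = GridSearchCV(sk_clone(self._base), grid, cv=inner, scoring="r2", n_jobs=1)
        try:
            search.fit(X, self._scaled_y(y, refit_stats=True))
        except Exception as exc:
            raise RuntimeError(f"hyperparameter grid exhausted for family '{self.name}'") from exc
        self._base = sk_clone(self._base).set_params(**search.best_params_)

    def _scaled_y(self, y, refit_stats: bool):
        # SVR has no intrinsic output scaling and its epsilon-tube is on the
        # y scale, so standardise the response around train statistics.
        if self.config.family != "svr":
            return y
        if refit_stats:
            self._y_loc = float(np.mean(y))
            self._y_scale = float(np.std(y)) or 1.0
        return (y - self._y_loc) / self._y_scale

    # -- contract -----------------------------------------------------------------
    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        self._model = sk_clone(self._base)
        self._model.fit(X, self._scaled_y(y, refit_stats=True))
        return self

    def predict(self, X):
        if self._model is None:
            raise RuntimeError("estimator is not fitted")
        pred = np.asarray(self._model.predict(np.asarray(X, dtype=float))).ravel()
        if self.config.family == "svr":
            pred = pred * self._y_scale + self._y_loc
        return pred

    def clone(self) -> "SuiteEstimator":
        """Unfitted copy that keeps any hyperparameters already selected."""
        new = SuiteEstimator(self.config)
        new._base = sk_clone(self._base)
        return new


def build_estimator(config: EstimatorConfig | str) -> SuiteEstimator:
    """Build a ready-to-use estimator from a config or a family name."""
    if isinstance(config, str):
        config = EstimatorConfig(family=config)
    return SuiteEstimator(config)
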