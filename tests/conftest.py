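import numpy as np
import pytest


class MeanRegressor:
    """Predicts the training-set mean of y everywhere."""

    def fit(self, X, y):
        self.mean_ = float(np.mean(y))
        return self

    def predict(self, X):
        return np.full(np.asarray(X).shape[0], self.mean_)


class OneNNRegressor:
    """1-nearest-neighbour on Euclidean distance; ties go to the lowest index."""

    def fit(self, X, y):
        self.X_ = np.asarray(X, dtype=float)
        self.y_ = np.asarray(y, dtype=float)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        d = ((X[:, None, :] - self.X_[None, :, :]) ** 2).sum(axis=2)
        return self.y_[np.argmin(d, axis=1)]


class LeastSquaresRegressor:
    """Plain linear least squares with intercept — a fast deterministic stand-in."""

    def fit(self, X, y):
        A = np.column_stack([np.ones(len(X)), np.asarray(X, dtype=float)])
        self.beta_, *_ = np.linalg.lstsq(A, np.asarray(y, dtype=float), rcond=None)
        return self

    def predict(self, X):
        A = np.column_stack([np.ones(len(X)), np.asarray(X, dtype=float)])
        return A @ self.beta_


@pytest.fixture
def mean_regressor():
    return MeanRegressor()


@pytest.fixture
def one_nn():
    return OneNNRegressor()


@pytest.fixture
def lsq():
    return LeastSquaresRegressor()
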