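"""Chance-correlation gating of pairwise feature correlations.

At small sample sizes the sample correlation between two genuinely independent
features is rarely zero. Using such noise correlations as co-sampling
probabilities would corrupt unrelated features together and distort importance
estimates. The gate keeps an absolute pairwise correlation only when an
interval estimate of the population correlation — built on the Fisher
z-transform, whose sampling distribution is approximately
Normal(z, 1/(m - 3)) — excludes zero; otherwise the entry is set to exactly 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GatedCorrelationMatrix",
    "fisher_z",
    "inverse_fisher",
    "correlation_interval",
    "gate_correlations",
]

# Clamp for perfectly collinear columns: |r| = 1 maps to infinite z, which must
# not crash the gate. The gated entry still reports 1.0.
_CLAMP = 1.0 - 1e-12


def _maybe_scalar(x: np.ndarray, scalar: bool):
    return float(x) if scalar else x


def fisher_z(r):
    """Fisher z-transform, z = (1/2) ln((1 + r)/(1 - r)).

    Accepts scalars or arrays. |r| >= 1 is clamped to ±(1 - 1e-12) so that
    degenerate, perfectly collinear columns yield a large finite z instead of
    an error. NaN input raises.
    """
    r = np.asarray(r, dtype=float)
    scalar = r.ndim == 0
    if np.isnan(r).any():
        raise ValueError("correlation coefficient is NaN")
    r = np.clip(r, -_CLAMP, _CLAMP)
    z = 0.5 * np.log((1.0 + r) / (1.0 - r))
    return _maybe_scalar(z, scalar)


def inverse_fisher(z):
    """Inverse Fisher transform, r = (exp(2z) - 1)/(exp(2z) + 1).

    Evaluated in a sign-symmetric form so large |z| saturates towards ±1
    without overflow; the result is strictly inside (-1, 1).
    """
    z = np.asarray(z, dtype=float)
    scalar = z.ndim == 0
    if not np.isfinite(z).all():
        raise ValueError("z-value must be finite")
    # (e^{2z}-1)/(e^{2z}+1) = (1 - e^{-2|z|})/(1 + e^{-2|z|}) * sign(z)
    t = np.exp(-2.0 * np.abs(z))
    r = np.sign(z) * (1.0 - t) / (1.0 + t)
    lim = np.nextafter(1.0, 0.0)  # keep the output strictly inside (-1, 1)
    r = np.clip(r, -lim, lim)
    return _maybe_scalar(r, scalar)


def correlation_interval(r, m: int, alpha: float):
    """Central interval for the population correlation at coverage ``alpha``.

    On the z-scale the estimator is approximately Normal(fisher_z(r),
    1/(m - 3)); the central interval with probability mass ``alpha`` is mapped
    back through the inverse transform.

    Parameters
    ----------
    r : float or array
        Sample correlation(s).
    m : int
        Sample count used to compute ``r``; must be at least 4.
    alpha : float
        Coverage probability of the central interval, in (0, 1).

    Returns
    -------
    (lower, upper) : pair of floats or arrays on the correlation scale.
    """
    if m <= 3:
        raise ValueError(f"need m >= 4 samples for the interval (got m={m})")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    z = fisher_z(r)
    s = 1.0 / np.sqrt(m - 3)
    c = stats.norm.ppf(0.5 + alpha / 2.0)
    return inverse_fisher(np.asarray(z) - c * s), inverse_fisher(np.asarray(z) + c * s)


@dataclass
class GatedCorrelationMatrix:
    """p x p absolute correlations after chance-correlation gating.

    ``values[i, q]`` is the Bernoulli probability with which feature ``q`` is
    co-corrupted when feature ``i`` is the corruption target. Entries whose
    population-correlation interval straddled zero are exactly 0. The diagonal
    is 1 by convention but is never used as a co-sampling probability (the
    target column is always resampled).
    """

    values: np.ndarray
    alpha: float
    m: int
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("gated correlation matrix must be square")
        if not self.feature_names:
            self.feature_names = [f"x{i + 1}" for i in range(v.shape[0])]
        self.values = v

    @property
    def p(self) -> int:
        return self.values.shape[0]

    def row(self, i: int) -> np.ndarray:
        """Co-sampling probabilities for target feature ``i``."""
        return self.values[i]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_names, columns=self.feature_names
        )

    def to_csv(self, path) -> None:
        """Write the gated matrix with feature names as row/column headers."""
        self.to_dataframe().to_csv(path)


def gate_correlations(X, alpha: float = 0.999, feature_names=None) -> GatedCorrelationMatrix:
    """Gate the absolute pairwise Pearson correlations of the columns of X.

    An off-diagonal entry (i, q) is |pearson(X[:, i], X[:, q])| when the
    ``alpha``-coverage interval around that absolute correlation excludes 0,
    and exactly 0 otherwise. Constant columns carry no co-movement
    information: their entries are set to 0 and a warning is emitted.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D feature matrix")
    m, p = X.shape
    if m < 4:
        raise ValueError(f"need at least 4 samples to gate correlations (got {m})")
    if p < 1:
        raise ValueError("need at least one feature")

    constant = X.std(axis=0) == 0.0
    if constant.any():
        which = [i for i in range(p) if constant[i]]
        warnings.warn(
            f"constant column(s) {which}: gated correlations set to 0",
            stacklevel=2,
        )

    if p == 1:
        corr = np.ones((1, 1))
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # 0/0 on constants
            corr = np.corrcoef(X, rowvar=False)
    absr = np.abs(np.nan_to_num(corr, nan=0.0))

    lower, upper = correlation_interval(absr, m, alpha)
    gated = np.where((lower < 0.0) & (0.0 < upper), 0.0, absr)
    gated[constant, :] = 0.0
    gated[:, constant] = 0.0
    gated = (gated + gated.T) / 2.0  # enforce exact symmetry
    np.fill_diagonal(gated, 1.0)
    return GatedCorrelationMatrix(
        values=gated, alpha=alpha, m=m,
        feature_names=list(feature_names) if feature_names is not None else [],
    )
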