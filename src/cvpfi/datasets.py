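"""Synthetic case-study generators.

Four seeded designs, each probing one failure mode of permutation
importance:

1. small-n linear — 20 samples, 15 uniform features, the first 10 carry unit
   weights, the last 5 none;
2. mixed linear/nonlinear — 60 samples, 15 features; features 1-5 enter
   through a fixed nonlinear response surface, 6-10 linearly with unit
   weight, 11-15 not at all;
3. correlated block — 100 samples, 10 features; 5 independent (uniform plus
   N(0, 0.1^2) jitter) and 5 sharing one uniform latent u per sample,
   x = u + 0.1 N(0,1), giving within-block population correlation
   (1/12)/(1/12 + 0.01) ~ 0.893; all columns standardised, unit weights;
4. quantised — 100 samples, 5 continuous uniform features and 5 binary
   indicators with a 10% rate of ones; standardised, unit weights.

Response noise in every case is Gaussian with standard deviation equal to
``noise_fraction`` (default 0.1) times the standard deviation of the
noiseless response. Generators are pure functions of the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CaseStudySpec",
    "case2_response_surface",
    "generate_case1",
    "generate_case2",
    "generate_case3",
    "generate_case4",
    "generate_case",
    "case_to_dataframe",
    "write_case_csv",
]


@dataclass
class CaseStudySpec:
    case_id: int
    m: int
    p: int
    relevant_count: int
    noise_fraction: float
    seed: int
    ground_truth: list[str]


def _add_noise(rng: np.random.Generator, y_clean: np.ndarray, noise_fraction: float):
    if noise_fraction == 0.0:
        return y_clean.copy()
    sd = noise_fraction * np.std(y_clean)
    return y_clean + rng.normal(0.0, sd, size=y_clean.shape)


def _standardise(X: np.ndarray) -> np.ndarray:
    # population (divide-by-n) standard deviation
    return (X - X.mean(axis=0)) / X.std(axis=0)


def generate_case1(seed: int, noise_fraction: float = 0.1):
    """Small-sample linear design: 20 x 15 uniform, first 10 features weighted 1."""
    rng = np.random.default_rng(seed)
    X = rng.uniform(0.0, 1.0, size=(20, 15))
    y_clean = X[:, :10].sum(axis=1)
    y = _add_noise(rng, y_clean, noise_fraction)
    roles = ["relevant-linear"] * 10 + ["irrelevant"] * 5
    return X, y, roles


def case2_response_surface(X: np.ndarray) -> np.ndarray:
    """Nonlinear part of the case-2 response, evaluated on features 1-5.

    3(x1 - 1.5)^2 + 2(x2 - 1)^3 + exp(x3 - 0.5) + 2 ln(x4 + 1) + 1.5 sin(x5)
    """
    x1, x2, x3, x4, x5 = (X[:, k] for k in range(5))
    return (
        3.0 * (x1 - 1.5) ** 2
        + 2.0 * (x2 - 1.0) ** 3
        + np.exp(x3 - 0.5)
        + 2.0 * np.log(x4 + 1.0)
        + 1.5 * np.sin(x5)
    )


def generate_case2(seed: int, noise_fraction: float = 0.1):
    """Mixed design: 60 x 15 uniform; nonlinear features 1-5, linear 6-10."""
    rng = np.random.default_rng(seed)
    X = rng.uniform(0.0, 1.0, size=(60, 15))
    y_clean = case2_response_surface(X) + X[:, 5:10].sum(axis=1)
    y = _add_noise(rng, y_clean, noise_fraction)
    roles = ["relevant-nonlinear"] * 5 + ["relevant-linear"] * 5 + ["irrelevant"] * 5
    return X, y, roles


def generate_case3(seed: int, noise_fraction: float = 0.1):
    """Correlated-block design: 5 independent + 5 shared-latent features, m=100."""
    rng = np.random.default_rng(seed)
    m = 100
    indep = rng.uniform(0.0, 1.0, size=(m, 5)) + rng.normal(0.0, 0.1, size=(m, 5))
    u = rng.uniform(0.0, 1.0, size=m)
    block = u[:, None] + rng.normal(0.0, 0.1, size=(m, 5))
    X = _standardise(np.hstack([indep, block]))
    y_clean = X.sum(axis=1)
    y = _add_noise(rng, y_clean, noise_fraction)
    roles = ["relevant-linear"] * 5 + ["correlated-block"] * 5
    return X, y, roles


def generate_case4(seed: int, noise_fraction: float = 0.1):
    """Quantised design: 5 continuous + 5 biased binary (10% ones), m=100."""
    rng = np.random.default_rng(seed)
    m = 100
    cont = rng.uniform(0.0, 1.0, size=(m, 5))
    binary = (rng.random(size=(m, 5)) < 0.1).astype(float)
    # a degenerate all-0 / all-1 column would make standardisation undefined
    for k in range(5):
        while binary[:, k].min() == binary[:, k].max():
            binary[:, k] = (rng.random(size=m) < 0.1).astype(float)
    X = _standardise(np.hstack([cont, binary]))
    y_clean = X.sum(axis=1)
    y = _add_noise(rng, y_clean, noise_fraction)
    roles = ["relevant-linear"] * 5 + ["quantised"] * 5
    return X, y, roles


_GENERATORS = {1: generate_case1, 2: generate_case2, 3: generate_case3, 4: generate_case4}


def generate_case(case_id: int, seed: int, noise_fraction: float = 0.1):
    """Dispatch to one of the four case-study generators."""
    try:
        gen = _GENERATORS[int(case_id)]
    except (KeyError, ValueError):
        raise ValueError(f"case_id must be 1..4, got {case_id}") from None
    return gen(seed, noise_fraction)


def case_spec(case_id: int, seed: int, noise_fraction: float = 0.1) -> CaseStudySpec:
    X, _, roles = generate_case(case_id, seed, noise_fraction)
    relevant = sum(r.startswith("relevant") or r in ("correlated-block", "quantised")
                   for r in roles)
    return CaseStudySpec(
        case_id=int(case_id),
        m=X.shape[0],
        p=X.shape[1],
        relevant_count=relevant,
        noise_fraction=noise_fraction,
        seed=int(seed),
        ground_truth=roles,
    )


def case_to_dataframe(case_id: int, seed: int, noise_fraction: float = 0.1) -> pd.DataFrame:
    X, y, _ = generate_case(case_id, seed, noise_fraction)
    frame = pd.DataFrame(X, columns=[f"x{i + 1}" for i in range(X.shape[1])])
    frame["y"] = y
    return frame


def write_case_csv(case_id: int, seed: int, path, noise_fraction: float = 0.1) -> None:
    """Write the dataset as CSV plus a JSON sidecar describing the design."""
    path = str(path)
    case_to_dataframe(case_id, seed, noise_fraction).to_csv(path, index=False)
    sidecar = path[:-4] + ".json" if path.endswith(".csv") else path + ".json"
    with open(sidecar, "w") as fh:
        json.dump(asdict(case_spec(case_id, seed, noise_fraction)), fh, indent=2)
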