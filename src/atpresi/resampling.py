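"""Class balancing for the training set: SMOTE oversampling and random
undersampling (RUS).

SMOTE synthesises minority-class (binding) feature vectors by linear
interpolation: for a minority sample ``x_old`` and one of its k nearest
minority neighbours ``x'`` (Euclidean distance), a synthetic point is
``x_new = x_old + lambda * (x' - x_old)`` with ``lambda ~ U[0, 1)``.
Parents are cycled round-robin in input order so the oversampling load is
spread as evenly as possible; neighbour ties are broken by ascending sample
index, so resampling is fully deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator

__all__ = [
    "ResampleConfig",
    "SyntheticSample",
    "smote_balance",
    "rus_balance",
    "SMOTESampler",
]


@dataclass
class ResampleConfig:
    """How the training portion of a fold is balanced before fitting."""

    method: str = "smote"  # none | smote | rus
    k_neighbors: int = 5
    rus_repeats: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("none", "smote", "rus"):
            raise ValueError(f"unknown resampling method {self.method!r}")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.rus_repeats < 1:
            raise ValueError("rus_repeats must be >= 1")


@dataclass
class SyntheticSample:
    """One SMOTE-interpolated minority sample with its provenance."""

    values: np.ndarray
    parent_index: int
    neighbor_index: int
    lam: float


def _knn_indices(minority: np.ndarray, k: int) -> np.ndarray:
    """Indices of each point's k nearest minority neighbours (self excluded).

    Brute-force all-pairs distances; ties broken by ascending index via a
    stable argsort on (distance, index).
    """
    d = cdist(minority, minority)
    np.fill_diagonal(d, np.inf)
    order = np.argsort(d, axis=1, kind="stable")
    return order[:, :k]


def smote_balance(
    minority: np.ndarray, majority_count: int, k: int = 5, seed: int = 0
) -> list[SyntheticSample]:
    """Generate ``majority_count - len(minority)`` synthetic minority samples.

    Each synthetic sample lies on the segment between its parent and one of
    the parent's k nearest minority neighbours.  Deterministic per seed.
    """
    minority = np.asarray(minority, dtype=float)
    n_min = len(minority)
    if majority_count <= n_min:
        raise ValueError("majority_count must exceed the minority size")
    if n_min < k + 1:
        raise ValueError(
            f"minority size {n_min} too small for k={k}; use k <= {n_min - 1}"
        )
    n_new = majority_count - n_min
    nn = _knn_indices(minority, k)
    rng = np.random.default_rng(seed)
    parents = np.arange(n_new) % n_min  # round-robin over input order
    neighbor_choice = rng.integers(0, k, size=n_new)
    lams = rng.random(n_new)
    out = []
    for parent, which, lam in zip(parents, neighbor_choice, lams):
        neighbor = int(nn[parent, which])
        values = minority[parent] + lam * (minority[neighbor] - minority[parent])
        out.append(SyntheticSample(values, int(parent), neighbor, float(lam)))
    return out


def rus_balance(majority_indices, minority_count: int, seed: int = 0) -> np.ndarray:
    """Uniform sample of majority indices without replacement, minority-sized."""
    majority_indices = np.asarray(majority_indices)
    if minority_count > len(majority_indices):
        raise ValueError(
            f"cannot undersample {len(majority_indices)} majority samples "
            f"down to {minority_count}"
        )
    rng = np.random.default_rng(seed)
    return rng.choice(majority_indices, size=minority_count, replace=False)


class SMOTESampler(BaseEstimator):
    """SMOTE resampler with a ``fit_resample(X, y)`` interface.

    After resampling the two classes have exactly equal counts; synthetic
    rows are appended after the originals and described in ``synthetic_``.
    """

    def __init__(self, k_neighbors: int = 5, random_state: int = 0):
        self.k_neighbors = k_neighbors
        self.random_state = random_state

    def fit_resample(self, X: np.ndarray, y: np.ndarray):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) != 2:
            raise ValueError("SMOTE requires exactly two classes")
        minority_class = classes[np.argmin(counts)]
        majority_count = int(counts.max())
        min_mask = y == minority_class
        minority = X[min_mask]
        if len(minority) == majority_count:
            self.synthetic_ = []
            return X, y
        synth = smote_balance(
            minority, majority_count, k=self.k_neighbors, seed=self.random_state
        )
        self.synthetic_ = synth
        X_new = np.vstack([X] + [s.values[None, :] for s in synth])
        y_new = np.concatenate([y, np.full(len(synth), minority_class, dtype=y.dtype)])
        return X_new, y_new
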