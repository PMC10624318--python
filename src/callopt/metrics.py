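"""Normalisation, data partitioning and evaluation metrics.

Inputs are min-max normalised to [0, 1] so the four hormones get equal
weight in distance-based models; outputs stay on their natural scales
(percent, grams).  Model quality is scored with the coefficient of
determination (R^2), root mean squared error (RMSE) and mean bias error
(MBE, predicted minus observed — positive means overestimation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import KFold


@dataclass
class MinMaxScaler:
    """Per-feature min-max normalisation fitted on training data.

    Constant features are mapped to 0 (with a warning at fit time) rather
    than dividing by zero; inverting is exact for non-constant features.
    """

    minimum: np.ndarray
    maximum: np.ndarray

    @property
    def scale(self) -> np.ndarray:
        span = self.maximum - self.minimum
        return np.where(span == 0, 1.0, span)

    def apply(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.minimum.shape[0]:
            raise ValueError(
                f"expected {self.minimum.shape[0]} features, got {X.shape[1]}"
            )
        return (X - self.minimum) / self.scale

    def invert(self, X_norm: np.ndarray) -> np.ndarray:
        X_norm = np.atleast_2d(np.asarray(X_norm, dtype=float))
        if X_norm.shape[1] != self.minimum.shape[0]:
            raise ValueError(
                f"expected {self.minimum.shape[0]} features, got {X_norm.shape[1]}"
            )
        return X_norm * self.scale + self.minimum


def fit_minmax(X: np.ndarray) -> MinMaxScaler:
    """Fit a min-max scaler on the rows of ``X``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    mn, mx = X.min(axis=0), X.max(axis=0)
    if np.any(mn == mx):
        const = np.flatnonzero(mn == mx)
        warnings.warn(
            f"feature(s) {const.tolist()} are constant and will normalise to 0",
            stacklevel=2,
        )
    return MinMaxScaler(minimum=mn, maximum=mx)


@dataclass
class SplitIndices:
    """A train/test partition of ``0..n-1``."""

    train: np.ndarray
    test: np.ndarray
    seed: int
    ratio: float


def split_train_test(n: int, ratio: float = 0.8, seed: int = 0) -> SplitIndices:
    """Random permutation then prefix split; |train| = floor(ratio * n)."""
    if n < 5:
        raise ValueError(f"need at least 5 records to split, got {n}")
    if not 0 < ratio < 1:
        raise ValueError(f"ratio must be in (0, 1), got {ratio}")
    perm = np.random.default_rng(seed).permutation(n)
    cut = int(np.floor(ratio * n))
    return SplitIndices(train=perm[:cut], test=perm[cut:], seed=seed, ratio=ratio)


def split_by_group(groups, ratio: float = 0.8, seed: int = 0) -> SplitIndices:
    """Train/test split keeping all records of a group on the same side.

    Used to split replicate vessels at the treatment level so near-identical
    replicates never straddle the partition.  Groups are permuted and a
    floor(ratio * n_groups) prefix forms the training side.
    """
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    gsplit = split_train_test(len(uniq), ratio=ratio, seed=seed)
    train_groups = set(uniq[gsplit.train].tolist())
    idx = np.arange(len(groups))
    in_train = np.array([g in train_groups for g in groups])
    return SplitIndices(train=idx[in_train], test=idx[~in_train], seed=seed, ratio=ratio)


def kfold_indices(n: int, k: int = 5, seed: int = 0) -> list[SplitIndices]:
    """Shuffled k-fold partition; fold sizes differ by at most one."""
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [
        SplitIndices(train=tr, test=te, seed=seed, ratio=1 - 1 / k)
        for tr, te in kf.split(np.arange(n))
    ]


def _check_pair(y_obs, y_pred):
    y_obs = np.asarray(y_obs, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_obs.shape != y_pred.shape:
        raise ValueError("y_obs and y_pred must have the same length")
    if y_obs.size < 2:
        raise ValueError("need at least 2 observations")
    return y_obs, y_pred


def r_squared(y_obs, y_pred) -> float:
    """R^2 = 1 - SS_res / SS_tot. Undefined (error) for constant y_obs."""
    y_obs, y_pred = _check_pair(y_obs, y_pred)
    ss_tot = np.sum((y_obs - y_obs.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("R^2 undefined: observed values are constant")
    return float(1.0 - np.sum((y_obs - y_pred) ** 2) / ss_tot)


def rmse(y_obs, y_pred) -> float:
    y_obs, y_pred = _check_pair(y_obs, y_pred)
    return float(np.sqrt(np.mean((y_pred - y_obs) ** 2)))


def mbe(y_obs, y_pred) -> float:
    """Mean bias error, mean(predicted - observed)."""
    y_obs, y_pred = _check_pair(y_obs, y_pred)
    return float(np.mean(y_pred - y_obs))


@dataclass
class MetricsReport:
    """R^2 / RMSE / MBE for one model, output and partition."""

    model: str
    output: str
    partition: str
    r2: float
    rmse: float
    mbe: float
    n: int

    def as_dict(self) -> dict:
        return {
            "model": self.model,
            "output": self.output,
            "partition": self.partition,
            "r2": self.r2,
            "rmse": self.rmse,
            "mbe": self.mbe,
            "n": self.n,
        }


def score(model_name, output, partition, y_obs, y_pred) -> MetricsReport:
    """Bundle the three metrics for one prediction set."""
    return MetricsReport(
        model=model_name,
        output=output,
        partition=partition,
        r2=r_squared(y_obs, y_pred),
        rmse=rmse(y_obs, y_pred),
        mbe=mbe(y_obs, y_pred),
        n=len(np.asarray(y_obs).ravel()),
    )
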