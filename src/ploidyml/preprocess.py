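"""Dataset container, hygiene and partitioning.

The experimental unit is one explant, described by two features —
oryzalin concentration (µM) and exposure time (h) — and a ploidy class
label.  This module provides the labeled-dataset container used across
the package, a PCA/Mahalanobis outlier screen, feature standardization
fitted on training data only, a stratified train/test split, and CSV
round-trip I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .errors import DataError, DomainError

#: Fixed class ordering used everywhere: tie-breaks, confusion-matrix axes,
#: posterior vectors.
CLASSES: tuple[str, str, str] = ("diploid", "mixoploid", "tetraploid")

#: Exact CSV header for dataset files.
CSV_COLUMNS = ("concentration_uM", "exposure_h", "ploidy")


@dataclass(frozen=True)
class PloidyDataset:
    """Labeled feature table: n × 2 features plus ploidy class labels.

    Features are kept in original units (µM, h) unless a standardizer has
    been applied explicitly.
    """

    X: np.ndarray
    y: np.ndarray
    classes: tuple[str, ...] = CLASSES

    def __post_init__(self):
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=object)
        if X.ndim != 2 or X.shape[1] != 2:
            raise DataError(f"feature matrix must be (n, 2); got {X.shape}")
        if len(y) != len(X):
            raise DataError("feature/label length mismatch")
        if np.any(~np.isfinite(X)):
            raise DataError("features contain non-finite values")
        unknown = set(y) - set(self.classes)
        if unknown:
            raise DataError(f"unknown class labels: {sorted(unknown)}")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", np.asarray([str(v) for v in y], dtype=object))

    @property
    def n(self) -> int:
        return len(self.y)

    def class_counts(self) -> dict[str, int]:
        return {c: int(np.sum(self.y == c)) for c in self.classes}

    def class_indices(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.y == label)

    def subset(self, indices) -> "PloidyDataset":
        idx = np.asarray(indices, dtype=int)
        return PloidyDataset(self.X[idx], self.y[idx], self.classes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                CSV_COLUMNS[0]: self.X[:, 0],
                CSV_COLUMNS[1]: self.X[:, 1],
                CSV_COLUMNS[2]: self.y,
            }
        )

    def __eq__(self, other) -> bool:  # value equality, used by round-trip tests
        if not isinstance(other, PloidyDataset):
            return NotImplemented
        return (
            self.classes == other.classes
            and self.X.shape == other.X.shape
            and bool(np.array_equal(self.X, other.X))
            and bool(np.array_equal(self.y, other.y))
        )


@dataclass(frozen=True)
class StandardizationParams:
    """Per-feature location/scale in original units (z = (x - mean) / std)."""

    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self):
        mean = np.asarray(self.mean, dtype=float)
        std = np.asarray(self.std, dtype=float)
        if np.any(std <= 0):
            raise DomainError("standard deviations must be > 0")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "std", std)


@dataclass(frozen=True)
class SplitDataset:
    """Stratified train/test partition plus the index bookkeeping."""

    train: PloidyDataset
    test: PloidyDataset
    train_indices: np.ndarray = field(repr=False)
    test_indices: np.ndarray = field(repr=False)
    seed: int = 0

    def per_class_counts(self) -> dict[str, dict[str, int]]:
        return {"train": self.train.class_counts(), "test": self.test.class_counts()}


def pca_outlier_filter(
    d: PloidyDataset, alpha: float = 0.025
) -> tuple[PloidyDataset, list[int]]:
    """Remove multivariate outliers by squared Mahalanobis distance in PC space.

    Features are standardized, projected on principal components, and a row
    is flagged when its squared Mahalanobis distance exceeds the chi-square
    quantile at 1 - alpha with df = number of features (2).  Because the
    Mahalanobis distance is invariant under the PCA rotation this equals the
    Mahalanobis distance of the standardized data itself; the PC route is
    kept explicit.
    """
    if d.n < 3:
        raise DataError("outlier filter needs at least 3 rows")
    if not 0 < alpha < 1:
        # alpha -> 0 means cutoff -> inf: allow alpha == 0 as "remove nothing"
        if alpha == 0:
            return d, []
        raise DomainError("alpha must be in [0, 1)")
    std = d.X.std(axis=0, ddof=0)
    if np.any(std == 0):
        raise DataError("zero-variance feature: covariance is degenerate")
    z = (d.X - d.X.mean(axis=0)) / std
    cov = np.cov(z, rowvar=False, ddof=1)
    eigval, eigvec = np.linalg.eigh(cov)
    if np.any(eigval <= 1e-12):
        raise DataError("degenerate covariance: zero principal-component variance")
    scores = z @ eigvec
    d2 = np.sum(scores**2 / eigval, axis=1)
    cutoff = chi2.ppf(1.0 - alpha, df=d.X.shape[1])
    removed = np.flatnonzero(d2 > cutoff)
    keep = np.flatnonzero(d2 <= cutoff)
    return d.subset(keep), [int(i) for i in removed]


def fit_standardizer(train: PloidyDataset) -> StandardizationParams:
    """Fit per-feature mean/std (population convention) on training data only."""
    if train.n == 0:
        raise DataError("cannot fit standardizer on an empty dataset")
    mean = train.X.mean(axis=0)
    std = train.X.std(axis=0, ddof=0)
    if np.any(std == 0):
        raise DataError("zero-variance feature: cannot standardize")
    return StandardizationParams(mean=mean, std=std)


def apply_standardizer(params: StandardizationParams, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return (X - params.mean) / params.std


def invert_standardizer(params: StandardizationParams, Z: np.ndarray) -> np.ndarray:
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    return Z * params.std + params.mean


def stratified_split(
    d: PloidyDataset, train_per_class: int = 19, seed: int = 0
) -> SplitDataset:
    """Seeded stratified split with an exact per-class training count.

    The default 19 per class turns the 72-row balanced dataset into 57
    training and 15 testing rows, the denominators behind every reported
    accuracy (each an exact multiple of 1/57 or 1/15); the often-quoted
    70/30 proportion is approximate.
    """
    if train_per_class < 0:
        raise DomainError("train_per_class must be >= 0")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for c in d.classes:
        idx = d.class_indices(c)
        if len(idx) < train_per_class:
            raise DataError(
                f"class {c!r} has {len(idx)} rows; needs >= {train_per_class}"
            )
        perm = rng.permutation(idx)
        train_idx.extend(int(i) for i in np.sort(perm[:train_per_class]))
        test_idx.extend(int(i) for i in np.sort(perm[train_per_class:]))
    train_idx_a = np.asarray(train_idx, dtype=int)
    test_idx_a = np.asarray(test_idx, dtype=int)
    return SplitDataset(
        train=d.subset(train_idx_a),
        test=d.subset(test_idx_a),
        train_indices=train_idx_a,
        test_indices=test_idx_a,
        seed=int(seed),
    )


def read_dataset(path) -> PloidyDataset:
    """Read a dataset CSV (header ``concentration_uM,exposure_h,ploidy``)."""
    try:
        df = pd.read_csv(path, dtype={"ploidy": str})
    except pd.errors.EmptyDataError as exc:
        raise DataError(f"{path}: empty file") from exc
    if list(df.columns) != list(CSV_COLUMNS):
        raise DataError(
            f"{path}: expected columns {list(CSV_COLUMNS)}, got {list(df.columns)}"
        )
    for col in CSV_COLUMNS[:2]:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(vals.isna().to_numpy())
        if len(bad):
            raise DataError(f"{path}: non-numeric {col!r} at data row {bad[0] + 1}")
        df[col] = vals
    labels = df["ploidy"].astype(str).str.strip()
    bad = np.flatnonzero(~labels.isin(CLASSES).to_numpy())
    if len(bad):
        raise DataError(
            f"{path}: unknown ploidy {labels.iloc[bad[0]]!r} at data row {bad[0] + 1}"
        )
    return PloidyDataset(df[list(CSV_COLUMNS[:2])].to_numpy(float), labels.to_numpy())


def write_dataset(d: PloidyDataset, path) -> None:
    """Write a dataset CSV losslessly (full float repr precision)."""
    d.to_frame().to_csv(path, index=False)
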