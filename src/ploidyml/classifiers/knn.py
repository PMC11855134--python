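"""k-nearest-neighbors classification under cosine distance.

Cosine distance 1 - (u.v)/(||u|| ||v||) compares feature *directions*, so
it is undefined at the origin and direction-degenerate around it.  After
standardization a point near the feature means lands near the origin;
``prepare_knn_features`` therefore shifts standardized features by a fixed
positive offset (default +3 per coordinate, beyond the z-range the designs
here produce), keeping every vector in the positive orthant.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from ..errors import DataError, DomainError
from ..preprocess import CLASSES, PloidyDataset

#: Offset added to standardized coordinates before cosine comparisons.
KNN_FEATURE_OFFSET = 3.0


@dataclass(frozen=True)
class KNNModel:
    X: np.ndarray
    y: np.ndarray
    k: int
    classes: tuple[str, ...] = CLASSES

    def __post_init__(self):
        if not 1 <= self.k <= len(self.X):
            raise DomainError(f"k={self.k} outside [1, n_train={len(self.X)}]")


def cosine_distance(u, v) -> float:
    """1 - cos(u, v), in [0, 2]; zero-norm inputs are a domain error."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise DomainError("cosine distance undefined for zero-norm vectors")
    return float(1.0 - np.dot(u, v) / (nu * nv))


def prepare_knn_features(Z: np.ndarray, offset: float = KNN_FEATURE_OFFSET) -> np.ndarray:
    """Shift standardized features into the positive orthant."""
    return np.asarray(Z, dtype=float) + offset


def knn_fit(train: PloidyDataset, k: int) -> KNNModel:
    if train.n == 0:
        raise DataError("cannot fit KNN on an empty dataset")
    return KNNModel(X=train.X.copy(), y=train.y.copy(), k=int(k),
                    classes=train.classes)


def _cosine_distances(X: np.ndarray, q: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(X, axis=1)
    nq = np.linalg.norm(q)
    if nq == 0 or np.any(norms == 0):
        raise DomainError("cosine distance undefined for zero-norm vectors")
    return 1.0 - (X @ q) / (norms * nq)


def _vote(m: KNNModel, order: np.ndarray) -> str:
    top = order[: m.k]
    counts = Counter(m.y[top])
    best = max(counts.values())
    tied = [c for c in m.classes if counts.get(c, 0) == best]
    if len(tied) == 1:
        return tied[0]
    # vote tie: the class of the single nearest neighbor
    return str(m.y[order[0]])


def knn_predict(m: KNNModel, x) -> str | np.ndarray:
    """Majority class among the k cosine-nearest stored patterns.

    Distance ties at the k-th rank resolve by stable training-set order;
    vote ties resolve to the class of the single nearest neighbor.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        order = np.argsort(_cosine_distances(m.X, x), kind="stable")
        return _vote(m, order)
    return np.asarray([knn_predict(m, row) for row in x], dtype=object)


def loo_accuracy_knn(train: PloidyDataset, k: int) -> float:
    """Leave-one-out training accuracy for a given k."""
    n = train.n
    if not 1 <= k <= n - 1:
        raise DomainError(f"k={k} outside [1, n_train-1={n - 1}]")
    correct = 0
    for i in range(n):
        keep = np.arange(n) != i
        m = KNNModel(X=train.X[keep], y=train.y[keep], k=k, classes=train.classes)
        if knn_predict(m, train.X[i]) == train.y[i]:
            correct += 1
    return correct / n


DEFAULT_K_GRID = (1, 3, 5, 7, 9)


def select_k(train: PloidyDataset, candidates=DEFAULT_K_GRID) -> int:
    """Candidate k maximizing LOO accuracy; ties break toward smaller k."""
    candidates = sorted(int(k) for k in candidates)
    if not candidates:
        raise DomainError("candidate k list must be nonempty")
    if candidates[0] < 1 or candidates[-1] > train.n - 1:
        raise DomainError("candidates must lie in [1, n_train - 1]")
    best_k, best_acc = candidates[0], -1.0
    for k in candidates:
        acc = loo_accuracy_knn(train, k)
        if acc > best_acc:  # strict > with ascending grid -> smaller k wins ties
            best_k, best_acc = k, acc
    return best_k
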