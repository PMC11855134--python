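"""Probabilistic neural network (Parzen-window kernel classifier).

Four conceptual layers: the input layer takes the 2-feature vector; the
pattern layer evaluates a Gaussian kernel exp(-||x - xi||^2 / (2 sigma^2))
against every stored training pattern; the summation layer adds pattern
activations per class, Sj = sum_{i in class j} f(x, xi); the output layer
normalizes to posteriors P(Cj | x) = Sj / sum_k Sk.

The per-class sums are deliberately unweighted (no 1/Nj factor, no
priors): with the balanced class design used throughout, the argmax is
identical to the classic Nj-normalized formulation.  All internal kernel
arithmetic runs in log space so that vanishingly small sigmas (the 1-NN
limit) stay numerically exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import logsumexp

from ..errors import DataError, DomainError
from ..preprocess import CLASSES, PloidyDataset


@dataclass(frozen=True)
class PNNModel:
    """Stored training patterns, their labels and the smoothing parameter."""

    X: np.ndarray
    y: np.ndarray
    sigma: float
    classes: tuple[str, ...] = CLASSES

    def __post_init__(self):
        if self.sigma <= 0:
            raise DomainError("sigma must be > 0")

    @property
    def class_counts(self) -> dict[str, int]:
        return {c: int(np.sum(self.y == c)) for c in self.classes}


def pnn_kernel(x, xi, sigma: float) -> float:
    """Pattern-layer activation exp(-||x - xi||^2 / (2 sigma^2)) in (0, 1]."""
    if sigma <= 0:
        raise DomainError("sigma must be > 0")
    x = np.asarray(x, dtype=float)
    xi = np.asarray(xi, dtype=float)
    if x.shape != xi.shape:
        raise DomainError(f"dimension mismatch: {x.shape} vs {xi.shape}")
    d2 = float(np.sum((x - xi) ** 2))
    return float(np.exp(-d2 / (2.0 * sigma**2)))


def pnn_fit(train: PloidyDataset, sigma: float) -> PNNModel:
    """Store the training set; every class must be represented."""
    if sigma <= 0:
        raise DomainError("sigma must be > 0")
    counts = train.class_counts()
    empty = [c for c, n in counts.items() if n == 0]
    if empty:
        raise DataError(f"cannot fit PNN: empty class(es) {empty}")
    return PNNModel(X=train.X.copy(), y=train.y.copy(), sigma=float(sigma),
                    classes=train.classes)


def _log_class_sums(m: PNNModel, X: np.ndarray) -> np.ndarray:
    """log Sj for each query row; shape (n_query, n_classes)."""
    logk = -cdist(X, m.X, "sqeuclidean") / (2.0 * m.sigma**2)
    out = np.empty((len(X), len(m.classes)))
    for j, c in enumerate(m.classes):
        out[:, j] = logsumexp(logk[:, m.y == c], axis=1)
    return out

def pnn_posterior(m: PNNModel, x) -> np.ndarray:
    """Posterior vector(s) over classes; rows sum to 1.

    Accepts a single feature vector (returns shape (n_classes,)) or a
     2-D batch (returns (n, n_classes)).
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    logs = _log_class_sums(m, np.atleast_2d(x))
    logs -= logsumexp(logs, axis=1, keepdims=True)
    post = np.exp(logs)
    post /= post.sum(axis=1, keepdims=True)
    return post[0] if single else post


def pnn_predict(m: PNNModel, x) -> str | np.ndarray:
    """Argmax-posterior class; ties go to the smallest class index."""
    post = np.atleast_2d(pnn_posterior(m, x))
    labels = np.asarray([m.classes[j] for j in np.argmax(post, axis=1)], dtype=object)
    return labels[0] if np.asarray(x).ndim == 1 else labels


def loo_accuracy_pnn(train: PloidyDataset, sigma: float) -> float:
    """Leave-one-out training accuracy for a given sigma."""
    if sigma <= 0:
        raise DomainError("sigma must be > 0")
    n = train.n
    logk = -cdist(train.X, train.X, "sqeuclidean") / (2.0 * sigma**2)
    np.fill_diagonal(logk, -np.inf)  # exclude the held-out point itself
    correct = 0
    logs = np.empty((n, len(train.classes)))
    for j, c in enumerate(train.classes):
        cols = train.y == c
        logs[:, j] = logsumexp(logk[:, cols], axis=1)
    pred = np.argmax(logs, axis=1)
    truth = np.array([list(train.classes).index(c) for c in train.y])
    correct = int(np.sum(pred == truth))
    return correct / n


DEFAULT_SIGMA_GRID = tuple(np.geomspace(0.05, 2.0, 25))


def select_sigma(train: PloidyDataset, grid=DEFAULT_SIGMA_GRID) -> float:
    """Grid sigma maximizing LOO accuracy; ties break toward larger sigma."""
    grid = sorted(float(s) for s in grid)
    if not grid:
        raise DomainError("sigma grid must be nonempty")
    if any(s <= 0 for s in grid):
        raise DomainError("sigma grid values must be > 0")
    best_sigma, best_acc = grid[0], -1.0
    for s in grid:
        acc = loo_accuracy_pnn(train, s)
        if acc >= best_acc:  # >= with ascending grid -> larger sigma wins ties
            best_sigma, best_acc = s, acc
    return best_sigma
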