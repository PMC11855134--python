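"""Soft-margin RBF support-vector classification, trained by SMO.

Each binary subproblem maximizes the standard dual

    W(a) = sum_i a_i - 1/2 sum_ij a_i a_j y_i y_j K(x_i, x_j)
    s.t.  0 <= a_i <= C,  sum_i a_i y_i = 0

with K(x_i, x) = exp(-gamma ||x - x_i||^2), using Platt's sequential
minimal optimization (pairwise coordinate ascent that preserves the
equality constraint exactly).  Multiclass decisions use one-vs-one
decomposition with majority voting; vote ties break by the largest summed
absolute decision value, then by the fixed class order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from ..errors import ConvergenceError, DataError, DomainError
from ..preprocess import CLASSES, PloidyDataset

KKT_TOL = 1e-3
_EPS = 1e-12


def rbf_kernel(X1: np.ndarray, X2: np.ndarray, gamma: float) -> np.ndarray:
    return np.exp(-gamma * cdist(np.atleast_2d(X1), np.atleast_2d(X2), "sqeuclidean"))


@dataclass(frozen=True)
class BinarySVC:
    """One fitted one-vs-one subproblem (positive class listed first)."""

    classes: tuple[str, str]
    X: np.ndarray
    y: np.ndarray  # signed labels in {-1, +1}; +1 <=> classes[0]
    alpha: np.ndarray
    b: float
    gamma: float
    C: float

    @property
    def n_support(self) -> int:
        return int(np.sum(self.alpha > _EPS))

    def decision(self, X: np.ndarray) -> np.ndarray:
        K = rbf_kernel(np.atleast_2d(X), self.X, self.gamma)
        return K @ (self.alpha * self.y) + self.b


@dataclass(frozen=True)
class SVCModel:
    subproblems: tuple[BinarySVC, ...]
    C: float
    gamma: float
    classes: tuple[str, ...] = CLASSES

    @property
    def n_support(self) -> int:
        return sum(p.n_support for p in self.subproblems)


def _smo_solve(K, y, C, tol=KKT_TOL, max_sweeps=10_000, rng_seed=0):
    """Platt-style SMO on a precomputed kernel matrix.

    Returns (alpha, b).  Raises ConvergenceError if the KKT conditions are
    not met within the sweep cap.
    """
    n = len(y)
    alpha = np.zeros(n)
    b = 0.0
    # E[i] = f(x_i) - y_i; with alpha = 0 this is just -y
    E = -y.astype(float)
    rng = np.random.default_rng(rng_seed)

    def take_step(i1, i2):
        nonlocal b, E
        if i1 == i2:
            return False
        a1, a2 = alpha[i1], alpha[i2]
        y1, y2 = y[i1], y[i2]
        E1, E2 = E[i1], E[i2]
        s = y1 * y2
        if s < 0:
            L, H = max(0.0, a2 - a1), min(C, C + a2 - a1)
        else:
            L, H = max(0.0, a1 + a2 - C), min(C, a1 + a2)
        if L >= H - _EPS:
            return False
        k11, k12, k22 = K[i1, i1], K[i1, i2], K[i2, i2]
        eta = k11 + k22 - 2.0 * k12
        if eta > _EPS:
            a2new = a2 + y2 * (E1 - E2) / eta
            a2new = min(max(a2new, L), H)
        else:
            # degenerate curvature: evaluate the objective at both ends
            f1 = y1 * E1 - a1 * k11 - s * a2 * k12
            f2 = y2 * E2 - s * a1 * k12 - a2 * k22
            L1, H1 = a1 + s * (a2 - L), a1 + s * (a2 - H)
            Lobj = L1 * f1 + L * f2 + 0.5 * L1**2 * k11 + 0.5 * L**2 * k22 + s * L * L1 * k12
            Hobj = H1 * f1 + H * f2 + 0.5 * H1**2 * k11 + 0.5 * H**2 * k22 + s * H * H1 * k12
            if Lobj < Hobj - 1e-3 * tol:
                a2new = L
            elif Lobj > Hobj + 1e-3 * tol:
                a2new = H
            else:
                a2new = a2
        if abs(a2new - a2) < 1e-3 * tol * (a2new + a2 + 1e-3 * tol):
            return False
        a1new = a1 + s * (a2 - a2new)
        # bias update keeps KKT on the two updated points
        b1 = b - E1 - y1 * (a1new - a1) * k11 - y2 * (a2new - a2) * k12
        b2 = b - E2 - y1 * (a1new - a1) * k12 - y2 * (a2new - a2) * k22
        if 0 < a1new < C:
            bnew = b1
        elif 0 < a2new < C:
            bnew = b2
        else:
            bnew = 0.5 * (b1 + b2)
        dE = (
            y1 * (a1new - a1) * K[i1]
            + y2 * (a2new - a2) * K[i2]
            + (bnew - b)
        )
        E += dE
        alpha[i1], alpha[i2] = a1new, a2new
        b = bnew
        return True

    def examine(i2):
        y2, a2, E2 = y[i2], alpha[i2], E[i2]
        r2 = E2 * y2
        if (r2 < -tol and a2 < C) or (r2 > tol and a2 > 0):
            non_bound = np.flatnonzero((alpha > _EPS) & (alpha < C - _EPS))
            if len(non_bound) > 1:
                i1 = non_bound[np.argmax(np.abs(E[non_bound] - E2))]
                if take_step(int(i1), i2):
                    return True
            for i1 in rng.permutation(non_bound):
                if take_step(int(i1), i2):
                    return True
            for i1 in rng.permutation(n):
                if take_step(int(i1), i2):
                    return True
        return False

    examine_all = True
    sweeps = 0
    while sweeps < max_sweeps:
        sweeps += 1
        changed = 0
        targets = (
            range(n)
            if examine_all
            else np.flatnonzero((alpha > _EPS) & (alpha < C - _EPS))
        )
        for i2 in targets:
            changed += examine(int(i2))
        if examine_all:
            if changed == 0:
                return alpha, b
            examine_all = False
        elif changed == 0:
            examine_all = True
    raise ConvergenceError(f"SMO did not converge within {max_sweeps} sweeps")


def default_gamma(X: np.ndarray) -> float:
    """Kernel width heuristic 1 / (2 * mean per-feature variance)."""
    v = float(np.mean(np.var(np.asarray(X, dtype=float), axis=0, ddof=0)))
    if v <= 0:
        raise DataError("zero feature variance: cannot set default gamma")
    return 1.0 / (2.0 * v)


def svc_fit(
    train: PloidyDataset,
    C: float = 1.0,
    gamma: float | None = None,
    tol: float = KKT_TOL,
) -> SVCModel:
    """Fit one-vs-one RBF subproblems over every class pair present."""
    if C <= 0:
        raise DomainError("C must be > 0")
    present = [c for c in train.classes if np.any(train.y == c)]
    if len(present) < 2:
        raise DataError("SVC needs at least 2 classes present")
    if gamma is None:
        gamma = default_gamma(train.X)
    if gamma <= 0:
        raise DomainError("gamma must be > 0")
    subs = []
    for i, ca in enumerate(present):
        for cb in present[i + 1 :]:
            mask = (train.y == ca) | (train.y == cb)
            X = train.X[mask]
            ysign = np.where(train.y[mask] == ca, 1.0, -1.0)
            K = rbf_kernel(X, X, gamma)
            try:
                alpha, b = _smo_solve(K, ysign, C, tol=tol)
            except ConvergenceError as exc:
                raise ConvergenceError(f"subproblem {ca!r} vs {cb!r}: {exc}") from exc
            subs.append(
                BinarySVC(classes=(ca, cb), X=X.copy(), y=ysign, alpha=alpha,
                          b=float(b), gamma=float(gamma), C=float(C))
            )
    return SVCModel(subproblems=tuple(subs), C=float(C), gamma=float(gamma),
                    classes=train.classes)


def svc_decision_values(m: SVCModel, x) -> dict[tuple[str, str], np.ndarray]:
    """Per-subproblem decision values f(x) for one query or a batch."""
    X = np.atleast_2d(np.asarray(x, dtype=float))
    return {p.classes: p.decision(X) for p in m.subproblems}


def svc_predict(m: SVCModel, x) -> str | np.ndarray:
    """One-vs-one majority vote over subproblem decision signs."""
    x_arr = np.asarray(x, dtype=float)
    X = np.atleast_2d(x_arr)
    n = len(X)
    votes = {c: np.zeros(n) for c in m.classes}
    absdec = {c: np.zeros(n) for c in m.classes}
    for p in m.subproblems:
        f = p.decision(X)
        pos = f > 0
        ca, cb = p.classes
        votes[ca] += pos
        votes[cb] += ~pos
        absdec[ca] += np.abs(f)
        absdec[cb] += np.abs(f)
    out = np.empty(n, dtype=object)
    for i in range(n):
        best = max(votes[c][i] for c in m.classes)
        tied = [c for c in m.classes if votes[c][i] == best]
        if len(tied) > 1:
            top = max(absdec[c][i] for c in tied)
            tied = [c for c in tied if absdec[c][i] == top]
        out[i] = tied[0]
    return out[0] if x_arr.ndim == 1 else out
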