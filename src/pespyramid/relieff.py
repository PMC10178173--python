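"""ReliefF feature weighting and iterative ranked-prefix selection.

ReliefF scores each feature by how well it separates nearest neighbors of
different classes while staying stable among neighbors of the same class.
For a queried instance R_i the k nearest same-class neighbors are its *hits*
H_j and the k nearest neighbors from each other class C its *misses* M_j^C;
every feature weight is updated by

    W[A] <- W[A] - sum_j diff(A, R_i, H_j) / (m k)
                 + sum_{C != class(R_i)} P(C)/(1 - P(class(R_i)))
                   * sum_j diff(A, R_i, M_j^C) / (m k)

where m is the number of update cycles, P(C) the empirical class prior, and
diff the per-feature distance on min-max normalized values (|a - b| for
continuous features; the 0/1 indicator in discrete mode).  Weights therefore
lie in [-1, 1] on [0, 1]-normalized data.

This implementation runs one deterministic cycle per instance (m = n) rather
than sampling instances at random, uses Manhattan distance (the sum of
per-feature diffs) for the neighbor search, and breaks distance ties by
lower instance index, so weights are a pure function of the data.

The iterative selection step then evaluates growing prefixes of the
descending-weight feature ranking with a cross-validated classifier loss and
keeps the prefix with minimum loss (first minimum on ties).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.spatial.distance import cdist

from .features import FeatureMatrix

__all__ = [
    "ReliefFParams",
    "RankedFeatures",
    "SelectionResult",
    "minmax_normalize",
    "diff",
    "relieff_rank",
    "iterative_select",
]


@dataclass
class ReliefFParams:
    """Neighborhood parameters: k nearest hits/misses (default 10)."""

    k_neighbors: int = 10
    distance: str = "cityblock"

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError(f"k_neighbors must be >= 1, got {self.k_neighbors}")


@dataclass
class RankedFeatures:
    """Per-feature ReliefF weights, their descending ordering, class priors."""

    weights: np.ndarray
    order: np.ndarray
    priors: dict = field(default_factory=dict)


@dataclass
class SelectionResult:
    """Loss per evaluated ranked prefix and the minimizing prefix."""

    prefix_sizes: np.ndarray
    losses: np.ndarray
    best_size: int
    selected_columns: np.ndarray

    @property
    def best_loss(self) -> float:
        return float(self.losses[np.searchsorted(self.prefix_sizes, self.best_size)])


def _as_values(X) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        return X.values
    return np.asarray(X, dtype=np.float64)


def minmax_normalize(X):
    """Map each column to [0, 1] via (x - min) / (max - min).

    Constant columns map to all-zeros (avoiding 0/0); they carry no
    neighborhood information and end up with ReliefF weight exactly 0.
    Accepts and returns either a FeatureMatrix or a plain array.
    """
    values = _as_values(X)
    if values.size == 0:
        raise ValueError("cannot normalize an empty matrix")
    if np.isnan(values).any():
        raise ValueError("feature matrix contains missing values")
    lo = values.min(axis=0)
    span = values.max(axis=0) - lo
    out = np.zeros_like(values, dtype=np.float64)
    nonconst = span > 0
    out[:, nonconst] = (values[:, nonconst] - lo[nonconst]) / span[nonconst]
    if isinstance(X, FeatureMatrix):
        return FeatureMatrix(
            values=out, labels=X.labels, column_origin=X.column_origin, case_ids=X.case_ids
        )
    return out


def diff(a: float, b: float, mode: str = "continuous") -> float:
    """Per-feature distance between two instances' normalized values.

    Continuous mode is |a - b|; discrete mode is the 0/1 disagreement
    indicator.
    """
    if mode == "continuous":
        return abs(float(a) - float(b))
    if mode == "discrete":
        return 0.0 if a == b else 1.0
    raise ValueError(f"unknown diff mode {mode!r}")


def relieff_rank(X, y, params: ReliefFParams | None = None) -> RankedFeatures:
    """Compute ReliefF weights and the descending-weight feature ordering.

    ``X`` must be min-max normalized.  One update cycle is run per instance
    in index order (m = n); neighbor ties are broken by lower instance index
    and the final ordering is a stable descending argsort of the weights.
    """
    params = params or ReliefFParams()
    values = _as_values(X)
    y = np.asarray(y)
    n, d = values.shape
    classes, y_idx = np.unique(y, return_inverse=True)
    if classes.size < 2:
        raise ValueError("relieff_rank needs at least 2 classes")
    counts = np.bincount(y_idx)
    priors = {c: counts[ci] / n for ci, c in enumerate(classes)}

    k = params.k_neighbors
    if np.any(counts <= k):
        small = {str(classes[ci]): int(counts[ci]) for ci in range(classes.size) if counts[ci] <= k}
        warnings.warn(
            f"k_neighbors={k} exceeds available neighbors in classes {small}; clipping per class"
        )

    # Full pairwise Manhattan distance over normalized features; argsort is
    # stable so equal distances resolve to the lower instance index.
    dist = cdist(values, values, metric=params.distance)
    w = np.zeros(d, dtype=np.float64)
    m = n
    for i in range(n):
        ci = y_idx[i]
        for cj in range(classes.size):
            members = np.flatnonzero(y_idx == cj)
            if cj == ci:
                members = members[members != i]
            if members.size == 0:
                continue
            k_used = min(k, members.size)
            nearest = members[np.argsort(dist[i, members], kind="stable")[:k_used]]
            contrib = np.abs(values[i] - values[nearest]).sum(axis=0) / (m * k_used)
            if cj == ci:
                w -= contrib
            else:
                w += (priors[classes[cj]] / (1.0 - priors[classes[ci]])) * contrib
    order = np.argsort(-w, kind="stable")
    return RankedFeatures(weights=w, order=order, priors=priors)


def iterative_select(
    X,
    y,
    ranked: RankedFeatures,
    evaluator: Callable[[np.ndarray, np.ndarray], float],
    max_prefix: int | None = None,
    step: int = 1,
) -> SelectionResult:
    """Evaluate ranked prefixes with a loss function; keep the minimizer.

    Prefix sizes step, 2*step, ... up to ``max_prefix`` are evaluated
    (step=1 with the full width sweeps every prefix).  The evaluator maps a
    feature submatrix and labels to a loss in [0, 1]; the first minimum wins
    on ties, favoring the smallest subset.
    """
    values = _as_values(X)
    y = np.asarray(y)
    d = values.shape[1]
    if ranked.order.shape[0] != d:
        raise ValueError(
            f"ranking covers {ranked.order.shape[0]} columns but X has {d}"
        )
    if step < 1:
        raise ValueError(f"step must be >= 1, got {step}")
    if max_prefix is None:
        max_prefix = d
    if max_prefix > d:
        warnings.warn(f"max_prefix={max_prefix} exceeds {d} columns; clipping")
        max_prefix = d
    sizes = np.arange(step, max_prefix + 1, step)
    if sizes.size == 0:
        raise ValueError("no prefix sizes to evaluate; lower step or raise max_prefix")
    losses = np.empty(sizes.size, dtype=np.float64)
    for j, size in enumerate(sizes):
        cols = ranked.order[:size]
        losses[j] = float(evaluator(values[:, cols], y))
    best_j = int(np.argmin(losses))  # argmin returns the first minimum
    best_size = int(sizes[best_j])
    return SelectionResult(
        prefix_sizes=sizes,
        losses=losses,
        best_size=best_size,
        selected_columns=ranked.order[:best_size].copy(),
    )
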