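"""Optimal cepstral-coefficient subset selection by branch and bound.

The separability criterion is the sum of squared Euclidean distances
between all inter-class pairs of training vectors, restricted to the
candidate coordinates.  Through the usual mean/second-moment expansion it
decomposes into a class-pair-weighted between-means term plus per-class
scatter terms; both parts are non-negative and additive over coordinates,
so the criterion is monotone under subset inclusion — exactly the property
branch and bound needs to guarantee the global optimum without exhaustive
search.

For this criterion, applied to features standardised to unit variance,
the between-means form below is used (the scatter part is constant across
equal-sized subsets of standardised features and carries no class
information):

    J(S) = Σ_{i<j} N_i N_j ‖μ_i − μ_j‖²_S

with class means μ and class sizes N.  Ties between equally scoring
subsets break toward the lexicographically smallest index set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Sequence

import numpy as np

from .errors import ConfigError, ValidationError

_ENUM_GUARD = 1_000_000


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of a subset search: indices, criterion value, target size."""

    selected_indices: tuple[int, ...]
    criterion_value: float
    d_target: int


def _as_xy(X, y) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValidationError("X must be (n_samples, n_features) aligned with y")
    if np.unique(y).size < 2:
        raise ValidationError("separability requires at least two classes")
    return X, y


def dimension_weights(X, y) -> np.ndarray:
    """Per-coordinate criterion contribution w_f = Σ_{i<j} N_i N_j (μ_{i,f} − μ_{j,f})²."""
    X, y = _as_xy(X, y)
    classes = np.unique(y)
    means = np.stack([X[y == c].mean(axis=0) for c in classes])
    counts = np.array([(y == c).sum() for c in classes])
    w = np.zeros(X.shape[1])
    for i in range(len(classes)):
        for j in range(i + 1, len(classes)):
            w += counts[i] * counts[j] * (means[i] - means[j]) ** 2
    return w


def separability_criterion(X, y, subset: Sequence[int]) -> float:
    """Between-class separability of the coordinates in ``subset``."""
    X, y = _as_xy(X, y)
    subset = list(subset)
    if not subset:
        raise ValidationError("subset must be non-empty")
    if min(subset) < 0 or max(subset) >= X.shape[1] or len(set(subset)) != len(subset):
        raise ValidationError(f"invalid feature subset {subset}")
    return float(dimension_weights(X[:, subset], y).sum())


def _search_result(best_set: tuple[int, ...], best_val: float, d: int) -> SelectionResult:
    return SelectionResult(selected_indices=best_set, criterion_value=best_val, d_target=d)


def exhaustive_select(
    X, y, d_target: int, criterion: Callable[[tuple[int, ...]], float] | None = None
) -> SelectionResult:
    """Global optimum by full enumeration (test oracle for branch and bound)."""
    X, y = _as_xy(X, y)
    D = X.shape[1]
    if not 0 < d_target <= D:
        raise ConfigError(f"d_target must be in [1, {D}], got {d_target}")
    if math.comb(D, d_target) > _ENUM_GUARD:
        raise ConfigError(
            f"C({D}, {d_target}) exceeds the {_ENUM_GUARD} enumeration guard"
        )
    if criterion is None:
        w = dimension_weights(X, y)
        criterion = lambda s: float(w[list(s)].sum())
    best_set, best_val = None, -np.inf
    for combo in combinations(range(D), d_target):  # lexicographic order
        v = criterion(combo)
        if v > best_val:
            best_set, best_val = combo, v
    return _search_result(best_set, best_val, d_target)


def branch_and_bound_select(
    X, y, d_target: int = 6, criterion: Callable[[tuple[int, ...]], float] | None = None
) -> SelectionResult:
    """Exact best-subset search for a monotone criterion.

    Depth-first search over the feature-removal tree (Narendra–Fukunaga):
    starting from the full set, features are removed one at a time down to
    ``d_target``.  Because the criterion never increases when a feature is
    removed, a node whose value already falls below the incumbent cannot
    contain a better subset and its whole branch is pruned.  Children are
    visited in order of least criterion loss.  Equal-value ties resolve to
    the lexicographically smallest index set, matching the exhaustive
    oracle.
    """
    X, y = _as_xy(X, y)
    D = X.shape[1]
    if not 0 < d_target <= D:
        raise ConfigError(f"d_target must be in [1, {D}], got {d_target}")
    if criterion is None:
        w = dimension_weights(X, y)
        criterion = lambda s: float(w[list(s)].sum())
    cache: dict[tuple[int, ...], float] = {}

    def crit(s: tuple[int, ...]) -> float:
        if s not in cache:
            cache[s] = criterion(s)
        return cache[s]

    best_set: tuple[int, ...] | None = None
    best_val = -np.inf

    def visit(current: tuple[int, ...], start: int) -> None:
        nonlocal best_set, best_val
        if len(current) == d_target:
            v = crit(current)
            if v > best_val or (v == best_val and (best_set is None or current < best_set)):
                best_set, best_val = current, v
            return
        # removal positions are non-decreasing along a path, so each subset
        # is reached exactly once; position may not exceed d_target or too
        # few positions would remain for the later removals
        last = min(len(current) - 1, d_target)
        children = []
        for pos in range(start, last + 1):
            child = current[:pos] + current[pos + 1 :]
            children.append((crit(child), pos, child))
        children.sort(key=lambda t: (-t[0], t[1]))  # least loss first
        for v, pos, child in children:
            if v < best_val:
                continue  # monotonicity: nothing below can beat the incumbent
            visit(child, pos)

    visit(tuple(range(D)), 0)
    assert best_set is not None
    return _search_result(best_set, best_val, d_target)
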