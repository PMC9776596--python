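"""Unsupervised permutation filtering of species (filtering-loss based).

Rare, low-signal species dominate metagenomic count tables; this filter
removes the ones whose contribution to the abundance cross-product is
indistinguishable from noise, producing the "reduced species set" used by
the downstream benchmark.

The filtering loss of a removal set J is the fraction of the squared
Frobenius norm of the species cross-product X'X lost when the columns in J
are dropped:

    FL(J) = 1 - ||X_{-J}' X_{-J}||_F^2 / ||X'X||_F^2

FL is 0 for the empty set, 1 when everything is removed, monotone under
supersets, and invariant to rescaling X by a positive scalar. Species are
ordered by increasing individual filtering loss; the sequential increments
(DFL) along that ordering are compared, position by position, against a
permutation null obtained by removing the columns of X in random order
(simultaneous variant; comparing each observed increment to the null
increments at the same removal position is the empirical analogue of
quantile-matching the null across positions). All species at and beyond the
first position whose increment is significant are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix

DEFAULT_ALPHA = 0.10
DEFAULT_N_PERM = 99


@dataclass(frozen=True)
class FilterResult:
    """Outcome of the permutation filter."""

    order: list = field(repr=False)        # species ids, increasing FL
    fl: np.ndarray = field(repr=False)     # cumulative FL along the order
    dfl: np.ndarray = field(repr=False)    # sequential increments
    pvalues: np.ndarray = field(repr=False)
    retained: list = field(repr=False)
    alpha: float = DEFAULT_ALPHA

    @property
    def retained_fraction(self) -> float:
        return len(self.retained) / len(self.order)


def _as_matrix(X):
    if isinstance(X, AbundanceMatrix):
        return X.to_numpy(), list(X.species_ids)
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    arr = np.asarray(X, dtype=float)
    return arr, list(range(arr.shape[1]))


def filtering_loss(X, removal_set) -> float:
    """FL(J) = 1 - ||X_{-J}' X_{-J}||_F^2 / ||X' X||_F^2."""
    arr, species = _as_matrix(X)
    removal = set(removal_set)
    unknown = removal - set(species)
    if unknown:
        raise ValueError(f"removal set contains unknown species: "
                         f"{sorted(map(str, unknown))[:5]}")
    total = float(((arr.T @ arr) ** 2).sum())
    if total == 0:
        raise ValueError("X'X is identically zero")
    keep = [i for i, s in enumerate(species) if s not in removal]
    sub = arr[:, keep]
    kept = float(((sub.T @ sub) ** 2).sum())
    return 1.0 - kept / total


def _crossprod_stats(arr: np.ndarray):
    M2 = (arr.T @ arr) ** 2
    total = M2.sum()
    if total == 0:
        raise ValueError("X'X is identically zero")
    return M2, total, M2.sum(axis=1), np.diag(M2).copy()


def _sequential_fl(M2, total, row, diag, order) -> np.ndarray:
    """Cumulative FL along a removal order. O(S^2) after one X'X."""
    acc = np.zeros(len(order))
    remaining = total
    fl = np.empty(len(order))
    for pos, j in enumerate(order):
        remaining -= 2 * (row[j] - acc[j]) - diag[j]
        fl[pos] = 1.0 - remaining / total
        acc += M2[j]
    return fl


def _ordered_sequential_fl(arr: np.ndarray, species: list):
    """Order species by increasing individual FL (ties by species id) and
    return the order together with the cumulative FL along it."""
    M2, total, row, diag = _crossprod_stats(arr)
    individual = (2 * row - diag) / total
    order = sorted(range(len(species)), key=lambda j: (individual[j],
                                                       str(species[j])))
    return order, _sequential_fl(M2, total, row, diag, order)


def perfect_reduce(
    X,
    alpha: float = DEFAULT_ALPHA,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> FilterResult:
    """Permutation filter: drop species whose sequential filtering-loss
    increment is consistent with column-shuffled noise.

    Returns a :class:`FilterResult`; ``retained`` holds every species from
    the first significant increment onward (all species if no increment is
    significant).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    arr, species = _as_matrix(X)
    if arr.shape[1] < 3:
        raise ValueError("need at least 3 species to filter")

    order_idx, fl = _ordered_sequential_fl(arr, species)
    dfl = np.diff(fl, prepend=0.0)

    # null: remove columns in random order; compare increments per position
    rng = np.random.default_rng(seed)
    _, S = arr.shape
    M2, total, row, diag = _crossprod_stats(arr)
    exceed = np.zeros(S)
    for _ in range(n_perm):
        fl_p = _sequential_fl(M2, total, row, diag, rng.permutation(S))
        exceed += np.diff(fl_p, prepend=0.0) >= dfl
    pvalues = (1.0 + exceed) / (1.0 + n_perm)

    significant = np.flatnonzero(pvalues <= alpha)
    first = int(significant[0]) if significant.size else 0
    order_ids = [species[j] for j in order_idx]
    retained = sorted(order_ids[first:], key=str)
    return FilterResult(order_ids, fl, dfl, pvalues, retained, alpha)
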