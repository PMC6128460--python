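"""Pareto ranking of alternatives on multiple minimization criteria.

Alternatives are compared by weak Pareto dominance: a criteria vector ``u``
dominates ``v`` when every element of ``u`` is less than or equal to the
corresponding element of ``v`` and at least one element is strictly smaller
(lower value = higher conservation priority).  Ranking peels non-dominated
sets iteratively: the non-dominated set of all alternatives gets rank 1, the
non-dominated set of the remainder rank 2, and so on until every alternative
is ranked.  Identical criteria vectors always share a rank, and the ranking
is deterministic and independent of row order.

Because only within-criterion comparisons are made, the ranking is invariant
to any strictly increasing transformation of a single criterion — in
particular to positive per-criterion weights, which is why no subjective
weighting step is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ParetoRanker",
    "RankAssignment",
    "weakly_dominates",
    "non_dominated_mask",
    "pareto_rank_array",
    "composite_pareto_rank_array",
    "check_weighted_consistency",
]

#: rank value marking an alternative excluded from ranking (ranks start at 1)
UNRANKED = 0

# pairwise-comparison block size; bounds peak memory at ~BLOCK * K * M floats
_BLOCK = 256


def _as_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise ValueError(f"criteria must be 1- or 2-dimensional, got ndim={X.ndim}")
    return X


def weakly_dominates(u, v) -> bool:
    """True iff ``u`` weakly Pareto-dominates ``v`` (minimization).

    Every element of ``u`` must be <= the corresponding element of ``v`` and
    at least one strictly smaller; equal vectors do not dominate each other.
    """
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape != v.shape:
        raise ValueError(f"criteria vectors differ in length: {u.size} vs {v.size}")
    if not (np.isfinite(u).all() and np.isfinite(v).all()):
        raise ValueError("criteria vectors must be finite")
    return bool(np.all(u <= v) and np.any(u < v))


def _dominance_counts(X: np.ndarray) -> np.ndarray:
    """Number of rows of X that weakly dominate each row, computed blockwise."""
    K = X.shape[0]
    counts = np.zeros(K, dtype=np.int64)
    for start in range(0, K, _BLOCK):
        B = X[start : start + _BLOCK]  # (b, M)
        le = (B[:, None, :] <= X[None, :, :]).all(axis=2)
        lt = (B[:, None, :] < X[None, :, :]).any(axis=2)
        counts += (le & lt).sum(axis=0)
    return counts


def non_dominated_mask(X) -> np.ndarray:
    """Boolean mask of rows not weakly dominated by any other row.

    Duplicate rows are mutually non-dominating, so all copies of a
    non-dominated vector are flagged.  Never empty for non-empty input.
    """
    X = _as_matrix(X)
    if X.shape[0] == 0:
        raise ValueError("no alternatives to compare")
    if not np.isfinite(X).all():
        raise ValueError("criteria must be finite")
    return _dominance_counts(X) == 0


def pareto_rank_array(X) -> np.ndarray:
    """Pareto ranks (1-based, dense over fronts) for the rows of ``X``.

    Rows with any NaN are treated as excluded and receive ``UNRANKED`` (0).
    Infinite values are rejected.  See :class:`ParetoRanker` for the
    estimator interface.
    """
    X = _as_matrix(X)
    if np.isinf(X).any():
        raise ValueError("criteria must not contain infinities")
    valid = ~np.isnan(X).any(axis=1)
    ranks = np.full(X.shape[0], UNRANKED, dtype=np.int64)
    if not valid.any():
        raise ValueError("no valid alternatives to rank")
    V = X[valid]

    # identical vectors provably share a rank: rank unique rows, re-expand
    uniq, inverse = np.unique(V, axis=0, return_inverse=True)
    if uniq.shape[1] == 1:
        # 1-D Pareto ranking is dense ranking of the single criterion
        order = np.argsort(uniq[:, 0], kind="stable")
        uranks = np.empty(len(uniq), dtype=np.int64)
        uranks[order] = np.arange(1, len(uniq) + 1)
    else:
        uranks = _peel_fronts(uniq)
    ranks[valid] = uranks[inverse]
    return ranks


def _peel_fronts(U: np.ndarray) -> np.ndarray:
    """Front-peeling on unique rows via dominance counts (Deb-style).

    Counts dominators once in O(K^2 M) blockwise passes; each peeled front
    then decrements the counts of the rows it dominates.  No K x K matrix is
    materialized, so memory stays O(block * K).
    """
    n = U.shape[0]
    counts = _dominance_counts(U)
    ranks = np.zeros(n, dtype=np.int64)
    active = np.ones(n, dtype=bool)
    current = 0
    while active.any():
        current += 1
        front = active & (counts == 0)
        if not front.any():  # pragma: no cover - guarded by dominance acyclicity
            raise RuntimeError("dominance cycle detected; input not a partial order")
        ranks[front] = current
        active &= ~front
        if not active.any():
            break
        F = U[front]
        R = U[active]
        dec = np.zeros(R.shape[0], dtype=np.int64)
        for start in range(0, F.shape[0], _BLOCK):
            B = F[start : start + _BLOCK]
            le = (B[:, None, :] <= R[None, :, :]).all(axis=2)
            lt = (B[:, None, :] < R[None, :, :]).any(axis=2)
            dec += (le & lt).sum(axis=0)
        counts[active] -= dec
    return ranks


class ParetoRanker(BaseEstimator):
    """Rank alternatives by iterative non-dominated-set extraction.

    Criteria are minimized: smaller values mean higher priority.  The
    estimator follows the clusterer protocol — :meth:`fit` computes a rank
    per sample and :meth:`fit_predict` returns it — since Pareto ranks, like
    cluster labels, are defined only for the fitted sample.

    Parameters
    ----------
    on_missing : {"exclude", "raise"}, default="exclude"
        How to treat rows containing NaN.  ``"exclude"`` leaves them
        unranked (rank 0), mirroring the rule that a grid cell with any
        missing criterion is not ranked; ``"raise"`` rejects them.

    Attributes
    ----------
    ranks_ : ndarray of shape (n_samples,)
        Pareto rank per sample, 1-based; 0 marks excluded rows.
    max_rank_ : int
        Largest assigned rank (number of Pareto fronts).
    n_features_in_ : int
        Number of criteria seen during fit.

    Examples
    --------
    >>> ParetoRanker().fit_predict([[1, 4], [2, 2], [3, 3]])
    array([1, 1, 2])
    """

    def __init__(self, on_missing: str = "exclude"):
        self.on_missing = on_missing

    def fit(self, X, y=None):
        if self.on_missing not in ("exclude", "raise"):
            raise ValueError(f"on_missing must be 'exclude' or 'raise', got {self.on_missing!r}")
        X = _as_matrix(X)
        if self.on_missing == "raise" and np.isnan(X).any():
            raise ValueError("X contains NaN and on_missing='raise'")
        self.n_features_in_ = X.shape[1]
        self.ranks_ = pareto_rank_array(X)
        self.max_rank_ = int(self.ranks_.max())
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).ranks_

    def predict(self, X=None) -> np.ndarray:
        """Return the ranks of the fitted sample (Pareto ranks are in-sample)."""
        check_is_fitted(self)
        return self.ranks_


@dataclass
class RankAssignment:
    """Pareto ranks for a set of identified alternatives.

    ``rank`` holds a positive integer per alternative, with 0 marking
    alternatives excluded from ranking; ranks over included alternatives are
    contiguous from 1 to ``max_rank``.
    """

    ids: np.ndarray
    rank: np.ndarray
    max_rank: int = field(init=False)

    def __post_init__(self):
        self.ids = np.asarray(self.ids)
        self.rank = np.asarray(self.rank, dtype=np.int64)
        if self.ids.shape != self.rank.shape:
            raise ValueError("ids and rank must have the same length")
        if len(np.unique(self.ids)) != len(self.ids):
            raise ValueError("alternative ids must be unique")
        ranked = self.rank[self.rank != UNRANKED]
        self.max_rank = int(ranked.max()) if ranked.size else 0
        if ranked.size:
            expected = np.arange(1, self.max_rank + 1)
            if not np.array_equal(np.unique(ranked), expected):
                raise ValueError("ranks must be contiguous from 1")

    @property
    def ranked_mask(self) -> np.ndarray:
        return self.rank != UNRANKED

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"id": self.ids, "rank": self.rank})


def composite_pareto_rank_array(component_ranks) -> np.ndarray:
    """Pareto-rank alternatives on the ranks from two or more prior rankings.

    The component ranks become the criteria of a new decision problem
    (lower rank = higher priority) which is Pareto-ranked again.  This
    widens the range of assigned ranks relative to ranking the pooled
    criteria directly.  An alternative unranked (0) in any component is
    unranked in the composite.
    """
    R = np.column_stack([np.asarray(r, dtype=float) for r in component_ranks])
    if R.shape[1] < 2:
        raise ValueError("composite ranking needs at least two components")
    R = R.copy()
    R[R == UNRANKED] = np.nan
    return pareto_rank_array(R)


def check_weighted_consistency(X, w) -> bool:
    """Validate that dominance implies weighted-sum order for positive weights.

    For every pair where row ``k`` weakly dominates row ``l``, checks that
    ``w @ x_k <= w @ x_l``.  This holds for any strictly positive weight
    vector, which is why additive multi-attribute value scores can never
    reverse a Pareto-dominance relation and weights play no role in the
    ranking itself.
    """
    X = _as_matrix(X)
    w = np.asarray(w, dtype=float).ravel()
    if w.size != X.shape[1]:
        raise ValueError("weight length must match number of criteria")
    if not (w > 0).all():
        raise ValueError("weights must be strictly positive")
    valid = ~np.isnan(X).any(axis=1)
    V = X[valid]
    scores = V @ w
    ok = True
    for start in range(0, V.shape[0], _BLOCK):
        B = V[start : start + _BLOCK]
        le = (B[:, None, :] <= V[None, :, :]).all(axis=2)
        lt = (B[:, None, :] < V[None, :, :]).any(axis=2)
        dom = le & lt
        k_idx, l_idx = np.nonzero(dom)
        if not np.all(scores[start + k_idx] <= scores[l_idx] + 1e-12):
            ok = False
            break
    return ok
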