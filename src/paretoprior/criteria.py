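"""Value functions and decision-matrix assembly.

Raw attributes become minimization criteria through one of two linear
min-max value functions, chosen by preference direction:

* ``f(a) = (a - min a) / (max a - min a)`` — order-preserving; used when a
  LOWER attribute value means higher priority (e.g. fire return interval
  departure, where negative departures flag overly frequent fire; patch
  area, where small fragments are the concern).
* ``g(a) = (max a - a) / (max a - min a)`` — order-reversing; used when a
  HIGHER attribute value means higher priority (fire counts, road and
  development density, species richness, genetic diversity/divergence).

Both map onto [0, 1] with lower = higher priority.  Because Pareto ranking
only uses within-criterion comparisons, these transforms never change the
ranking — they standardize sign and scale for presentation and for
downstream weighted-score checks.  Min and max are computed over in-mask,
non-missing cells only, and missing values propagate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .ranking import UNRANKED, RankAssignment, pareto_rank_array
from .stack import AttributeStack

__all__ = [
    "ValueFunctionSpec",
    "DecisionMatrix",
    "MinMaxCriteria",
    "value_fn_f",
    "value_fn_g",
    "build_decision_matrix",
    "concat_matrices",
    "pareto_rank",
    "composite_pareto_rank",
]

#: preference direction -> value function kind
DIRECTIONS = ("lower_is_priority", "higher_is_priority")


@dataclass(frozen=True)
class ValueFunctionSpec:
    """One criterion: which attribute, and which direction marks priority."""

    attribute_name: str
    direction: str

    def __post_init__(self):
        if self.direction not in DIRECTIONS:
            raise ValueError(
                f"direction must be one of {DIRECTIONS}, got {self.direction!r}"
            )


def _minmax(a: np.ndarray) -> tuple[float, float]:
    finite = a[~np.isnan(a)]
    if finite.size == 0:
        raise ValueError("attribute column is entirely missing")
    return float(finite.min()), float(finite.max())


def _scale(a: np.ndarray, lo: float, hi: float, reverse: bool) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if hi == lo:
        warnings.warn(
            "constant attribute column: criterion set to 0 everywhere "
            "(expresses no preference)",
            UserWarning,
            stacklevel=3,
        )
        out = np.zeros_like(a)
        out[np.isnan(a)] = np.nan
        return out
    return (hi - a) / (hi - lo) if reverse else (a - lo) / (hi - lo)


def value_fn_f(a) -> np.ndarray:
    """Order-preserving min-max value function: min -> 0, max -> 1."""
    a = np.asarray(a, dtype=float)
    lo, hi = _minmax(a)
    return _scale(a, lo, hi, reverse=False)


def value_fn_g(a) -> np.ndarray:
    """Order-reversing min-max value function: max -> 0, min -> 1."""
    a = np.asarray(a, dtype=float)
    lo, hi = _minmax(a)
    return _scale(a, lo, hi, reverse=True)


class MinMaxCriteria(TransformerMixin, BaseEstimator):
    """Direction-aware min-max scaling of attributes into criteria.

    Like ``MinMaxScaler``, but each column may be order-reversed so that
    lower output always means higher priority.  Column statistics are
    learned in :meth:`fit` over non-missing rows and reused in
    :meth:`transform`; NaN propagates.

    Parameters
    ----------
    directions : sequence of str, or single str, default="lower_is_priority"
        Per-column preference direction (``"lower_is_priority"`` applies the
        order-preserving map f, ``"higher_is_priority"`` the order-reversing
        map g).  A single string is broadcast to all columns.
    """

    def __init__(self, directions="lower_is_priority"):
        self.directions = directions

    def _resolved_directions(self, n_cols: int) -> list[str]:
        dirs = self.directions
        if isinstance(dirs, str):
            dirs = [dirs] * n_cols
        dirs = list(dirs)
        if len(dirs) != n_cols:
            raise ValueError(f"expected {n_cols} directions, got {len(dirs)}")
        for d in dirs:
            if d not in DIRECTIONS:
                raise ValueError(f"direction must be one of {DIRECTIONS}, got {d!r}")
        return dirs

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        self.n_features_in_ = X.shape[1]
        self.directions_ = self._resolved_directions(X.shape[1])
        mins, maxs = [], []
        for j in range(X.shape[1]):
            lo, hi = _minmax(X[:, j])
            mins.append(lo)
            maxs.append(hi)
        self.data_min_ = np.array(mins)
        self.data_max_ = np.array(maxs)
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[1] != self.n_features_in_:
            raise ValueError("column count changed between fit and transform")
        out = np.empty_like(X)
        for j, direction in enumerate(self.directions_):
            out[:, j] = _scale(
                X[:, j],
                self.data_min_[j],
                self.data_max_[j],
                reverse=(direction == "higher_is_priority"),
            )
        return out


@dataclass
class DecisionMatrix:
    """Alternatives x criteria table for Pareto ranking.

    Rows are spatial units (grid cells), columns are criteria in [0, 1]
    where lower = higher priority.  A row participates in ranking only when
    ``valid`` — i.e. none of its criteria are missing *in this matrix*;
    validity may differ between matrices built from different criteria
    subsets of the same stack.
    """

    ids: np.ndarray
    criteria_names: list[str]
    values: np.ndarray
    valid: np.ndarray = None

    def __post_init__(self):
        self.ids = np.asarray(self.ids)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != len(self.ids):
            raise ValueError("values row count must match ids")
        if self.values.shape[1] != len(self.criteria_names):
            raise ValueError("values column count must match criteria_names")
        if len(np.unique(self.ids)) != len(self.ids):
            raise ValueError("alternative ids must be unique")
        computed = ~np.isnan(self.values).any(axis=1)
        if self.valid is None:
            self.valid = computed
        else:
            self.valid = np.asarray(self.valid, dtype=bool) & computed

    @property
    def n_alternatives(self) -> int:
        return len(self.ids)

    @property
    def n_criteria(self) -> int:
        return len(self.criteria_names)

    def masked_values(self) -> np.ndarray:
        """Values with invalid rows fully NaN (the form the ranker consumes)."""
        out = self.values.copy()
        out[~self.valid] = np.nan
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.criteria_names)
        df.insert(0, "id", self.ids)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DecisionMatrix":
        if "id" not in df.columns:
            raise ValueError("decision-matrix table needs an 'id' column")
        names = [c for c in df.columns if c != "id"]
        return cls(df["id"].to_numpy(), names, df[names].to_numpy(dtype=float))

    @classmethod
    def from_csv(cls, path) -> "DecisionMatrix":
        return cls.from_frame(pd.read_csv(path))


def build_decision_matrix(
    stack: AttributeStack, specs: list[ValueFunctionSpec]
) -> DecisionMatrix:
    """Assemble a decision matrix from an attribute stack.

    One row per in-mask cell (id = row-major cell index).  Each named
    attribute is min-max transformed per its direction, with statistics
    taken over in-mask non-missing cells.  A row is valid only if all of its
    criteria are non-missing; such cells are left unranked downstream.
    """
    if not specs:
        raise ValueError("need at least one criterion spec")
    in_mask = stack.mask.ravel()
    if not in_mask.any():
        raise ValueError("analysis mask is empty")
    ids = stack.cell_ids()[in_mask]
    cols = []
    for spec in specs:
        a = stack.masked_values(spec.attribute_name)[in_mask]
        fn = value_fn_f if spec.direction == "lower_is_priority" else value_fn_g
        cols.append(fn(a))
    names = [s.attribute_name for s in specs]
    return DecisionMatrix(ids, names, np.column_stack(cols))


def concat_matrices(matrices: list[DecisionMatrix]) -> DecisionMatrix:
    """Column-wise concatenation [A | B | ...] over identical alternatives.

    A row of the result is valid iff it is valid in every component.
    """
    if not matrices:
        raise ValueError("nothing to concatenate")
    first = matrices[0]
    for m in matrices[1:]:
        if not np.array_equal(m.ids, first.ids):
            raise ValueError("alternative ids differ between matrices")
    names = [n for m in matrices for n in m.criteria_names]
    values = np.hstack([m.values for m in matrices])
    valid = np.logical_and.reduce([m.valid for m in matrices])
    return DecisionMatrix(first.ids.copy(), names, values, valid)


def pareto_rank(X: DecisionMatrix) -> RankAssignment:
    """Pareto-rank a decision matrix; invalid rows stay unranked."""
    if not X.valid.any():
        raise ValueError("no valid alternatives to rank")
    return RankAssignment(X.ids, pareto_rank_array(X.masked_values()))


def composite_pareto_rank(components: list[RankAssignment]) -> RankAssignment:
    """Pareto-rank alternatives on the ranks of two or more prior rankings.

    Component ranks become the criteria of a new (lower-is-better) decision
    problem.  An alternative unranked in any component is unranked in the
    composite.  Used to widen the range of assigned ranks when many criteria
    compress the fronts.
    """
    if len(components) < 2:
        raise ValueError("composite ranking needs at least two components")
    first = components[0]
    for c in components[1:]:
        if not np.array_equal(c.ids, first.ids):
            raise ValueError("components cover different alternative sets")
    R = np.column_stack([c.rank.astype(float) for c in components])
    R[R == UNRANKED] = np.nan
    return RankAssignment(first.ids.copy(), pareto_rank_array(R))
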