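"""Quantile regression forests for difference outcomes.

A random forest regressor is fitted to each difference outcome; conditional
quantiles are then read off the weighted empirical distribution of training
outcomes, with weights given by leaf co-membership between the query point
and the training points (Meinshausen's quantile regression forest).  For a
query ``x`` the weight of training point ``i`` is the average over trees of
``1/|leaf(x)|`` if ``i`` falls in the same leaf as ``x``, else 0; quantiles
are lower-weighted-order statistics (type-1) of the training outcomes under
those weights, so a forest consisting of a single unsplit tree reproduces
plain empirical quantiles exactly.

All training points (in-bag and out-of-bag alike) participate in the
weighting; each tree is grown on a bootstrap resample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence, Union

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .frames import DiffFrame

__all__ = ["ForestParams", "QuantileForestModel", "fit_forest"]

# cumulative-weight comparisons: floating summation of n weights of size 1/n
# can undershoot exact multiples of q by a few ulp
_CUM_EPS = 1e-9


@dataclass(frozen=True)
class ForestParams:
    """Hyperparameters of the tree ensemble.

    ``features_per_split`` may be a positive integer, the string ``"all"``,
    or ``"third"`` (the default: ceil(p/3) candidate features per split, the
    customary regression-forest default).
    """

    n_trees: int = 500
    min_leaf_size: int = 5
    features_per_split: Union[int, str] = "third"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.min_leaf_size < 1:
            raise ValueError("min_leaf_size must be >= 1")
        if isinstance(self.features_per_split, str):
            if self.features_per_split not in ("all", "third"):
                raise ValueError("features_per_split must be an int, 'all' or 'third'")
        elif self.features_per_split < 1:
            raise ValueError("features_per_split must be >= 1")

    def resolve_max_features(self, n_predictors: int) -> int:
        if self.features_per_split == "all":
            return n_predictors
        if self.features_per_split == "third":
            return max(1, math.ceil(n_predictors / 3))
        return min(int(self.features_per_split), n_predictors)


class QuantileForestModel:
    """A fitted forest for one difference outcome.

    Use :func:`fit_forest` to construct.  Exposes ensemble-mean prediction
    (:meth:`predict_mean`) and conditional quantiles
    (:meth:`predict_quantiles`).
    """

    def __init__(
        self,
        forest: RandomForestRegressor,
        X_train: np.ndarray,
        y_train: np.ndarray,
        outcome_name: str,
        predictor_names: Sequence[str],
        params: ForestParams,
    ):
        self._forest = forest
        self._X_train = X_train
        self._y_train = y_train
        self.outcome_name = outcome_name
        self.predictor_names = tuple(predictor_names)
        self.params = params
        # per-tree leaf bookkeeping for Meinshausen weights
        self._order_y = np.argsort(y_train, kind="stable")
        self._y_sorted = y_train[self._order_y]
        self._train_leaves: List[np.ndarray] = []
        self._leaf_sort: List[np.ndarray] = []  # train indices grouped by leaf
        self._leaf_starts: List[np.ndarray] = []
        self._leaf_counts: List[np.ndarray] = []
        rank_of = np.empty_like(self._order_y)
        rank_of[self._order_y] = np.arange(len(y_train))
        self._rank_of = rank_of
        for est in forest.estimators_:
            tl = est.apply(X_train)
            n_leaf_ids = int(tl.max()) + 1
            counts = np.bincount(tl, minlength=n_leaf_ids)
            order = np.argsort(tl, kind="stable")
            starts = np.searchsorted(tl[order], np.arange(n_leaf_ids))
            self._train_leaves.append(tl)
            self._leaf_sort.append(order)
            self._leaf_starts.append(starts)
            self._leaf_counts.append(counts)

    # ------------------------------------------------------------------
    @property
    def n_train(self) -> int:
        return len(self._y_train)

    @property
    def training_targets(self) -> np.ndarray:
        return self._y_train.copy()

    def _as_matrix(self, points: Union[pd.DataFrame, np.ndarray]) -> np.ndarray:
        if isinstance(points, pd.DataFrame):
            missing = [c for c in self.predictor_names if c not in points.columns]
            if missing:
                raise ValueError(f"points are missing predictor columns {missing}")
            return points[list(self.predictor_names)].to_numpy(dtype=float)
        X = np.asarray(points, dtype=float)
        if X.ndim == 1:
            X = X.reshape(1, -1)
        if X.shape[1] != len(self.predictor_names):
            raise ValueError(
                f"expected {len(self.predictor_names)} predictor columns, got {X.shape[1]}"
            )
        return X

    def predict_mean(self, points: Union[pd.DataFrame, np.ndarray]) -> np.ndarray:
        """Ensemble-average predicted change at each query row."""
        return self._forest.predict(self._as_matrix(points))

    def predict_quantiles(
        self,
        points: Union[pd.DataFrame, np.ndarray],
        qs: Sequence[float],
        chunk_size: int = 4096,
    ) -> np.ndarray:
        """Conditional quantiles of the change distribution at each query row.

        Returns an array of shape ``(n_rows, len(qs))`` that is non-decreasing
        along the quantile axis.
        """
        qs = list(qs)
        if not qs:
            raise ValueError("qs must be non-empty")
        if any(not 0 < q < 1 for q in qs):
            raise ValueError(f"quantile levels must lie in (0, 1), got {qs}")
        if sorted(qs) != qs:
            raise ValueError("quantile levels must be sorted ascending")
        X = self._as_matrix(points)
        out = np.empty((X.shape[0], len(qs)))
        for lo in range(0, X.shape[0], chunk_size):
            out[lo : lo + chunk_size] = self._quantiles_chunk(X[lo : lo + chunk_size], qs)
        return out

    def _quantiles_chunk(self, X: np.ndarray, qs: Sequence[float]) -> np.ndarray:
        m = X.shape[0]
        n = self.n_train
        n_trees = len(self._forest.estimators_)
        # weight matrix in sorted-outcome order
        W = np.zeros((m, n), dtype=np.float64)
        W_flat = W.ravel()
        rows_base = np.arange(m) * n
        for k, est in enumerate(self._forest.estimators_):
            ql = est.apply(X)
            counts = self._leaf_counts[k]
            starts = self._leaf_starts[k]
            lens = counts[ql]
            total = int(lens.sum())
            row = np.repeat(rows_base, lens)
            offs = np.repeat(np.cumsum(lens) - lens, lens)
            within = np.arange(total) - offs
            members = self._leaf_sort[k][np.repeat(starts[ql], lens) + within]
            cols = self._rank_of[members]
            w = 1.0 / (np.repeat(lens, lens) * n_trees)
            # each (query, train) pair occurs at most once per tree
            W_flat[row + cols] += w
        np.cumsum(W, axis=1, out=W)
        out = np.empty((m, len(qs)))
        for j, q in enumerate(qs):
            idx = np.argmax(W >= q - _CUM_EPS, axis=1)
            out[:, j] = self._y_sorted[idx]
        return out

    # ------------------------------------------------------------------
    def save(self, path: str) -> None:
        """Persist the fitted model (forest, training targets, metadata)."""
        joblib.dump(
            {
                "format": "dyntopo-quantile-forest",
                "version": 1,
                "forest": self._forest,
                "X_train": self._X_train,
                "y_train": self._y_train,
                "outcome_name": self.outcome_name,
                "predictor_names": self.predictor_names,
                "params": self.params,
            },
            path,
        )

    @classmethod
    def load(cls, path: str) -> "QuantileForestModel":
        blob = joblib.load(path)
        if blob.get("format") != "dyntopo-quantile-forest":
            raise ValueError(f"{path} is not a saved quantile-forest model")
        return cls(
            forest=blob["forest"],
            X_train=blob["X_train"],
            y_train=blob["y_train"],
            outcome_name=blob["outcome_name"],
            predictor_names=blob["predictor_names"],
            params=blob["params"],
        )


def fit_forest(
    train: DiffFrame,
    outcome: str,
    params: ForestParams = ForestParams(),
) -> QuantileForestModel:
    """Fit a quantile regression forest for one difference outcome.

    Predictors are the frame's current-value columns (modeled channels plus
    controls); ``outcome`` must be one of the frame's outcome columns.
    """
    if outcome not in train.outcome_names:
        raise ValueError(
            f"outcome {outcome!r} not in frame outcomes {list(train.outcome_names)}"
        )
    predictors = list(train.predictor_names)
    n = len(train)
    # an ensemble of unsplit trees (min_leaf_size == n) is legitimate: it
    # predicts the marginal outcome distribution everywhere
    if n < max(2, params.min_leaf_size):
        raise ValueError(
            f"need at least {max(2, params.min_leaf_size)} rows to fit (got {n})"
        )
    X = train.data[predictors].to_numpy(dtype=float)
    y = train.data[outcome].to_numpy(dtype=float)
    forest = RandomForestRegressor(
        n_estimators=params.n_trees,
        min_samples_leaf=params.min_leaf_size,
        max_features=params.resolve_max_features(len(predictors)),
        bootstrap=True,
        random_state=params.seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    return QuantileForestModel(forest, X, y, outcome, predictors, params)
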