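"""Set-point detection on predictor grids.

A *set point* is a coordinate in predictor space at which the fitted model
predicts no change: the pseudo-confidence interval spanned by a below-median
and an above-median conditional quantile of predicted change contains zero.
For a system of several simultaneous difference equations the interval must
contain zero for *every* equation at the same coordinate.

The multi-quantile sweep repeats the test over a family of nested quantile
pairs and counts, per coordinate, how many pairs flag it — the support count
visualized as a heat map (darker = flagged by more, hence narrower, pairs).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .forest import QuantileForestModel

__all__ = [
    "Grid",
    "SetPoint",
    "build_grid",
    "find_setpoints",
    "quantile_sweep",
    "default_quantile_pairs",
    "cusp_default_grid",
]


@dataclass(frozen=True)
class Grid:
    """A Cartesian product of axis coordinates over predictor space."""

    axes: Tuple[Tuple[str, np.ndarray], ...]
    points: pd.DataFrame

    @property
    def axis_names(self) -> Tuple[str, ...]:
        return tuple(name for name, _ in self.axes)

    @property
    def steps(self) -> Dict[str, float]:
        """Axis step sizes (NaN for single-coordinate axes)."""
        return {
            name: float(vals[1] - vals[0]) if len(vals) > 1 else float("nan")
            for name, vals in self.axes
        }

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class SetPoint:
    """A flagged zero-change coordinate with its per-equation intervals."""

    coordinate: Dict[str, float]
    intervals: Dict[str, Tuple[float, float]]
    support_count: int = 0
    dynamics_class: str = "unclassified"


def build_grid(axis_specs: Sequence[Tuple[str, float, float, float]]) -> Grid:
    """Build an inclusive-endpoint grid from ``(name, min, max, step)`` specs.

    Coordinates are enumerated as ``min + k*step`` for integer ``k``, which is
    robust to floating-point accumulation; the endpoint is included whenever
    ``(max - min)`` is an integer multiple of ``step`` to within 1e-9 steps.
    """
    if not axis_specs:
        raise ValueError("at least one axis is required")
    axes = []
    for name, lo, hi, step in axis_specs:
        if not lo < hi:
            raise ValueError(f"axis {name!r}: min {lo} must be < max {hi}")
        if step <= 0:
            raise ValueError(f"axis {name!r}: step must be positive, got {step}")
        n_steps = int(np.floor((hi - lo) / step + 1e-9))
        vals = lo + step * np.arange(n_steps + 1)
        axes.append((name, vals))
    mesh = np.meshgrid(*[v for _, v in axes], indexing="ij")
    points = pd.DataFrame({name: m.ravel() for (name, _), m in zip(axes, mesh)})
    return Grid(axes=tuple((n, v) for n, v in axes), points=points)


def cusp_default_grid() -> Grid:
    """The default grid for the cusp study: Y in [-1, 1], A and B in
    [-0.5, 0.5], all with step 0.05 (41 x 21 x 21 = 18081 candidates)."""
    return build_grid(
        [("y", -1.0, 1.0, 0.05), ("a", -0.5, 0.5, 0.05), ("b", -0.5, 0.5, 0.05)]
    )


def default_quantile_pairs() -> List[Tuple[float, float]]:
    """The 24 even-integer quantile pairs (0.02, 0.98) ... (0.48, 0.52)."""
    return [(k / 100, 1 - k / 100) for k in range(2, 50, 2)]


def _check_grid_covers(models: Sequence[QuantileForestModel], grid: Grid) -> None:
    for m in models:
        missing = [p for p in m.predictor_names if p not in grid.axis_names]
        if missing:
            raise ValueError(
                f"grid axes {list(grid.axis_names)} do not cover predictors "
                f"{missing} of model for {m.outcome_name!r}"
            )


def _interval_matrix(
    models: Sequence[QuantileForestModel], grid: Grid, q_low: float, q_high: float
) -> List[np.ndarray]:
    """Per model, an (n_points, 2) array of [q_low, q_high] predicted change."""
    return [m.predict_quantiles(grid.points, [q_low, q_high]) for m in models]


def find_setpoints(
    models: Sequence[QuantileForestModel],
    grid: Grid,
    q_low: float = 0.4,
    q_high: float = 0.6,
) -> List[SetPoint]:
    """Flag grid coordinates whose predicted-change interval contains zero.

    A coordinate qualifies when ``q_low quantile <= 0 <= q_high quantile`` of
    predicted change holds for every model in ``models`` (exact comparisons;
    quantiles are observed training outcomes).
    """
    if not models:
        raise ValueError("at least one model is required")
    if not (q_low < 0.5 < q_high):
        raise ValueError(f"need q_low < 0.5 < q_high, got ({q_low}, {q_high})")
    _check_grid_covers(models, grid)
    intervals = _interval_matrix(models, grid, q_low, q_high)
    mask = np.ones(len(grid), dtype=bool)
    for iv in intervals:
        mask &= (iv[:, 0] <= 0.0) & (0.0 <= iv[:, 1])
    out: List[SetPoint] = []
    coords = grid.points
    idxs = np.flatnonzero(mask)
    for i in idxs:
        out.append(
            SetPoint(
                coordinate={c: float(coords.iloc[i][c]) for c in coords.columns},
                intervals={
                    m.outcome_name: (float(iv[i, 0]), float(iv[i, 1]))
                    for m, iv in zip(models, intervals)
                },
            )
        )
    return out


def setpoints_to_frame(setpoints: Sequence[SetPoint]) -> pd.DataFrame:
    """Tabular view of set points (coordinates, intervals, class, support)."""
    rows = []
    for sp in setpoints:
        row = dict(sp.coordinate)
        for eq, (lo, hi) in sp.intervals.items():
            row[f"{eq}_qlow"] = lo
            row[f"{eq}_qhigh"] = hi
        row["support_count"] = sp.support_count
        row["dynamics_class"] = sp.dynamics_class
        rows.append(row)
    return pd.DataFrame(rows)


def quantile_sweep(
    models: Sequence[QuantileForestModel],
    grid: Grid,
    pairs: Sequence[Tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Count, per grid coordinate, how many quantile pairs flag it.

    Returns the grid coordinates plus a ``support_count`` column in
    ``0..len(pairs)``; by default the 24 even-integer pairs are swept.
    Because quantile intervals are nested in the pair width, support counts
    are highest where even the narrowest interval still contains zero.
    """
    if pairs is None:
        pairs = default_quantile_pairs()
    if not pairs:
        raise ValueError("pairs must be non-empty")
    for lo, hi in pairs:
        if not lo < 0.5 < hi:
            raise ValueError(f"each pair must straddle the median, got ({lo}, {hi})")
    if not models:
        raise ValueError("at least one model is required")
    _check_grid_covers(models, grid)
    # evaluate all needed quantile levels in one pass per model
    levels = sorted({q for pair in pairs for q in pair})
    level_idx = {q: j for j, q in enumerate(levels)}
    support = np.zeros(len(grid), dtype=int)
    per_model = [m.predict_quantiles(grid.points, levels) for m in models]
    for lo, hi in pairs:
        mask = np.ones(len(grid), dtype=bool)
        for Q in per_model:
            mask &= (Q[:, level_idx[lo]] <= 0.0) & (0.0 <= Q[:, level_idx[hi]])
        support += mask
    out = grid.points.copy()
    out["support_count"] = support
    return out
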