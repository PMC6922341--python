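"""Local-dynamics classification around set points.

Two routes are provided.  The probe route perturbs one modeled dimension at
a time by a small offset ``delta`` (controls held at the set-point values)
and compares the sign of predicted change below and above the set point:
change toward the point on both sides is attraction, away on both sides is
repulsion, and a shared direction is a transient slowing-down.  The Jacobian
route fits least-squares slopes of predicted change against state offsets on
a small star of probe points; the eigenvalues of the slope matrix give the
standard linear-stability reading (all real parts negative: attracting; all
positive: repelling; mixed: saddle; dominant imaginary parts: rotation,
i.e. cycling).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .forest import QuantileForestModel
from .setpoints import SetPoint

__all__ = [
    "ProbeResult",
    "JacobianEstimate",
    "classify_setpoint",
    "classify_setpoints",
    "estimate_jacobian",
    "count_by_class",
]

CLASSES = ("attractor", "repeller", "transient", "cycle", "unclassified")


@dataclass(frozen=True)
class ProbeResult:
    """Per-dimension probe outcomes and the combined dynamics label."""

    setpoint: SetPoint
    delta: float
    below_change: Dict[str, float]
    above_change: Dict[str, float]
    label: str


@dataclass(frozen=True)
class JacobianEstimate:
    """Least-squares slope matrix of predicted change around a set point."""

    matrix: np.ndarray
    eigenvalues: np.ndarray

    @property
    def label(self) -> str:
        """Eigenvalue-based stability reading.

        Rotation is called only when the imaginary parts dominate the real
        parts: least-squares slopes on forest predictions always carry a
        small spurious imaginary component, so any-nonzero-imaginary would
        misread noisy point attractors as cycles.
        """
        re = self.eigenvalues.real
        im = self.eigenvalues.imag
        if np.max(np.abs(im)) > 0.5 * np.max(np.abs(re)):
            return "cycle"
        if np.all(re < 0):
            return "attractor"
        if np.all(re > 0):
            return "repeller"
        return "saddle"


def _dim_label(below: float, above: float) -> str:
    if below > 0 and above < 0:
        return "attractor"
    if below < 0 and above > 0:
        return "repeller"
    # same-sign predicted change on both sides, or an exact zero: the point
    # slows the flow but is not topologically stable
    return "transient"


def _probe_frames(sp: SetPoint, model: QuantileForestModel, channel: str, delta: float):
    base = {p: sp.coordinate[p] for p in model.predictor_names}
    below = dict(base)
    below[channel] -= delta
    above = dict(base)
    above[channel] += delta
    return pd.DataFrame([below]), pd.DataFrame([above])


def _check_delta(delta: float, grid_step: float | None) -> None:
    if delta <= 0:
        raise ValueError(f"probe delta must be positive, got {delta}")
    if grid_step is not None and not (0.5 * grid_step <= delta <= grid_step):
        warnings.warn(
            f"probe delta {delta} outside the recommended half-to-whole grid "
            f"step range [{0.5 * grid_step}, {grid_step}]",
            stacklevel=3,
        )


def classify_setpoint(
    models: Sequence[QuantileForestModel],
    setpoint: SetPoint,
    delta: float = 0.05,
    grid_step: float | None = None,
) -> ProbeResult:
    """Classify one set point by probing each modeled dimension at ±delta.

    For multi-equation systems the per-dimension labels are combined:
    attraction (repulsion) in every dimension yields ``attractor``
    (``repeller``); any mixture yields ``transient`` (a saddle-like or
    partially stable point).  For two or more dimensions the Jacobian
    eigenvalue route (:func:`estimate_jacobian`) is the sharper instrument,
    in particular for rotation.
    """
    _check_delta(delta, grid_step)
    below: Dict[str, float] = {}
    above: Dict[str, float] = {}
    labels: List[str] = []
    for model in models:
        channel = _modeled_channel(model)
        lo_pts, hi_pts = _probe_frames(setpoint, model, channel, delta)
        _warn_if_outside_range(model, lo_pts, hi_pts, channel)
        lo = float(model.predict_mean(lo_pts)[0])
        hi = float(model.predict_mean(hi_pts)[0])
        below[channel] = lo
        above[channel] = hi
        labels.append(_dim_label(lo, hi))
    if all(l == "attractor" for l in labels):
        label = "attractor"
    elif all(l == "repeller" for l in labels):
        label = "repeller"
    else:
        label = "transient"
    return ProbeResult(
        setpoint=setpoint, delta=delta, below_change=below, above_change=above, label=label
    )


def _modeled_channel(model: QuantileForestModel) -> str:
    name = model.outcome_name
    return name[2:] if name.startswith("d_") else name


def _warn_if_outside_range(model, lo_pts, hi_pts, channel) -> None:
    col = model.predictor_names.index(channel)
    tmin = model._X_train[:, col].min()
    tmax = model._X_train[:, col].max()
    for pts in (lo_pts, hi_pts):
        v = float(pts[channel].iloc[0])
        if v < tmin or v > tmax:
            warnings.warn(
                f"probe value {v:.4g} on {channel!r} lies outside the model's "
                f"training range [{tmin:.4g}, {tmax:.4g}]",
                stacklevel=4,
            )


def classify_setpoints(
    models: Sequence[QuantileForestModel],
    setpoints: Sequence[SetPoint],
    delta: float = 0.05,
    grid_step: float | None = None,
) -> List[ProbeResult]:
    """Vectorized probe classification of many set points at once."""
    if not setpoints:
        return []
    _check_delta(delta, grid_step)
    n = len(setpoints)
    per_model = []
    for model in models:
        channel = _modeled_channel(model)
        base = pd.DataFrame(
            [[sp.coordinate[p] for p in model.predictor_names] for sp in setpoints],
            columns=list(model.predictor_names),
        )
        lo_pts = base.copy()
        lo_pts[channel] -= delta
        hi_pts = base.copy()
        hi_pts[channel] += delta
        lo = model.predict_mean(lo_pts)
        hi = model.predict_mean(hi_pts)
        per_model.append((channel, lo, hi))
    results: List[ProbeResult] = []
    for i in range(n):
        below = {ch: float(lo[i]) for ch, lo, _ in per_model}
        above = {ch: float(hi[i]) for ch, _, hi in per_model}
        labels = [_dim_label(below[ch], above[ch]) for ch, _, _ in per_model]
        if all(l == "attractor" for l in labels):
            label = "attractor"
        elif all(l == "repeller" for l in labels):
            label = "repeller"
        else:
            label = "transient"
        results.append(
            ProbeResult(
                setpoint=setpoints[i],
                delta=delta,
                below_change=below,
                above_change=above,
                label=label,
            )
        )
    return results


def estimate_jacobian(
    models: Sequence[QuantileForestModel],
    setpoint: SetPoint,
    delta: float = 0.05,
) -> JacobianEstimate:
    """Estimate the d×d slope matrix of predicted change around a set point.

    Probes the 2d+1 star of points (center plus ±delta along each modeled
    dimension, controls held fixed) and regresses each model's predicted
    change on the state offsets.  Eigenvalues of the resulting matrix carry
    the stability classification (see :class:`JacobianEstimate`).
    """
    if delta <= 0:
        raise ValueError(f"probe delta must be positive, got {delta}")
    channels = [_modeled_channel(m) for m in models]
    d = len(channels)
    # star design: center + axis offsets
    offsets = [np.zeros(d)]
    for j in range(d):
        for s in (-1.0, 1.0):
            v = np.zeros(d)
            v[j] = s * delta
            offsets.append(v)
    offsets = np.array(offsets)
    J = np.zeros((d, d))
    X = np.column_stack([np.ones(len(offsets)), offsets])
    for i, model in enumerate(models):
        rows = []
        for off in offsets:
            pt = {p: setpoint.coordinate[p] for p in model.predictor_names}
            for j, ch in enumerate(channels):
                if ch in pt:
                    pt[ch] += off[j]
            rows.append(pt)
        preds = model.predict_mean(pd.DataFrame(rows))
        coef, *_ = np.linalg.lstsq(X, preds, rcond=None)
        J[i, :] = coef[1:]
    eig = np.linalg.eigvals(J)
    return JacobianEstimate(matrix=J, eigenvalues=eig)


def count_by_class(probes: Sequence[ProbeResult]) -> Dict[str, int]:
    """Totals per dynamics class (all classes present in the mapping)."""
    counts = Counter(p.label for p in probes)
    return {c: counts.get(c, 0) for c in CLASSES}
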