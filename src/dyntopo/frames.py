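"""Difference-equation regression frames.

Turns aligned multivariate time series into the supervised-learning layout
``Y[t+1] - Y[t] = F(Y[t], C[t])``: one outcome column per modeled channel
holding the lead-minus-current difference, predictors holding the current
values of the modeled channels and any control channels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = ["DiffFrame", "make_diff_frame", "split_frame", "outcome_name"]


def outcome_name(channel: str) -> str:
    """Column name used for the difference outcome of ``channel``."""
    return f"d_{channel}"


@dataclass(frozen=True)
class DiffFrame:
    """Aligned (current state, controls, next-minus-current change) rows.

    ``data`` has one row per time index ``t`` in ``0..n-2``; column
    ``d_<ch>`` holds ``ch[t+1] - ch[t]`` while ``<ch>`` itself holds the
    current value.  Differences are stored at the index of the *current*
    observation.
    """

    data: pd.DataFrame
    channel_names: Tuple[str, ...]
    control_names: Tuple[str, ...]

    @property
    def predictor_names(self) -> Tuple[str, ...]:
        return self.channel_names + self.control_names

    @property
    def outcome_names(self) -> Tuple[str, ...]:
        return tuple(outcome_name(c) for c in self.channel_names)

    def __len__(self) -> int:
        return len(self.data)


def make_diff_frame(
    series: pd.DataFrame,
    modeled: Sequence[str],
    controls: Sequence[str] = (),
) -> DiffFrame:
    """Build a :class:`DiffFrame` from a table of aligned channels.

    Parameters
    ----------
    series : pandas.DataFrame
        One column per channel, rows in time order.
    modeled : sequence of str
        Channels whose change is treated as an outcome (their current value
        is also always a predictor).
    controls : sequence of str
        Additional channels used only as predictors (control parameters).

    Raises
    ------
    ValueError
        On overlapping modeled/control sets, missing columns, missing values,
        or fewer than two rows.
    """
    modeled = list(modeled)
    controls = list(controls)
    if not modeled:
        raise ValueError("at least one modeled channel is required")
    overlap = set(modeled) & set(controls)
    if overlap:
        raise ValueError(f"channels cannot be both modeled and control: {sorted(overlap)}")
    used = modeled + controls
    missing = [c for c in used if c not in series.columns]
    if missing:
        raise ValueError(f"columns not found in series: {missing}")
    if len(series) < 2:
        raise ValueError("need at least 2 observations to form differences")
    sub = series[used]
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any()].tolist()
        raise ValueError(f"missing values in columns {bad}; impute or drop before framing")

    data = {}
    for c in used:
        data[c] = sub[c].to_numpy()[:-1]
    for c in modeled:
        vals = sub[c].to_numpy()
        data[outcome_name(c)] = vals[1:] - vals[:-1]
    frame = pd.DataFrame(data)
    frame.index = np.arange(len(frame))
    return DiffFrame(data=frame, channel_names=tuple(modeled), control_names=tuple(controls))


def split_frame(
    frame: DiffFrame,
    fraction: float = 0.5,
    seed: int = 0,
    contiguous: bool = False,
) -> Tuple[DiffFrame, DiffFrame]:
    """Partition a frame into train/test subsets.

    ``fraction`` is the share of rows assigned to the training part.  The
    default draws rows uniformly at random without replacement; with
    ``contiguous=True`` the first ``fraction`` block (in time order) trains,
    guarding against temporal leakage.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    n = len(frame)
    if n == 0:
        raise ValueError("cannot split an empty frame")
    n_train = int(round(n * fraction))
    n_train = min(max(n_train, 1), n - 1) if n > 1 else n_train
    if contiguous:
        train_idx = np.arange(n_train)
        test_idx = np.arange(n_train, n)
    else:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        train_idx = np.sort(perm[:n_train])
        test_idx = np.sort(perm[n_train:])

    def take(idx: np.ndarray) -> DiffFrame:
        return DiffFrame(
            data=frame.data.iloc[idx].reset_index(drop=True),
            channel_names=frame.channel_names,
            control_names=frame.control_names,
        )

    return take(train_idx), take(test_idx)
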