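"""Delimited time-series readers, set-point tables, and fit-quality reports.

Sensor logs come in many delimited flavors (comma, tab, whitespace; with or
without a header).  :func:`read_timeseries` autodetects the delimiter and
lets channels be addressed either by header name or by 0-based column index,
which covers headerless accelerometer logs directly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression
from sklearn.metrics import r2_score

from .forest import QuantileForestModel
from .frames import DiffFrame
from .setpoints import SetPoint, setpoints_to_frame

__all__ = [
    "read_timeseries",
    "write_setpoints",
    "read_setpoints",
    "report_r2_table",
]

ColumnKey = Union[str, int]


def read_timeseries(
    path: Union[str, Path],
    columns: Mapping[str, ColumnKey],
    header: Union[str, bool] = "auto",
    delimiter: Optional[str] = None,
) -> pd.DataFrame:
    """Read named channels out of a delimited text file.

    Parameters
    ----------
    path : path
        Comma-, tab- or whitespace-delimited text file.
    columns : mapping
        Output channel name → source column, given either as a header name
        (str) or a 0-based column index (int).  A key named ``"activity"``
        is kept as a label column; all other channels must be numeric.
    header : "auto" | True | False
        Whether the first row is a header.  ``"auto"`` treats the first row
        as a header when any referenced column key is a string, or when the
        first row is non-numeric.
    delimiter : str, optional
        Explicit delimiter; autodetected when omitted (whitespace runs count
        as one delimiter).

    Raises
    ------
    ValueError
        If a referenced column is absent, or a numeric channel contains a
        non-numeric entry (reported with its 1-based line number).
    """
    path = Path(path)
    wants_names = any(isinstance(k, str) for k in columns.values())
    if header == "auto":
        header = wants_names or _first_row_nonnumeric(path, delimiter)
    read_kwargs: Dict = dict(header=0 if header else None, dtype=str, comment=None)
    if delimiter is None:
        read_kwargs.update(sep=None, engine="python")
    elif delimiter.strip() == "":
        read_kwargs.update(sep=r"\s+")
    else:
        read_kwargs.update(sep=delimiter)
    raw = pd.read_csv(path, **read_kwargs)
    out = {}
    header_offset = 2 if header else 1  # 1-based data line numbers in the file
    for name, key in columns.items():
        if isinstance(key, int):
            if key < 0 or key >= raw.shape[1]:
                raise ValueError(
                    f"column index {key} out of range for {path.name} "
                    f"({raw.shape[1]} columns)"
                )
            col = raw.iloc[:, key]
        else:
            if key not in raw.columns:
                raise ValueError(
                    f"column {key!r} not found in {path.name} header "
                    f"{list(raw.columns)}"
                )
            col = raw[key]
        if name == "activity":
            out[name] = col.astype(str).to_numpy()
            continue
        numeric = pd.to_numeric(col, errors="coerce")
        bad = numeric.isna() & col.notna() & (col.astype(str).str.strip() != "")
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + header_offset
            raise ValueError(
                f"non-numeric value {col[bad].iloc[0]!r} for channel {name!r} "
                f"at line {line} of {path.name}"
            )
        out[name] = numeric.to_numpy(dtype=float)
    return pd.DataFrame(out)


def _first_row_nonnumeric(path: Path, delimiter: Optional[str]) -> bool:
    with open(path) as fh:
        first = fh.readline()
    if delimiter and delimiter.strip():
        tokens = first.strip().split(delimiter)
    elif "," in first:
        tokens = first.strip().split(",")
    elif "\t" in first:
        tokens = first.strip().split("\t")
    else:
        tokens = first.split()
    for tok in tokens:
        try:
            float(tok)
        except ValueError:
            return True
    return False


def write_setpoints(
    setpoints: Union[Sequence[SetPoint], pd.DataFrame], path: Union[str, Path]
) -> None:
    """Write set points (list or tabular form) as CSV."""
    frame = setpoints if isinstance(setpoints, pd.DataFrame) else setpoints_to_frame(setpoints)
    frame.to_csv(path, index=False)


def read_setpoints(path: Union[str, Path]) -> pd.DataFrame:
    """Read a set-point CSV back into tabular form (lossless round trip)."""
    return pd.read_csv(path)


def report_r2_table(
    train: DiffFrame,
    test: DiffFrame,
    models: Sequence[QuantileForestModel],
) -> pd.DataFrame:
    """Train/validation R² of each forest against a least-squares baseline.

    The baseline for each outcome is an OLS regression on the same current
    values the forest uses.  Rows are indexed by modeled channel; columns are
    ``(ls|rf)_(train|validation)``.
    """
    rows = {}
    predictors = list(train.predictor_names)
    for model in models:
        outcome = model.outcome_name
        channel = outcome[2:] if outcome.startswith("d_") else outcome
        Xtr = train.data[predictors].to_numpy(dtype=float)
        ytr = train.data[outcome].to_numpy(dtype=float)
        Xte = test.data[predictors].to_numpy(dtype=float)
        yte = test.data[outcome].to_numpy(dtype=float)
        ols = LinearRegression().fit(Xtr, ytr)
        rows[channel] = {
            "ls_train": r2_score(ytr, ols.predict(Xtr)),
            "rf_train": r2_score(ytr, model.predict_mean(Xtr)),
            "ls_validation": r2_score(yte, ols.predict(Xte)),
            "rf_validation": r2_score(yte, model.predict_mean(Xte)),
        }
    return pd.DataFrame(rows).T
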