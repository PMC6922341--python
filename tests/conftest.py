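import numpy as np
import pandas as pd
import pytest

from dyntopo import ForestParams, fit_forest, make_diff_frame


def frame_from_map(f, y_values):
    """DiffFrame whose outcome column is exactly f(y) at each grid value.

    Builds a synthetic single-channel series table whose lead-minus-current
    difference equals f(y); used to hand the forest a known generating field.
    """
    y = np.asarray(y_values, dtype=float)
    df = pd.DataFrame({"y": y})
    frame = make_diff_frame(df, modeled=["y"])
    # overwrite the mechanical differences with the analytic field
    frame.data["d_y"] = f(frame.data["y"].to_numpy())
    return frame


@pytest.fixture(scope="session")
def small_params():
    """Cheap forest hyperparameters for unit tests."""
    return ForestParams(n_trees=50, min_leaf_size=5, seed=0)


@pytest.fixture(scope="session")
def decay_model(small_params):
    """Forest fitted to the contraction field dy = -y + noise on y in [-1, 1].

    Noise SD 0.2 makes the conditional 40-60% quantile band (~±0.05) span
    the field's change across one 0.05 grid step, so the interval rule can
    flag a cluster of set points around the fixed point at the origin.
    """
    rng = np.random.default_rng(0)
    y = rng.uniform(-1, 1, 400)
    frame = frame_from_map(lambda v: -v + rng.normal(0, 0.2, len(v)), y)
    return fit_forest(frame, "d_y", small_params)


@pytest.fixture(scope="session")
def growth_model(small_params):
    """Forest fitted to the expansion field dy = +y + noise on y in [-1, 1]."""
    rng = np.random.default_rng(1)
    y = rng.uniform(-1, 1, 400)
    frame = frame_from_map(lambda v: v + rng.normal(0, 0.2, len(v)), y)
    return fit_forest(frame, "d_y", small_params)
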