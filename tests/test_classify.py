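import numpy as np
import pandas as pd
import pytest

from dyntopo import (
    ForestParams,
    SetPoint,
    classify_setpoint,
    classify_setpoints,
    count_by_class,
    estimate_jacobian,
    fit_forest,
    make_diff_frame,
)
from conftest import frame_from_map


def origin(**coords):
    return SetPoint(coordinate=coords, intervals={})


def two_channel_models(fx, fy, n=800, noise=0.05, seed=0):
    """Forests for a known planar field (dx, dy) = (fx(x,y), fy(x,y))."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({"x": rng.uniform(-1, 1, n), "y": rng.uniform(-1, 1, n)})
    frame = make_diff_frame(df, modeled=["x", "y"])
    X = frame.data["x"].to_numpy()
    Y = frame.data["y"].to_numpy()
    frame.data["d_x"] = fx(X, Y) + rng.normal(0, noise, len(X))
    frame.data["d_y"] = fy(X, Y) + rng.normal(0, noise, len(X))
    params = ForestParams(n_trees=100, seed=0)
    return [fit_forest(frame, "d_x", params), fit_forest(frame, "d_y", params)]


class TestProbeRoute:
    def test_contraction_is_attractor(self, decay_model):
        res = classify_setpoint([decay_model], origin(y=0.0), delta=0.2)
        assert res.label == "attractor"
        assert res.below_change["y"] > 0 > res.above_change["y"]
        assert res.delta == 0.2

    def test_expansion_is_repeller(self, growth_model):
        res = classify_setpoint([growth_model], origin(y=0.0), delta=0.2)
        assert res.label == "repeller"
        assert res.below_change["y"] < 0 < res.above_change["y"]

    def test_constant_drift_is_transient(self, small_params):
        frame = frame_from_map(lambda v: np.full(len(v), 0.25), np.linspace(-1, 1, 80))
        model = fit_forest(frame, "d_y", small_params)
        res = classify_setpoint([model], origin(y=0.0), delta=0.2)
        assert res.label == "transient"

    def test_exactly_zero_field_is_transient(self, small_params):
        frame = frame_from_map(lambda v: np.zeros(len(v)), np.linspace(-1, 1, 80))
        model = fit_forest(frame, "d_y", small_params)
        res = classify_setpoint([model], origin(y=0.0), delta=0.2)
        assert res.label == "transient"

    def test_planar_contraction_is_attractor(self):
        models = two_channel_models(lambda x, y: -x, lambda x, y: -y)
        res = classify_setpoint(models, origin(x=0.0, y=0.0), delta=0.2)
        assert res.label == "attractor"

    def test_planar_saddle_is_transient(self):
        # attracting in x, repelling in y: probe labels disagree
        models = two_channel_models(lambda x, y: -x, lambda x, y: y)
        res = classify_setpoint(models, origin(x=0.0, y=0.0), delta=0.2)
        assert res.label == "transient"

    def test_vectorized_matches_single(self, decay_model, growth_model):
        sps = [origin(y=v) for v in (-0.4, 0.0, 0.4)]
        for model in (decay_model, growth_model):
            batch = classify_setpoints([model], sps, delta=0.2)
            singles = [classify_setpoint([model], sp, delta=0.2) for sp in sps]
            assert [b.label for b in batch] == [s.label for s in singles]
            for b, s in zip(batch, singles):
                assert b.below_change == s.below_change
                assert b.above_change == s.above_change

    def test_empty_input_gives_empty_output(self, decay_model):
        assert classify_setpoints([decay_model], []) == []

    def test_invalid_delta_raises(self, decay_model):
        with pytest.raises(ValueError, match="delta"):
            classify_setpoint([decay_model], origin(y=0.0), delta=0.0)
        with pytest.raises(ValueError, match="delta"):
            classify_setpoints([decay_model], [origin(y=0.0)], delta=-0.1)

    def test_delta_outside_grid_step_range_warns(self, decay_model):
        with pytest.warns(UserWarning, match="grid"):
            classify_setpoint([decay_model], origin(y=0.0), delta=0.2, grid_step=0.05)

    def test_probe_outside_training_range_warns(self, decay_model):
        with pytest.warns(UserWarning, match="training range"):
            classify_setpoint([decay_model], origin(y=1.5), delta=0.2)


class TestJacobianRoute:
    def test_one_dim_contraction(self, decay_model):
        est = estimate_jacobian([decay_model], origin(y=0.0), delta=0.2)
        assert est.matrix.shape == (1, 1)
        assert est.eigenvalues[0].real < 0
        assert est.label == "attractor"

    def test_one_dim_expansion(self, growth_model):
        est = estimate_jacobian([growth_model], origin(y=0.0), delta=0.2)
        assert est.eigenvalues[0].real > 0
        assert est.label == "repeller"

    def test_rotation_field_is_cycle(self):
        # dx = -0.3x - y, dy = x - 0.3y: eigenvalues -0.3 +/- i
        models = two_channel_models(lambda x, y: -0.3 * x - y, lambda x, y: x - 0.3 * y)
        est = estimate_jacobian(models, origin(x=0.0, y=0.0), delta=0.2)
        assert est.matrix.shape == (2, 2)
        assert np.all(np.abs(est.eigenvalues.imag) > 0.1)
        assert est.label == "cycle"
        # off-diagonal structure of the rotation survives the forest smoothing
        assert est.matrix[0, 1] < 0 < est.matrix[1, 0]

    def test_saddle_field_is_saddle(self):
        models = two_channel_models(lambda x, y: x, lambda x, y: -y)
        est = estimate_jacobian(models, origin(x=0.0, y=0.0), delta=0.2)
        assert est.label == "saddle"
        assert est.eigenvalues.real.min() < 0 < est.eigenvalues.real.max()

    def test_planar_contraction_eigenvalues_negative(self):
        models = two_channel_models(lambda x, y: -x, lambda x, y: -y)
        est = estimate_jacobian(models, origin(x=0.0, y=0.0), delta=0.2)
        assert est.label == "attractor"
        assert np.all(est.eigenvalues.real < 0)

    def test_invalid_delta_raises(self, decay_model):
        with pytest.raises(ValueError, match="delta"):
            estimate_jacobian([decay_model], origin(y=0.0), delta=0.0)


class TestCounting:
    def test_count_by_class_totals_and_keys(self, decay_model, growth_model):
        # only y=0 is a fixed point of the decay field: three copies of it
        probes = classify_setpoints([decay_model], [origin(y=0.0)] * 3, delta=0.2)
        probes += classify_setpoints([growth_model], [origin(y=0.0)], delta=0.2)
        counts = count_by_class(probes)
        assert set(counts) == {"attractor", "repeller", "transient", "cycle", "unclassified"}
        assert sum(counts.values()) == 4
        assert counts["attractor"] == 3
        assert counts["repeller"] == 1

    def test_empty_counts_are_zero(self):
        assert all(v == 0 for v in count_by_class([]).values())
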