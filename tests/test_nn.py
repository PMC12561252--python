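import numpy as np
import pytest

import tearmap as tm
from tearmap.nn import (
    TrainOptions,
    _forward_scaled,
    _jacobian_scaled,
    fit_scaler,
)


def _realizable_problem(arch=(1, 4, 6, 10), n=30, gen_seed=9, scale=0.5):
    """Targets generated by a fixed random model of the same architecture."""
    gen = tm.init_model(arch, seed=gen_seed)
    for w in gen.weights:
        w *= scale
    for b in gen.biases:
        b *= scale
    X = np.linspace(10, 180, n)
    gen.input_scaler = fit_scaler(X.reshape(-1, 1))
    Y = _forward_scaled(gen, gen.input_scaler.apply(X.reshape(-1, 1)))
    return X, Y


class TestScaler:
    def test_linear_map(self):
        s = tm.fit_scaler(np.array([0.0, 10.0]))
        assert s.apply(np.array([[0.0], [10.0], [5.0]])).ravel() == pytest.approx(
            [-1.0, 1.0, 0.0])

    def test_degenerate_variable(self):
        s = tm.fit_scaler(np.array([3.0, 3.0]))
        assert s.apply(np.array([[3.0]]))[0, 0] == 0.0
        assert s.invert(np.array([[0.0]]))[0, 0] == 3.0

    def test_round_trip(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(-5, 5, (20, 4))
        s = tm.fit_scaler(x)
        assert np.allclose(s.invert(s.apply(x)), x, atol=1e-12)


class TestSplit:
    @pytest.mark.parametrize("n,expected", [(100, (70, 15, 15)),
                                            (92, (64, 14, 14))])
    def test_sizes(self, n, expected):
        s = tm.split_data(n, rng=0)
        assert (s.train.size, s.val.size, s.test.size) == expected

    def test_partition_property(self):
        s = tm.split_data(53, rng=4)
        all_idx = np.concatenate([s.train, s.val, s.test])
        assert sorted(all_idx.tolist()) == list(range(53))

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            tm.split_data(5)


class TestModel:
    def test_seeded_init_reproducible(self):
        a = tm.init_model((1, 5, 8, 121), seed=3)
        b = tm.init_model((1, 5, 8, 121), seed=3)
        c = tm.init_model((1, 5, 8, 121), seed=4)
        assert np.array_equal(a.pack(), b.pack())
        assert not np.array_equal(a.pack(), c.pack())

    def test_reference_architecture_parameter_count(self):
        # (1*5+5) + (5*8+8) + (8*121+121) = 10 + 48 + 1089
        assert tm.init_model((1, 5, 8, 121), seed=0).n_params == 1147

    def test_zero_weight_model_outputs_scaler_midpoint(self):
        m = tm.init_model((1, 3, 4), seed=0)
        for w in m.weights:
            w[:] = 0.0
        for b in m.biases:
            b[:] = 0.0
        m.input_scaler = tm.fit_scaler(np.array([0.0, 100.0]))
        m.output_scaler = tm.MinMaxScaler(mins=np.array([0.1] * 4),
                                          maxs=np.array([0.5] * 4))
        out = tm.forward(m, [40.0])
        assert np.allclose(out, 0.3)  # midpoint of [0.1, 0.5]

    def test_hand_computed_forward_pass(self):
        """(1,1,1) net: y = w2 tanh(w1 x + b1) + b2, checked by hand."""
        m = tm.init_model((1, 1, 1), seed=0)
        m.weights[0][:] = 0.7
        m.biases[0][:] = -0.2
        m.weights[1][:] = 1.5
        m.biases[1][:] = 0.1
        out = _forward_scaled(m, np.array([[0.4]]))
        assert out[0, 0] == pytest.approx(1.5 * np.tanh(0.7 * 0.4 - 0.2) + 0.1,
                                          abs=1e-15)

    def test_batch_rows_identical_for_identical_inputs(self):
        m = tm.init_model((1, 6, 9), seed=1)
        m.input_scaler = tm.fit_scaler(np.array([0.0, 50.0]))
        m.output_scaler = tm.MinMaxScaler(mins=np.zeros(9), maxs=np.ones(9))
        out = tm.forward(m, [20.0, 20.0, 20.0])
        assert np.array_equal(out[0], out[1]) and np.array_equal(out[1], out[2])

    def test_nonfinite_input_rejected(self):
        m = tm.init_model((1, 2, 2), seed=0)
        with pytest.raises(ValueError):
            tm.forward(m, [np.nan])

    def test_json_round_trip(self):
        m = tm.init_model((1, 5, 8, 121), seed=5)
        m.input_scaler = tm.fit_scaler(np.array([10.0, 180.0]))
        m.output_scaler = tm.MinMaxScaler(mins=np.zeros(121), maxs=np.ones(121))
        back = tm.MLPModel.from_json_dict(m.to_json_dict())
        assert np.array_equal(back.pack(), m.pack())
        assert np.array_equal(back.input_scaler.mins, m.input_scaler.mins)


class TestJacobian:
    @pytest.mark.parametrize("arch", [(1, 3, 2), (1, 4, 6, 10), (1, 2, 2, 2, 3)])
    def test_matches_central_differences(self, arch):
        m = tm.init_model(arch, seed=3)
        xs = np.random.default_rng(0).uniform(-1, 1, (5, 1))
        _, J = _jacobian_scaled(m, xs)
        w0 = m.pack()
        eps = 1e-6
        for k in range(0, w0.size, max(1, w0.size // 40)):
            wp, wm = w0.copy(), w0.copy()
            wp[k] += eps
            wm[k] -= eps
            m.unpack(wp)
            yp = _forward_scaled(m, xs)
            m.unpack(wm)
            ym = _forward_scaled(m, xs)
            fd = ((yp - ym) / (2 * eps)).ravel()
            assert np.abs(J[:, k] - fd).max() < 1e-5 * max(1.0, np.abs(fd).max())
        m.unpack(w0)


class TestTrainLM:
    def test_accepted_costs_strictly_decreasing(self):
        X, Y = _realizable_problem()
        split = tm.split_data(len(X), rng=1)
        _, rec = tm.train_lm(tm.init_model((1, 4, 6, 10), seed=0), X, Y, split,
                             TrainOptions(max_epochs=40, patience=40))
        costs = rec.cost_trajectory
        assert all(b < a for a, b in zip(costs, costs[1:]))

    def test_realizable_targets_fit_to_machine_precision(self):
        X, Y = _realizable_problem()
        split = tm.split_data(len(X), rng=1)
        _, rec = tm.train_lm(tm.init_model((1, 4, 6, 10), seed=0), X, Y, split,
                             TrainOptions(max_epochs=200, patience=200))
        assert min(rec.train_rmse) < 1e-6

    def test_linear_target_matches_least_squares(self):
        """(1,1,1) net on noisy linear data reaches the normal-equations optimum."""
        rng = np.random.default_rng(2)
        X = np.linspace(0, 10, 40)
        Y = (2.0 * X + 1.0 + rng.normal(0, 0.3, 40)).reshape(-1, 1)
        split = tm.SplitIndices(train=np.arange(40), val=np.arange(0),
                                test=np.arange(0))
        model, rec = tm.train_lm(tm.init_model((1, 1, 1), seed=1), X, Y, split,
                                 TrainOptions(max_epochs=400, patience=400))
        xs = model.input_scaler.apply(X.reshape(-1, 1)).ravel()
        ys = model.output_scaler.apply(Y).ravel()
        A = np.column_stack([xs, np.ones_like(xs)])
        coef, _, _, _ = np.linalg.lstsq(A, ys, rcond=None)
        mse_ls = np.mean((A @ coef - ys) ** 2)
        mse_net = np.mean((_forward_scaled(model, xs.reshape(-1, 1)).ravel() - ys) ** 2)
        assert mse_net <= mse_ls * (1 + 1e-3)

    def test_best_validation_weights_returned(self):
        X, Y = _realizable_problem(n=40)
        Y = Y + np.random.default_rng(3).normal(0, 0.05, Y.shape)
        split = tm.split_data(len(X), rng=2)
        model, rec = tm.train_lm(tm.init_model((1, 4, 6, 10), seed=0), X, Y,
                                 split, TrainOptions(max_epochs=60))
        returned_val = np.sqrt(np.mean(
            (tm.forward(model, X[split.val]) - Y[split.val]) ** 2))
        assert returned_val == pytest.approx(min(rec.val_rmse), abs=1e-9)

    def test_scaling_equivariance(self):
        """Affinely rescaling inputs/outputs leaves original-scale predictions unchanged."""
        X, Y = _realizable_problem(n=25)
        split = tm.split_data(len(X), rng=1)
        opts = TrainOptions(max_epochs=30, patience=30)
        m1, _ = tm.train_lm(tm.init_model((1, 4, 6, 10), seed=2), X, Y, split, opts)
        m2, _ = tm.train_lm(tm.init_model((1, 4, 6, 10), seed=2),
                            3.0 * X + 7.0, 0.5 * Y - 2.0, split, opts)
        p1 = tm.forward(m1, X)
        p2 = (tm.forward(m2, 3.0 * X + 7.0) + 2.0) / 0.5
        assert np.allclose(p1, p2, atol=1e-6)


class TestGridSearch:
    def test_single_config(self):
        X, Y = _realizable_problem(n=20)
        split = tm.split_data(len(X), rng=1)
        gs = tm.grid_search(X, Y, split, depths=[2], widths=[8], seed=0,
                            opts=TrainOptions(max_epochs=5, patience=5))
        assert len(gs.records) == 1
        assert gs.selected == gs.records[0]

    def test_selection_is_argmin_with_tiebreaks(self):
        X, Y = _realizable_problem(n=20)
        split = tm.split_data(len(X), rng=1)
        gs = tm.grid_search(X, Y, split, depths=[1, 2], widths=[4, 8], seed=0,
                            opts=TrainOptions(max_epochs=4, patience=4))
        best = min(gs.records,
                   key=lambda r: (r["val_rmse"], r["n_params"], r["depth"]))
        assert gs.selected == best


class TestPredictMapAndEvaluate:
    def test_constant_pivots_give_constant_map(self):
        grid = tm.make_standard_grid(5.0, 20, 60)
        layout = tm.build_pivot_layout("OD", 5.0)
        m = tm.init_model((1, 2, 121), seed=0)
        for w in m.weights:
            w[:] = 0.0
        for b in m.biases:
            b[:] = 0.0
        m.input_scaler = tm.fit_scaler(np.array([0.0, 100.0]))
        c = 0.23
        m.output_scaler = tm.MinMaxScaler(mins=np.full(121, c),
                                          maxs=np.full(121, c))
        tfm = tm.predict_map(m, 30.0, layout, grid)
        assert np.allclose(tfm.values[np.isfinite(tfm.values)], c, atol=1e-9)

    def test_deterministic(self):
        grid = tm.make_standard_grid(5.0, 15, 36)
        layout = tm.build_pivot_layout("OD", 5.0)
        m = tm.init_model((1, 3, 121), seed=1)
        m.input_scaler = tm.fit_scaler(np.array([10.0, 180.0]))
        m.output_scaler = tm.MinMaxScaler(mins=np.zeros(121),
                                          maxs=np.full(121, 0.4))
        a = tm.predict_map(m, 55.0, layout, grid)
        b = tm.predict_map(m, 55.0, layout, grid)
        assert np.array_equal(np.nan_to_num(a.values), np.nan_to_num(b.values))

    def test_evaluate_perfect_and_offset_models(self):
        X, Y = _realizable_problem(n=30)
        split = tm.split_data(len(X), rng=1)
        gen = tm.init_model((1, 4, 6, 10), seed=9)
        for w in gen.weights:
            w *= 0.5
        for b in gen.biases:
            b *= 0.5
        gen.input_scaler = fit_scaler(X.reshape(-1, 1))
        gen.output_scaler = tm.MinMaxScaler(mins=np.zeros(10), maxs=np.full(10, 2.0))
        Y_orig = gen.output_scaler.invert(Y)
        ev = tm.evaluate(gen, X, Y_orig, split)
        for part in ("train", "val", "test"):
            assert ev[part]["rmse"] < 1e-12
            assert ev[part]["spearman_r"] == pytest.approx(1.0)
        # constant offset: rmse = |c|, rank correlation unchanged
        ev2 = tm.evaluate(gen, X, Y_orig - 0.05, split)
        assert ev2["test"]["rmse"] == pytest.approx(0.05)
        assert ev2["test"]["spearman_r"] == pytest.approx(1.0)
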