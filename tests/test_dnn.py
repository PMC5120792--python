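"""DNN mapping: initialization, forward pass, CG updates, layer-wise training."""

import numpy as np
import pytest

import emasynth as es
from emasynth import dnn
from emasynth.dnn import (
    DNNModel,
    TrainConfig,
    _flatten,
    _loss_and_grad,
    cg_block_update,
    init_layer,
    mse_loss,
    split_items,
    train_layerwise,
)


def _norm(d):
    return es.Normalizer(np.zeros(d), np.ones(d))


class TestInit:
    def test_sd_is_one_over_fan_in(self):
        rng = np.random.default_rng(0)
        w, b = init_layer(200, 5000, rng)
        assert abs(w.std() - 1.0 / 200) < 0.01 / 200
        assert np.all(b == 0)

    def test_fan_in_one(self):
        rng = np.random.default_rng(1)
        w, _ = init_layer(1, 1_000_000, rng)
        assert abs(w.std() - 1.0) < 0.01


class TestForward:
    def test_zero_weights_give_output_mean(self):
        out_norm = es.Normalizer(np.full(25, 3.5), np.ones(25))
        model = DNNModel(
            weights=[np.zeros((10, 4)), np.zeros((4, 25))],
            biases=[np.zeros(4), np.zeros(25)],
            slope=0.01, in_norm=_norm(2), out_norm=out_norm,
        )
        pred = model.predict(np.random.default_rng(0).normal(size=(7, 2)))
        assert pred.shape == (7, 25)
        assert np.allclose(pred, 3.5)

    def test_single_unit_hand_computation(self):
        # one hidden leaky-ReLU unit: y = w2 * lrelu(w1*x + b1) + b2
        model = DNNModel(
            weights=[np.array([[2.0]]), np.array([[-3.0]])],
            biases=[np.array([0.5]), np.array([1.0])],
            slope=0.1, in_norm=_norm(1), out_norm=_norm(1),
        )
        x = np.array([[1.0], [-1.0]])
        h = np.array([2.5, -1.5])
        h = np.where(h > 0, h, 0.1 * h)
        expected = -3.0 * h + 1.0
        assert np.allclose(model.forward(x).ravel(), expected)

    def test_dimension_mismatch_rejected(self):
        model = DNNModel([np.zeros((4, 2))], [np.zeros(2)], 0.01, _norm(4), _norm(2))
        with pytest.raises(ValueError, match="dim"):
            model.forward(np.zeros((3, 5)))


class TestLoss:
    def test_identities(self):
        assert mse_loss(np.zeros(25), np.zeros(25)) == 0.0
        assert mse_loss(np.ones(25), np.zeros(25)) == 1.0

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(2)
        o, m = rng.normal(size=25), rng.normal(size=25)
        naive = sum((o[i] - m[i]) ** 2 for i in range(25)) / 25
        assert abs(mse_loss(o, m) - naive) < 1e-12

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(3)
        shapes_w = [(3, 4), (4, 2)]
        shapes_b = [(4,), (2,)]
        theta = rng.normal(size=3 * 4 + 4 * 2 + 4 + 2) * 0.5
        x, y = rng.normal(size=(6, 3)), rng.normal(size=(6, 2))
        _, g = _loss_and_grad(theta, shapes_w, shapes_b, 0.01, x, y)
        for i in rng.choice(len(theta), 6, replace=False):
            e = np.zeros_like(theta)
            e[i] = 1e-6
            fp, _ = _loss_and_grad(theta + e, shapes_w, shapes_b, 0.01, x, y)
            fm, _ = _loss_and_grad(theta - e, shapes_w, shapes_b, 0.01, x, y)
            assert abs((fp - fm) / 2e-6 - g[i]) < 1e-5


class TestCgUpdate:
    def test_converges_to_least_squares_on_linear_net(self):
        """A linear (slope=1) single-layer net under squared loss has the
        normal-equations solution as its optimum; repeated CG updates must
        reach it."""
        rng = np.random.default_rng(4)
        x = rng.normal(size=(100, 3))
        w_true = rng.normal(size=(3, 2))
        y = x @ w_true
        shapes_w, shapes_b = [(3, 2)], [(2,)]
        theta = np.zeros(8)
        for _ in range(50):
            theta, _ = cg_block_update(theta, shapes_w, shapes_b, 1.0, x, y)
        xd = np.column_stack([x, np.ones(100)])
        beta, *_ = np.linalg.lstsq(xd, y, rcond=None)
        w_fit = theta[:6].reshape(3, 2)
        b_fit = theta[6:]
        assert np.allclose(w_fit, beta[:3], atol=1e-6)
        assert np.allclose(b_fit, beta[3], atol=1e-6)

    def test_zero_gradient_is_noop(self):
        x = np.zeros((10, 2))
        y = np.zeros((10, 1))
        theta = np.array([1.0, -2.0, 0.0])  # any weights map 0 -> 0 = target
        out, f = cg_block_update(theta, [(2, 1)], [(1,)], 0.01, x, y)
        assert np.array_equal(out, theta) and f == 0.0

    def test_block_loss_never_increases(self):
        rng = np.random.default_rng(5)
        shapes_w, shapes_b = [(4, 8), (8, 3)], [(8,), (3,)]
        theta = rng.normal(size=4 * 8 + 8 * 3 + 8 + 3) * 0.3
        x, y = rng.normal(size=(40, 4)), rng.normal(size=(40, 3))
        f_prev = _loss_and_grad(theta, shapes_w, shapes_b, 0.01, x, y)[0]
        for _ in range(10):
            theta, f = cg_block_update(theta, shapes_w, shapes_b, 0.01, x, y)
            assert f <= f_prev + 1e-12
            f_prev = f


class TestSplit:
    def test_fractions_and_no_leakage(self):
        cfg = TrainConfig(seed=0)
        train, val, test = split_items(100, cfg, np.random.default_rng(0))
        assert len(train) == 90
        assert len(val) == 5 and len(test) == 5
        assert len(set(train) | set(val) | set(test)) == 100

    def test_odd_leftover_goes_to_validation(self):
        cfg = TrainConfig(seed=0)
        train, val, test = split_items(11, cfg, np.random.default_rng(1))
        assert len(train) == 9 and len(val) == 1 and len(test) == 1
        train, val, test = split_items(25, cfg, np.random.default_rng(1))
        # 22/3 leftover: 2 validation, 1 test
        assert len(val) == 2 and len(test) == 1

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            split_items(2, TrainConfig(), np.random.default_rng(0))


@pytest.fixture(scope="module")
def linear_problem():
    """Items whose targets are a fixed linear map of the stacked input
    plus Gaussian noise: the achievable MSE floor is the noise variance."""
    rng = np.random.default_rng(6)
    sigma = 0.3
    w = rng.normal(0, 0.1, (5 * 4, 25))
    items = []
    for _ in range(15):
        x = rng.normal(0, 1, (400, 4))
        y = es.stack_context(x, 4) @ w + sigma * rng.standard_normal((400, 25))
        items.append((x, y))
    return items, sigma


@pytest.fixture(scope="module")
def trained(linear_problem):
    items, _ = linear_problem
    cfg = TrainConfig(hidden=30, n_hidden_layers=3, max_epochs=40,
                      patience_epochs=12, blocks_per_epoch=20, seed=1)
    model, report = train_layerwise(items, cfg)
    return model, report


class TestTrainLayerwise:
    def test_noise_floor_recovery(self, linear_problem, trained):
        items, sigma = linear_problem
        model, report = trained
        floor = float(np.mean(sigma**2 / model.out_norm.sd**2))
        assert report.final_test_mse <= 1.2 * floor

    def test_architecture(self, trained):
        model, _ = trained
        assert model.layer_sizes == [20, 30, 30, 30, 25]

    def test_stagewise_validation_monotonicity(self, trained):
        _, report = trained
        best = [lg["best_val_mse"] for lg in report.layer_log]
        for prev, nxt in zip(best, best[1:]):
            assert nxt <= prev * 1.05

    def test_determinism(self, linear_problem, trained):
        items, _ = linear_problem
        model, report = trained
        cfg = TrainConfig(hidden=30, n_hidden_layers=3, max_epochs=40,
                          patience_epochs=12, blocks_per_epoch=20, seed=1)
        model2, report2 = train_layerwise(items, cfg)
        assert all(np.array_equal(a, b) for a, b in zip(model.weights, model2.weights))
        assert report.final_test_mse == report2.final_test_mse

    def test_early_stopping_and_best_restore(self, trained):
        _, report = trained
        for lg in report.layer_log:
            assert lg["epochs"] - lg["best_epoch"] <= 12  # the patience bound
            assert min(lg["val_history"]) == lg["best_val_mse"]


class TestEvaluate:
    def test_ground_truth_model_and_constant_baseline(self):
        rng = np.random.default_rng(7)
        w = rng.normal(size=(5 * 2, 25))
        x = rng.normal(size=(500, 2))
        y = es.stack_context(x, 4) @ w
        in_norm = es.fit_normalizer(x)
        out_norm = es.fit_normalizer(y)
        # exact linear model expressed as a slope-1 "network"
        sx = es.stack_context(es.apply_normalizer(in_norm, x), 4)
        beta, *_ = np.linalg.lstsq(
            np.column_stack([sx, np.ones(len(sx))]), es.apply_normalizer(out_norm, y),
            rcond=None)
        model = DNNModel([beta[:-1]], [beta[-1]], 1.0, in_norm, out_norm)
        res = es.evaluate_mapping(model, [(x, y)])
        assert res["mse"] < 1e-10
        assert res["mcd_db"] < 1e-4
        # constant predictor scores ~1 on z-scored targets
        const = DNNModel([np.zeros((10, 25))], [np.zeros(25)], 1.0, in_norm, out_norm)
        res_const = es.evaluate_mapping(const, [(x, y)])
        assert 0.9 < res_const["mse"] < 1.1
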