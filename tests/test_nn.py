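"""Autodiff correctness, layer semantics, and the five architectures."""

import numpy as np
import pytest

from hemonet.nn import autograd as ag
from hemonet.nn.autograd import Tensor
from hemonet.nn.architectures import (
    InceptionBlock,
    build_baseline_dnn,
    build_bilstm,
    build_hemo_net,
    build_hybrid,
    build_lstm,
)
from hemonet.nn.layers import BatchNorm, LSTM, LSTMCellWeights, lstm_step
from hemonet.nn.training import TrainingPlan, predict_proba_net, train_deep


def _numeric_grad(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x[i] += eps
        fp = f()
        x[i] -= 2 * eps
        fm = f()
        x[i] += eps
        g[i] = (fp - fm) / (2 * eps)
    return g


class TestAutogradGradients:
    @pytest.mark.parametrize("op_name", ["conv1d", "maxpool", "batchnorm",
                                         "softmax_ce", "concat_flip"])
    def test_matches_numerical_gradient(self, op_name, rng):
        if op_name == "conv1d":
            x = Tensor(rng.normal(size=(2, 3, 9)), requires_grad=True)
            w = Tensor(rng.normal(size=(4, 3, 4)), requires_grad=True)
            b = Tensor(rng.normal(size=4), requires_grad=True)

            def forward():
                o = ag.conv1d_same(x, w, b)
                return ag.sum_(ag.mul(o, o))

            checks = [x, w, b]
        elif op_name == "maxpool":
            x = Tensor(rng.normal(size=(2, 3, 9)), requires_grad=True)

            def forward():
                o = ag.maxpool1d_same(x, 3)
                return ag.sum_(ag.mul(o, o))

            checks = [x]
        elif op_name == "batchnorm":
            bn = BatchNorm(3)
            x = Tensor(rng.normal(size=(5, 3, 7)), requires_grad=True)

            def forward():
                bn.running_mean[:] = 0
                bn.running_var[:] = 1
                o = bn(x, train=True)
                return ag.sum_(ag.mul(o, o))

            checks = [x, bn.gamma, bn.beta]
        elif op_name == "softmax_ce":
            x = Tensor(rng.normal(size=(4, 5)), requires_grad=True)
            labels = np.array([0, 2, 4, 1])

            def forward():
                return ag.softmax_cross_entropy(x, labels)

            checks = [x]
        else:  # concat + time reversal
            x = Tensor(rng.normal(size=(2, 3, 5)), requires_grad=True)
            y = Tensor(rng.normal(size=(2, 2, 5)), requires_grad=True)

            def forward():
                o = ag.concat([x, ag.flip_time(y)], axis=1)
                return ag.sum_(ag.mul(o, o))

            checks = [x, y]

        loss = forward()
        loss.backward()
        grads = [t.grad for t in checks]
        for t, analytic in zip(checks, grads):
            numeric = _numeric_grad(lambda: float(forward().data), t.data)
            assert np.abs(numeric - analytic).max() < 1e-5

    def test_softmax_rows_sum_to_one(self, rng):
        p = ag.softmax(Tensor(rng.normal(size=(6, 5)))).data
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(p > 0)


class TestLSTMStep:
    def test_zero_weights_hand_values(self):
        """All weights/biases 0: gates = 0.5, candidate = 0; canonical cell
        c_t = 0.5 c_{t-1}, a_t = 0.5 tanh(c_t); literal form wraps both in
        sigmoids."""
        rng = np.random.default_rng(0)
        cell = LSTMCellWeights(1, 1, rng)
        cell.Wx.data[:] = 0
        cell.Wa.data[:] = 0
        cell.b.data[:] = 0
        x = Tensor([[0.0]])
        a0 = Tensor([[0.0]])
        c0 = Tensor([[0.6]])

        a, c = lstm_step(x, a0, c0, cell)
        assert c.data[0, 0] == pytest.approx(0.5 * 0.6)
        assert a.data[0, 0] == pytest.approx(0.5 * np.tanh(0.3))

        sig = lambda v: 1.0 / (1.0 + np.exp(-v))
        a, c = lstm_step(x, a0, c0, cell, literal=True)
        assert c.data[0, 0] == pytest.approx(sig(0.5 * 0.6))
        assert a.data[0, 0] == pytest.approx(sig(0.5 * sig(0.5 * 0.6)))

    def test_unit_weights_scalar_chain(self):
        """Weights 1, inputs 0, biases 0, one scalar step: pre-activations
        equal a_prev, so every gate is sigma(a_prev) and the candidate is
        tanh(a_prev)."""
        rng = np.random.default_rng(0)
        cell = LSTMCellWeights(1, 1, rng)
        cell.Wx.data[:] = 1
        cell.Wa.data[:] = 1
        cell.b.data[:] = 0
        a_prev, c_prev = 0.3, -0.2
        a, c = lstm_step(Tensor([[0.0]]), Tensor([[a_prev]]), Tensor([[c_prev]]), cell)
        sig = lambda v: 1.0 / (1.0 + np.exp(-v))
        g = np.tanh(a_prev)
        c_hand = sig(a_prev) * g + sig(a_prev) * c_prev
        assert c.data[0, 0] == pytest.approx(c_hand)
        assert a.data[0, 0] == pytest.approx(sig(a_prev) * np.tanh(c_hand))

    def test_gate_outputs_bounded(self, rng):
        cell = LSTMCellWeights(3, 4, rng)
        x = Tensor(rng.normal(scale=5, size=(6, 3)))
        a, c = lstm_step(x, Tensor(np.zeros((6, 4))), Tensor(np.zeros((6, 4))), cell)
        # canonical activation a_t = o * tanh(c_t) with o in (0,1)
        assert np.all(np.abs(a.data) < 1.0)

    def test_literal_cell_state_bounded_in_unit_interval(self, rng):
        cell = LSTMCellWeights(3, 4, rng)
        x = Tensor(rng.normal(scale=5, size=(6, 3)))
        a, c = lstm_step(x, Tensor(np.zeros((6, 4))), Tensor(np.zeros((6, 4))),
                         cell, literal=True)
        assert np.all((c.data > 0) & (c.data < 1))
        assert np.all((a.data > 0) & (a.data < 1))

    def test_lstm_layer_gradients(self, rng):
        lstm = LSTM(2, 3, rng, return_sequences=True)
        x = Tensor(rng.normal(size=(2, 2, 5)), requires_grad=True)

        def forward():
            o = lstm(x)
            return ag.sum_(ag.mul(o, o))

        loss = forward()
        loss.backward()
        for t in [x, lstm.cell.Wx, lstm.cell.Wa, lstm.cell.b]:
            analytic = t.grad
            numeric = _numeric_grad(lambda: float(forward().data), t.data)
            assert np.abs(numeric - analytic).max() < 1e-5


class TestArchitectures:
    def test_baseline_dnn_parameter_count(self):
        """Dense chain 77->1024->512->128->64->5 plus 2 batch-norm terms per
        normalised layer."""
        net = build_baseline_dnn(77, 5, np.random.default_rng(0))
        widths = [77, 1024, 512, 128, 64, 5]
        dense = sum(a * b + b for a, b in zip(widths, widths[1:]))
        bn = sum(2 * w for w in widths[1:-1])
        assert net.n_params() == dense + bn

    @pytest.mark.parametrize("builder", [build_baseline_dnn, build_lstm,
                                         build_bilstm, build_hybrid,
                                         build_hemo_net])
    def test_forward_shape_and_finite(self, builder, rng):
        net = builder(77, 5, rng=np.random.default_rng(1)) \
            if builder is build_hemo_net else builder(77, 5, np.random.default_rng(1))
        x = rng.normal(size=(3, 77))
        xin = x[:, None, :] if net.input_kind == "sequence" else x
        out = net(Tensor(xin), train=False)
        assert out.shape == (3, 5)
        assert np.all(np.isfinite(out.data))
        proba = predict_proba_net(net, x)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_inception_block_output_channels_and_length(self, rng):
        blk = InceptionBlock(1, 32, np.random.default_rng(0))
        out = blk(Tensor(rng.normal(size=(2, 1, 77))))
        assert out.shape == (2, 4 * 32, 77)
        blk8 = InceptionBlock(16, 8, np.random.default_rng(0), bottleneck=8)
        out8 = blk8(Tensor(rng.normal(size=(2, 16, 77))))
        assert out8.shape == (2, 32, 77)

    def test_inception_zero_input_zero_preactivation(self):
        blk = InceptionBlock(1, 8, np.random.default_rng(0), bottleneck=4)
        out = blk(Tensor(np.zeros((1, 1, 77))))
        # bias-free convs + batch-norm beta 0 -> ReLU(0) = 0
        assert np.allclose(out.data, 0.0)

    def test_hemonet_residual_connection_is_live(self, rng):
        x = rng.normal(size=(2, 77))
        with_res = build_hemo_net(77, 5, n_filters=4, bottleneck=4,
                                  residual=True, rng=np.random.default_rng(3))
        without = build_hemo_net(77, 5, n_filters=4, bottleneck=4,
                                 residual=False, rng=np.random.default_rng(3))
        a = with_res(Tensor(x[:, None, :]), train=False).data
        b = without(Tensor(x[:, None, :]), train=False).data
        assert not np.allclose(a, b)

    def test_untrained_hemonet_is_chance_level(self, rng):
        net = build_hemo_net(77, 5, n_filters=4, bottleneck=4,
                             rng=np.random.default_rng(5))
        X = rng.normal(size=(500, 77))
        y = rng.integers(0, 5, 500)
        acc = (predict_proba_net(net, X).argmax(axis=1) == y).mean()
        assert abs(acc - 0.2) <= 0.1

    def test_invalid_input_length_rejected(self):
        with pytest.raises(ValueError):
            build_baseline_dnn(0)
        with pytest.raises(ValueError):
            build_hemo_net(77, n_classes=1)


class TestTraining:
    def _toy_problem(self, n=300, seed=0):
        """Five classes encoded by the amplitude of a smooth bump."""
        rng = np.random.default_rng(seed)
        t = np.arange(77)
        bump = np.exp(-0.5 * ((t - 40) / 8.0) ** 2)
        y = rng.integers(0, 5, n)
        X = (1 + y[:, None]) * bump[None, :] + rng.normal(scale=0.3, size=(n, 77))
        return X, y

    def test_loss_decreases_on_learnable_data(self):
        X, y = self._toy_problem()
        net = build_baseline_dnn(77, 5, np.random.default_rng(0))
        hist = train_deep(net, X, y, TrainingPlan(max_epochs=10, patience=0,
                                                  val_fraction=0.0, seed=0))
        assert np.median(hist.train_loss[-3:]) < np.median(hist.train_loss[:3])

    def test_same_seed_identical_weights(self):
        X, y = self._toy_problem(n=120)
        runs = []
        for _ in range(2):
            net = build_hemo_net(77, 5, n_filters=4, bottleneck=4,
                                 rng=np.random.default_rng(7))
            train_deep(net, X, y, TrainingPlan(max_epochs=2, patience=0,
                                               val_fraction=0.0, seed=7))
            runs.append(np.concatenate([p.data.ravel() for p in net.params()]))
        assert np.array_equal(runs[0], runs[1])

    def test_early_stopping_restores_best_weights(self):
        X, y = self._toy_problem(n=200)
        net = build_baseline_dnn(77, 5, np.random.default_rng(1))
        hist = train_deep(net, X, y, TrainingPlan(max_epochs=60, patience=3,
                                                  val_fraction=0.2, seed=1))
        assert hist.stopped_epoch <= 60
        assert len(hist.val_loss) == len(hist.train_loss)

    def test_non_finite_loss_raises_with_epoch(self):
        X, y = self._toy_problem(n=100)
        X[0, 0] = np.nan
        net = build_baseline_dnn(77, 5, np.random.default_rng(0))
        with pytest.raises(FloatingPointError, match="epoch"):
            train_deep(net, X, y, TrainingPlan(max_epochs=3, patience=0,
                                               val_fraction=0.0))

    def test_invalid_plan_rejected(self):
        with pytest.raises(ValueError):
            TrainingPlan(lr_min=0.1, lr_max=0.01)
        with pytest.raises(ValueError):
            TrainingPlan(lr_schedule="linear")

    def test_hemonet_learns_amplitude_classes(self):
        """Scaled-down Hemo-Net reaches high held-out accuracy on cleanly
        amplitude-coded bumps."""
        X, y = self._toy_problem(n=400, seed=3)
        net = build_hemo_net(77, 5, n_filters=8, bottleneck=8,
                             rng=np.random.default_rng(3))
        train_deep(net, X[:300], y[:300],
                   TrainingPlan(max_epochs=15, patience=15, seed=3))
        acc = (predict_proba_net(net, X[300:]).argmax(axis=1) == y[300:]).mean()
        assert acc >= 0.9
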